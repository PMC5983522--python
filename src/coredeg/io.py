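"""Reading and writing differential-expression tables, annotations and results.

The module speaks two table dialects:

* ``cuffdiff`` — the ``gene_exp.diff`` layout produced by Cuffdiff
  (``test_id  gene_id  gene  locus  sample_1  sample_2  status  value_1
  value_2  log2(fold_change)  test_stat  p_value  q_value  significant``).
* ``generic`` — a minimal five-column TSV
  (``locus_id  log2_fold_change  p_value  q_value  status``).

Both map onto a :class:`ContrastTable`, a thin wrapper around a pandas
DataFrame with one row per locus. Dashes (``-``) and non-``OK`` status
markers become ``status != TESTED`` with missing test results, mirroring how
Cuffdiff flags loci whose transcript abundance is too low for reliable
testing.

Directionality is organ-anchored, not column-anchored: the caller declares
which sample column is the storage-organ ("tuber") cultivar via
``tuber_side`` and fold changes are re-signed so that positive always means
higher expression in the tuberous cultivar.

I/O stays free of analysis policy: loci present in one table but not the
other are retained here; universe filtering is an explicit later step.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

# Status vocabulary of a ContrastTable row.
TESTED = "TESTED"
NOTEST = "NOTEST"
FAIL = "FAIL"
STATUSES = frozenset({TESTED, NOTEST, FAIL})

#: Pseudocount (FPKM) used when recomputing fold changes from abundances
#: that include zeros.
DEFAULT_EPSILON = 1e-6

GENERIC_COLUMNS = ["locus_id", "log2_fold_change", "p_value", "q_value", "status"]
CUFFDIFF_COLUMNS = [
    "test_id", "gene_id", "gene", "locus", "sample_1", "sample_2", "status",
    "value_1", "value_2", "log2(fold_change)", "test_stat", "p_value",
    "q_value", "significant",
]


@dataclass(frozen=True)
class ContrastTable:
    """Per-locus differential-expression results for one contrast.

    ``data`` holds one row per locus with columns ``locus_id``,
    ``fpkm_tuber``, ``fpkm_thin`` (NaN when the dialect carries no
    abundances), ``log2_fold_change`` (positive = higher in the tuberous
    cultivar), ``p_value``, ``q_value`` and ``status``.
    """

    contrast_id: str
    tuber_side: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        ids = self.data["locus_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValidationError(
                f"duplicate locus_id {dup!r} in contrast {self.contrast_id!r}"
            )
        bad = set(self.data["status"]) - STATUSES
        if bad:
            raise ValidationError(f"unknown status values: {sorted(bad)}")
        tested = self.data["status"] == TESTED
        for col in ("p_value", "q_value"):
            vals = self.data.loc[tested, col]
            if vals.isna().any():
                locus = self.data.loc[tested & self.data[col].isna(), "locus_id"].iloc[0]
                raise ValidationError(
                    f"locus {locus!r} is TESTED but has no numeric {col}"
                )
        both = tested & self.data["p_value"].notna() & self.data["q_value"].notna()
        # BH never decreases a p-value; tolerate float round-off in inputs.
        viol = self.data.loc[both][
            self.data.loc[both, "q_value"] < self.data.loc[both, "p_value"] * (1 - 1e-9)
        ]
        if len(viol):
            raise ValidationError(
                f"q_value < p_value for locus {viol['locus_id'].iloc[0]!r}"
            )

    @property
    def loci(self) -> frozenset[str]:
        return frozenset(self.data["locus_id"])

    @property
    def tested_loci(self) -> frozenset[str]:
        return frozenset(self.data.loc[self.data["status"] == TESTED, "locus_id"])

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class AnnotationMap:
    """Mapping of locus ids to sets of functional term ids (GO/KEGG-style)."""

    namespace: str
    assignments: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for locus, terms in self.assignments.items():
            if not terms:
                raise ValidationError(f"locus {locus!r} listed with empty term set")
            if any(not t for t in terms):
                raise ValidationError(f"locus {locus!r} has an empty term id")

    @property
    def terms(self) -> frozenset[str]:
        out: set[str] = set()
        for t in self.assignments.values():
            out |= t
        return frozenset(out)

    @property
    def annotated_loci(self) -> frozenset[str]:
        return frozenset(self.assignments)


@dataclass(frozen=True)
class TermHierarchy:
    """Child→parent term edges; must be acyclic.

    An empty hierarchy means every term counts as most specific.
    """

    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        cycle = _find_cycle(self.edges)
        if cycle is not None:
            raise ValidationError(
                "term hierarchy contains a cycle: " + " -> ".join(cycle)
            )

    def parents_of(self, term: str) -> frozenset[str]:
        return frozenset(p for c, p in self.edges if c == term)

    def ancestors_of(self, term: str) -> frozenset[str]:
        """All proper ancestors of ``term`` (transitive parents)."""
        parent_map: dict[str, set[str]] = {}
        for c, p in self.edges:
            parent_map.setdefault(c, set()).add(p)
        seen: set[str] = set()
        stack = list(parent_map.get(term, ()))
        while stack:
            t = stack.pop()
            if t in seen:
                continue
            seen.add(t)
            stack.extend(parent_map.get(t, ()))
        return frozenset(seen)


def _find_cycle(edges: Iterable[tuple[str, str]]) -> list[str] | None:
    """Return one cycle as a node list, or None. Iterative DFS, child→parent."""
    adj: dict[str, list[str]] = {}
    for c, p in edges:
        adj.setdefault(c, []).append(p)
    WHITE, GREY, BLACK = 0, 1, 2
    color: dict[str, int] = {}
    parent_edge: dict[str, str] = {}
    for start in adj:
        if color.get(start, WHITE) != WHITE:
            continue
        stack: list[tuple[str, int]] = [(start, 0)]
        color[start] = GREY
        while stack:
            node, i = stack[-1]
            nbrs = adj.get(node, [])
            if i < len(nbrs):
                stack[-1] = (node, i + 1)
                nxt = nbrs[i]
                c = color.get(nxt, WHITE)
                if c == WHITE:
                    color[nxt] = GREY
                    parent_edge[nxt] = node
                    stack.append((nxt, 0))
                elif c == GREY:
                    # walk back from node to nxt
                    cyc = [nxt, node]
                    cur = node
                    while cur != nxt:
                        cur = parent_edge[cur]
                        cyc.append(cur)
                    return cyc[::-1]
            else:
                color[node] = BLACK
                stack.pop()
    return None


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _numeric(series: pd.Series, col: str, allow_missing: pd.Series) -> pd.Series:
    """Parse a string column to float; '-' or '' allowed only where flagged."""
    raw = series.replace({"-": "", "NA": "", "nan": ""})
    out = pd.to_numeric(raw.where(raw != "", np.nan), errors="coerce")
    bad = out.isna() & (raw != "") & ~allow_missing
    if bad.any():
        raise ValidationError(
            f"non-numeric {col} value {series[bad].iloc[0]!r} in a TESTED row"
        )
    return out


def read_de_table(
    path: str | Path,
    dialect: str = "generic",
    tuber_side: str | None = None,
    contrast_id: str | None = None,
    epsilon: float = DEFAULT_EPSILON,
) -> ContrastTable:
    """Read a differential-expression table into a :class:`ContrastTable`.

    Parameters
    ----------
    path
        TSV file with a header row.
    dialect
        ``"cuffdiff"`` for ``gene_exp.diff`` layout or ``"generic"``.
    tuber_side
        For the cuffdiff dialect: which sample holds the storage-organ
        cultivar — either the literal column role (``"sample_1"`` /
        ``"sample_2"``) or the sample name appearing in those columns.
        Fold changes are re-signed so positive means higher in that sample.
        Ignored for the generic dialect (whose sign convention is already
        tuber-over-thin by contract).
    epsilon
        Pseudocount (FPKM) when recomputing a missing fold change from
        abundances: ``log2((fpkm_tuber + eps) / (fpkm_thin + eps))``.
    """
    if dialect not in ("generic", "cuffdiff"):
        raise FormatError(f"unknown dialect {dialect!r}")
    df = _read_tsv(path)
    name = contrast_id or Path(path).stem

    if dialect == "generic":
        missing = [c for c in GENERIC_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(
                f"generic table missing required column(s): {', '.join(missing)}"
            )
        status = df["status"].str.upper().replace({"OK": TESTED, "": NOTEST})
        untested = status != TESTED
        out = pd.DataFrame(
            {
                "locus_id": df["locus_id"],
                "fpkm_tuber": np.nan,
                "fpkm_thin": np.nan,
                "log2_fold_change": _numeric(
                    df["log2_fold_change"], "log2_fold_change", untested
                ),
                "p_value": _numeric(df["p_value"], "p_value", untested),
                "q_value": _numeric(df["q_value"], "q_value", untested),
                "status": status,
            }
        )
        return ContrastTable(name, tuber_side or "b", out)

    # cuffdiff dialect
    missing = [c for c in CUFFDIFF_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"cuffdiff table missing required column(s): {', '.join(missing)}"
        )
    if tuber_side is None:
        raise FormatError("cuffdiff dialect requires tuber_side")
    sample_1 = df["sample_1"].iloc[0] if len(df) else "sample_1"
    sample_2 = df["sample_2"].iloc[0] if len(df) else "sample_2"
    if tuber_side in ("sample_1", sample_1):
        tuber_is_2 = False
    elif tuber_side in ("sample_2", sample_2):
        tuber_is_2 = True
    else:
        raise FormatError(
            f"tuber_side {tuber_side!r} matches neither sample column "
            f"({sample_1!r}, {sample_2!r})"
        )

    status = df["status"].str.upper().map(
        lambda s: TESTED if s == "OK" else (FAIL if s == "FAIL" else NOTEST)
    )
    untested = status != TESTED
    value_1 = _numeric(df["value_1"], "value_1", pd.Series(True, index=df.index))
    value_2 = _numeric(df["value_2"], "value_2", pd.Series(True, index=df.index))
    l2fc = _numeric(df["log2(fold_change)"], "log2(fold_change)",
                    pd.Series(True, index=df.index))
    fpkm_tuber = value_2 if tuber_is_2 else value_1
    fpkm_thin = value_1 if tuber_is_2 else value_2
    # Cuffdiff sign is log2(value_2/value_1); flip when tuber is sample_1.
    signed = l2fc if tuber_is_2 else -l2fc
    recompute = signed.isna() & fpkm_tuber.notna() & fpkm_thin.notna()
    signed = signed.where(
        ~recompute,
        np.log2((fpkm_tuber + epsilon) / (fpkm_thin + epsilon)),
    )
    out = pd.DataFrame(
        {
            "locus_id": df["gene_id"].where(df["gene_id"] != "", df["test_id"]),
            "fpkm_tuber": fpkm_tuber,
            "fpkm_thin": fpkm_thin,
            "log2_fold_change": signed,
            "p_value": _numeric(df["p_value"], "p_value", untested),
            "q_value": _numeric(df["q_value"], "q_value", untested),
            "status": status,
        }
    )
    return ContrastTable(name, tuber_side, out)


def write_de_table(table: ContrastTable, path: str | Path) -> None:
    """Write a ContrastTable in the generic dialect ('-' for missing values)."""
    df = table.data
    rows = pd.DataFrame(
        {
            "locus_id": df["locus_id"],
            "log2_fold_change": _fmt_floats(df["log2_fold_change"]),
            "p_value": _fmt_floats(df["p_value"]),
            "q_value": _fmt_floats(df["q_value"]),
            "status": df["status"],
        }
    )
    rows.to_csv(path, sep="\t", index=False)


def _fmt_floats(s: pd.Series) -> pd.Series:
    # shortest repr round-trips floats exactly
    return s.map(lambda v: "-" if (v is None or (isinstance(v, float) and math.isnan(v)))
                 else str(float(v)))


def read_annotation(
    path: str | Path, format: str = "two_column_tsv", namespace: str = "GO"
) -> AnnotationMap:
    """Read locus→term annotations from a two-column TSV or a GMT file.

    Duplicate (locus, term) pairs collapse; loci with no terms are omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    assignments: dict[str, set[str]] = {}
    if format == "two_column_tsv":
        text = path.read_text().strip()
        if not text:
            raise ValidationError(f"empty annotation file: {path}")
        for ln, line in enumerate(text.splitlines(), 1):
            parts = line.rstrip("\n").split("\t")
            if ln == 1 and parts[:2] == ["locus_id", "term_id"]:
                continue  # optional header
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise FormatError(f"{path}:{ln}: expected two tab-separated columns")
            assignments.setdefault(parts[0], set()).add(parts[1])
    elif format == "gmt":
        text = path.read_text().strip()
        if not text:
            raise ValidationError(f"empty annotation file: {path}")
        for ln, line in enumerate(text.splitlines(), 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: GMT needs term, description, genes")
            term = parts[0]
            for locus in parts[2:]:
                if locus:
                    assignments.setdefault(locus, set()).add(term)
    else:
        raise FormatError(f"unknown annotation format {format!r}")
    if not assignments:
        raise ValidationError(f"annotation file has no assignments: {path}")
    return AnnotationMap(
        namespace, {k: frozenset(v) for k, v in assignments.items()}
    )


def read_term_hierarchy(path: str | Path) -> TermHierarchy:
    """Read child/parent term edges from a two-column TSV; verifies acyclicity."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    edges: set[tuple[str, str]] = set()
    text = path.read_text().strip()
    for ln, line in enumerate(text.splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if ln == 1 and parts[:2] == ["child_term", "parent_term"]:
            continue
        if len(parts) < 2 or not parts[0] or not parts[1]:
            raise FormatError(f"{path}:{ln}: expected child<TAB>parent")
        edges.add((parts[0], parts[1]))
    return TermHierarchy(frozenset(edges))


# ---------------------------------------------------------------------------
# Result writing
# ---------------------------------------------------------------------------

def write_results(results, path: str | Path, format: str = "tsv") -> None:
    """Serialize a result object (DataFrame, dataclass or mapping).

    TSV uses 12-significant-digit floats so a read-back reproduces values;
    JSON keeps full double precision.
    """
    if results is None:
        raise ValidationError("cannot write null results")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if dataclasses.is_dataclass(results) and not isinstance(results, type):
        results = dataclasses.asdict(results)
    if format == "json":
        if isinstance(results, pd.DataFrame):
            results = results.to_dict(orient="records")
        with open(path, "w") as fh:
            json.dump(results, fh, indent=2, default=_json_default)
            fh.write("\n")
    elif format == "tsv":
        if isinstance(results, Mapping):
            results = pd.DataFrame([results])
        if not isinstance(results, pd.DataFrame):
            raise ValidationError(f"cannot write {type(results).__name__} as TSV")
        results.to_csv(path, sep="\t", index=False, float_format="%.12g")
    else:
        raise FormatError(f"unknown output format {format!r}")


def _json_default(obj):
    if isinstance(obj, (frozenset, set)):
        return sorted(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj).__name__}")
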
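"""Direction calls, testable universe, Venn partition and core-set extraction.

A locus is called UP in a contrast when it is tested, its FDR-adjusted
q-value is at or below the significance level alpha, and its fold change is
positive (positive = higher in the storage-organ cultivar); DOWN with a
negative fold change; NS when tested but not significant; UNTESTED when the
source table flagged the locus as untestable.

The testable universe Omega defaults to loci tested in *both* contrasts
(size N). Over Omega, the pair of direction calls partitions loci into eight
disjoint Venn regions; the core set is the concordant regions
(up in both, or down in both), loci significant in both contrasts with
opposite signs are "discordant" — they count toward k1 and k2 but never
toward r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError
from .io import TESTED, ContrastTable
from . import overlap

UP = "UP"
DOWN = "DOWN"
NS = "NS"
UNTESTED = "UNTESTED"

UNIVERSE_MODES = ("tested_in_both", "tested_in_either", "explicit_list")

#: Default alpha grid for the significance-level sweep.
DEFAULT_ALPHA_GRID = (0.05, 1e-2, 1e-3, 1e-4, 1e-5, 1e-6, 1e-7, 1e-8, 1e-9)


@dataclass(frozen=True)
class Universe:
    """The set Omega of loci testable for differential expression; |Omega| = N."""

    loci: frozenset[str]

    @property
    def size_N(self) -> int:
        return len(self.loci)


@dataclass(frozen=True)
class VennPartition:
    """The eight direction-pair regions over the universe.

    Region membership is by (direction in contrast 1, direction in
    contrast 2); NS and UNTESTED both count as "not a DEG" here.
    """

    concordant_up: frozenset[str]
    concordant_down: frozenset[str]
    discordant: frozenset[str]
    only1_up: frozenset[str]
    only1_down: frozenset[str]
    only2_up: frozenset[str]
    only2_down: frozenset[str]
    neither: frozenset[str]

    _REGIONS = (
        "concordant_up", "concordant_down", "discordant",
        "only1_up", "only1_down", "only2_up", "only2_down", "neither",
    )

    def __post_init__(self) -> None:
        sets = [getattr(self, n) for n in self._REGIONS]
        total = sum(len(s) for s in sets)
        union: set[str] = set()
        for s in sets:
            union |= s
        if len(union) != total:
            raise ValidationError("Venn regions are not pairwise disjoint")

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for n in self._REGIONS:
            out |= getattr(self, n)
        return frozenset(out)

    @property
    def N(self) -> int:
        return sum(len(getattr(self, n)) for n in self._REGIONS)

    @property
    def r(self) -> int:
        return len(self.concordant_up) + len(self.concordant_down)

    @property
    def k1(self) -> int:
        return (len(self.concordant_up) + len(self.concordant_down)
                + len(self.discordant) + len(self.only1_up) + len(self.only1_down))

    @property
    def k2(self) -> int:
        return (len(self.concordant_up) + len(self.concordant_down)
                + len(self.discordant) + len(self.only2_up) + len(self.only2_down))

    def counts(self) -> dict[str, int]:
        d = {n: len(getattr(self, n)) for n in self._REGIONS}
        d.update(N=self.N, k1=self.k1, k2=self.k2, r=self.r)
        return d

    def to_frame(self) -> pd.DataFrame:
        """Long-format membership table (locus_id, region, direction)."""
        rows = []
        dir_of = {
            "concordant_up": UP, "concordant_down": DOWN,
            "only1_up": UP, "only1_down": DOWN,
            "only2_up": UP, "only2_down": DOWN,
            "discordant": "", "neither": "",
        }
        for region in self._REGIONS:
            for locus in sorted(getattr(self, region)):
                rows.append((locus, region, dir_of[region]))
        return pd.DataFrame(rows, columns=["locus_id", "region", "direction"])


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs shared by the core-set operations."""

    alpha: float = 0.05
    universe_mode: str = "tested_in_both"
    zero_fc_policy: str = "ns"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise DomainError(f"alpha must be in (0,1), got {self.alpha}")
        if self.universe_mode not in UNIVERSE_MODES:
            raise DomainError(f"unknown universe_mode {self.universe_mode!r}")
        if self.zero_fc_policy not in ("ns", "error"):
            raise DomainError(f"unknown zero_fc_policy {self.zero_fc_policy!r}")


def call_directions(
    table: ContrastTable, alpha: float = 0.05, zero_fc_policy: str = "ns"
) -> pd.DataFrame:
    """Per-locus direction calls at significance level alpha.

    Returns a DataFrame (locus_id, contrast_id, direction, q_value); the
    threshold is closed (q <= alpha). A significant locus with fold change
    exactly 0 has no direction: policy ``"ns"`` demotes it to NS,
    ``"error"`` raises naming the locus.
    """
    AnalysisConfig(alpha=alpha, zero_fc_policy=zero_fc_policy)
    df = table.data
    tested = (df["status"] == TESTED).to_numpy()
    q = df["q_value"].to_numpy(dtype=float)
    fc = df["log2_fold_change"].to_numpy(dtype=float)
    sig = tested & (q <= alpha)
    zero_sig = sig & (fc == 0)
    if zero_fc_policy == "error" and zero_sig.any():
        locus = df.loc[zero_sig, "locus_id"].iloc[0]
        raise ValidationError(
            f"locus {locus!r} significant at alpha={alpha} with zero fold change"
        )
    direction = np.where(
        ~tested, UNTESTED,
        np.where(sig & (fc > 0), UP, np.where(sig & (fc < 0), DOWN, NS)),
    )
    return pd.DataFrame(
        {
            "locus_id": df["locus_id"].to_numpy(),
            "contrast_id": table.contrast_id,
            "direction": direction,
            "q_value": q,
        }
    )


def build_universe(
    table1: ContrastTable,
    table2: ContrastTable,
    mode: str = "tested_in_both",
    explicit: frozenset[str] | None = None,
) -> Universe:
    """Build Omega from the two contrast tables.

    ``tested_in_both`` (default) keeps loci with status TESTED in both
    tables; ``tested_in_either`` takes the union; ``explicit_list`` uses a
    caller-supplied set.
    """
    if mode == "explicit_list":
        if explicit is None:
            raise DomainError("explicit_list mode requires an explicit locus set")
        return Universe(frozenset(explicit))
    if mode == "tested_in_both":
        loci = table1.tested_loci & table2.tested_loci
    elif mode == "tested_in_either":
        loci = table1.tested_loci | table2.tested_loci
    else:
        raise DomainError(f"unknown universe_mode {mode!r}")
    if not loci:
        raise ValidationError("universe is empty: the tested locus sets do not meet")
    return Universe(frozenset(loci))


def venn_partition(
    calls1: pd.DataFrame, calls2: pd.DataFrame, universe: Universe
) -> VennPartition:
    """Partition the universe into the eight direction-pair regions.

    Every universe locus must carry a call in both contrasts; loci outside
    the universe are ignored.
    """
    d1 = dict(zip(calls1["locus_id"], calls1["direction"]))
    d2 = dict(zip(calls2["locus_id"], calls2["direction"]))
    missing = [g for g in universe.loci if g not in d1 or g not in d2]
    if missing:
        raise ValidationError(
            f"{len(missing)} universe loci lack a direction call "
            f"(e.g. {sorted(missing)[:3]})"
        )
    regions: dict[str, set[str]] = {n: set() for n in VennPartition._REGIONS}
    for locus in universe.loci:
        a, b = d1[locus], d2[locus]
        a_sig = a in (UP, DOWN)
        b_sig = b in (UP, DOWN)
        if a_sig and b_sig:
            key = ("concordant_up" if a == UP else "concordant_down") if a == b \
                else "discordant"
        elif a_sig:
            key = "only1_up" if a == UP else "only1_down"
        elif b_sig:
            key = "only2_up" if b == UP else "only2_down"
        else:
            key = "neither"
        regions[key].add(locus)
    return VennPartition(**{k: frozenset(v) for k, v in regions.items()})


def extract_core_set(partition: VennPartition) -> dict[str, str]:
    """Concordant loci with their shared direction; discordant loci excluded."""
    core = {g: UP for g in partition.concordant_up}
    core.update({g: DOWN for g in partition.concordant_down})
    return core


def overlap_counts(
    table1: ContrastTable,
    table2: ContrastTable,
    alpha: float = 0.05,
    universe_mode: str = "tested_in_both",
) -> tuple[int, int, int, int]:
    """(N, k1, k2, r) without materializing region sets.

    Vectorized fast path used by the alpha sweep and simulation studies;
    agrees exactly with :func:`venn_partition` counts (tested property).
    """
    m = table1.data.merge(
        table2.data, on="locus_id", how="outer", suffixes=("_1", "_2")
    )
    t1 = (m["status_1"] == TESTED).to_numpy()
    t2 = (m["status_2"] == TESTED).to_numpy()
    if universe_mode == "tested_in_both":
        in_omega = t1 & t2
    elif universe_mode == "tested_in_either":
        in_omega = t1 | t2
    else:
        raise DomainError(f"unsupported universe_mode {universe_mode!r}")
    if not in_omega.any():
        raise ValidationError("universe is empty")
    q1 = m["q_value_1"].to_numpy(dtype=float)
    q2 = m["q_value_2"].to_numpy(dtype=float)
    f1 = m["log2_fold_change_1"].to_numpy(dtype=float)
    f2 = m["log2_fold_change_2"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        s1 = in_omega & t1 & (q1 <= alpha) & (f1 != 0)
        s2 = in_omega & t2 & (q2 <= alpha) & (f2 != 0)
        conc = s1 & s2 & (np.sign(f1) == np.sign(f2))
    return int(in_omega.sum()), int(s1.sum()), int(s2.sum()), int(conc.sum())


def alpha_sweep(
    table1: ContrastTable,
    table2: ContrastTable,
    alphas: tuple[float, ...] = DEFAULT_ALPHA_GRID,
    universe_mode: str = "tested_in_both",
    variant: str = overlap.DIRECTIONAL,
) -> pd.DataFrame:
    """Core-set size and significance across a grid of DEG alpha levels.

    One row per alpha with (alpha, N, k1, k2, r, p_value, log10_p,
    expected_r, fold_enrichment). The universe does not depend on alpha, so
    N is constant down the column; k1, k2 and r shrink as alpha tightens.
    """
    if len(alphas) == 0:
        raise DomainError("alpha grid is empty")
    for a in alphas:
        if not 0 < a < 1:
            raise DomainError(f"alpha {a} outside (0,1)")
    rows = []
    for a in alphas:
        N, k1, k2, r = overlap_counts(table1, table2, a, universe_mode)
        res = overlap._overlap_test(r, k1, k2, N, variant)
        rows.append(
            dict(alpha=a, N=N, k1=k1, k2=k2, r=r, p_value=res.p_value,
                 log10_p=res.log10_p, expected_r=res.expected_r,
                 fold_enrichment=res.fold_enrichment)
        )
    return pd.DataFrame(rows)
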
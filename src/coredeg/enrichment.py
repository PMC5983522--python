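"""Functional-term enrichment of the core set against a reference set.

For each functional term (GO/KEGG-style) a 2x2 contingency table is formed:

                 has term   lacks term
    core loci        a          b
    reference        c          d

tested with Fisher's exact test (two-sided by default, since terms may be
over- or under-represented) and Benjamini–Hochberg adjusted within the
annotation namespace. Loci without any annotation are dropped from both
sets before counting. The reference set is a uniform random sample of the
expressed universe (the study protocol: 10,000 loci, core not excluded).

When a term hierarchy is supplied, testing is limited to the most specific
annotated terms — terms with no annotated descendant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .coreset import Universe
from .errors import DomainError, ValidationError
from .io import AnnotationMap, TermHierarchy

logger = logging.getLogger(__name__)

SIDEDNESS = ("greater", "less", "two_sided")

#: Reference-set size used by the study protocol.
DEFAULT_REFERENCE_SIZE = 10_000


@dataclass(frozen=True)
class ReferenceSet:
    """A seeded uniform sample of loci used as the enrichment background."""

    loci: frozenset[str]
    seed: int

    @property
    def size(self) -> int:
        return len(self.loci)


def sample_reference(
    universe: Universe,
    size: int = DEFAULT_REFERENCE_SIZE,
    seed: int = 0,
    exclude: frozenset[str] | None = None,
) -> ReferenceSet:
    """Sample ``size`` loci uniformly without replacement from the universe.

    ``exclude`` removes loci (e.g. the core set) from the pool first; by
    default the pool is the whole universe, so core loci may be drawn.
    Deterministic for a fixed seed.
    """
    pool = sorted(universe.loci - (exclude or frozenset()))
    if size > len(pool):
        raise DomainError(
            f"cannot sample {size} loci from a pool of {len(pool)}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=size, replace=False)
    return ReferenceSet(frozenset(pool[i] for i in chosen), seed=seed)


def fisher_two_by_two(a: int, b: int, c: int, d: int,
                      sidedness: str = "two_sided") -> float:
    """Exact Fisher p for the table [[a, b], [c, d]].

    ``greater`` tests over-representation of the term in the top row;
    ``two_sided`` uses the minimum-likelihood convention (sums all tables
    with point probability <= the observed one).
    """
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if v != int(v) or v < 0:
            raise DomainError(f"count {name} must be a non-negative integer, got {v!r}")
    if a + b + c + d < 1:
        raise DomainError("empty contingency table")
    if sidedness not in SIDEDNESS:
        raise DomainError(f"unknown sidedness {sidedness!r}")
    alt = {"greater": "greater", "less": "less", "two_sided": "two-sided"}[sidedness]
    return float(fisher_exact([[a, b], [c, d]], alternative=alt).pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, input order preserved.

    adjusted_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def most_specific_terms(
    annotation: AnnotationMap, hierarchy: TermHierarchy | None = None
) -> frozenset[str]:
    """Annotated terms with no annotated descendant.

    Without a hierarchy every term is kept and a warning is logged (the
    caller cannot distinguish specific from broad terms).
    """
    used = annotation.terms
    if hierarchy is None or not hierarchy.edges:
        if hierarchy is None:
            logger.warning(
                "no term hierarchy supplied; treating all %d terms as most specific",
                len(used),
            )
        return used
    # A term is non-specific iff it is a proper ancestor of another used term.
    non_specific: set[str] = set()
    for term in used:
        non_specific |= hierarchy.ancestors_of(term) & used
    return frozenset(used - non_specific)


def term_enrichment(
    core: frozenset[str] | set[str] | dict,
    reference: ReferenceSet,
    annotation: AnnotationMap,
    hierarchy: TermHierarchy | None = None,
    sidedness: str = "two_sided",
    alpha_fdr: float = 0.05,
    min_annotated: int = 2,
) -> pd.DataFrame:
    """Per-term enrichment table for the core set versus the reference.

    Returns one row per tested term with columns term_id, namespace, a, b,
    c, d, odds_ratio, p_value, fdr, direction, significant, sorted by fdr.
    Terms with fewer than ``min_annotated`` annotated loci across both sets
    are skipped (singletons cannot reach significance and only inflate the
    BH denominator).
    """
    if sidedness not in SIDEDNESS:
        raise DomainError(f"unknown sidedness {sidedness!r}")
    core_set = frozenset(core)
    annotated = annotation.annotated_loci
    core_annot = core_set & annotated
    ref_annot = frozenset(reference.loci) & annotated
    if not core_annot:
        raise ValidationError("no core locus carries any annotation")
    if not ref_annot:
        raise ValidationError("no reference locus carries any annotation")
    n_core, n_ref = len(core_annot), len(ref_annot)

    testable = most_specific_terms(annotation, hierarchy)
    term_core: dict[str, int] = {}
    term_ref: dict[str, int] = {}
    for locus in core_annot:
        for t in annotation.assignments[locus]:
            term_core[t] = term_core.get(t, 0) + 1
    for locus in ref_annot:
        for t in annotation.assignments[locus]:
            term_ref[t] = term_ref.get(t, 0) + 1

    rows = []
    skipped = 0
    for term in sorted(testable):
        a = term_core.get(term, 0)
        c = term_ref.get(term, 0)
        if a + c < min_annotated:
            skipped += 1
            continue
        b, d = n_core - a, n_ref - c
        p = fisher_two_by_two(a, b, c, d, sidedness)
        if a * d > 0 and b * c > 0:
            odds = (a * d) / (b * c)
        else:  # 0.5 continuity for display only when a zero cell occurs
            odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        direction = "enriched" if a * (c + d) >= c * (a + b) else "depleted"
        rows.append((term, annotation.namespace, a, b, c, d, odds, p, direction))
    if skipped:
        logger.info("skipped %d terms with < %d annotated loci", skipped, min_annotated)
    if not rows:
        return pd.DataFrame(
            columns=["term_id", "namespace", "a", "b", "c", "d", "odds_ratio",
                     "p_value", "fdr", "direction", "significant"]
        )
    out = pd.DataFrame(
        rows,
        columns=["term_id", "namespace", "a", "b", "c", "d", "odds_ratio",
                 "p_value", "direction"],
    )
    out["fdr"] = bh_adjust(out["p_value"])
    out["significant"] = out["fdr"] <= alpha_fdr
    out = out.sort_values(
        ["fdr", "p_value", "term_id"], kind="mergesort"
    ).reset_index(drop=True)
    return out[["term_id", "namespace", "a", "b", "c", "d", "odds_ratio",
                "p_value", "fdr", "direction", "significant"]]
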
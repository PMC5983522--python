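"""Synthetic paired-contrast differential-expression data with known truth.

The generator emulates the parallel-evolution scenario behind the core-set
statistic: two independent contrasts (storage-organ vs thin cultivar in two
lineages) over one universe of loci, where

* a planted fraction ``f_core`` of loci is differentially expressed in both
  contrasts with one shared direction (the parallel "core"),
* each non-core locus is independently marked lineage-specific DE in
  contrast 1 (probability ``f_spec1``) and in contrast 2 (``f_spec2``) —
  independently per contrast, so a locus can be DE in both by chance with
  independently drawn directions (class ``spec_both``),
* the remainder are null loci with uniform p-values,
* a fraction ``f_untested`` per contrast is flagged untestable (the
  Cuffdiff ``NOTEST`` behaviour on low-abundance loci), independently per
  contrast.

The per-contrast independence of lineage-specific DE is essential: with
``f_core = 0`` it makes one DEG list a random sample of the universe with
respect to the other — exactly the null hypothesis of the directional
overlap test, and the basis of :func:`null_calibration`.

DE evidence is simulated at the summary-statistic level. A planted locus
carries a true log2 fold change of magnitude |Normal(effect_mean,
effect_sd)| with its class's sign; the observed log2 fold change adds
measurement noise Normal(0, null_sd), where ``null_sd`` is the per-locus
standard error of the estimate. The test statistic is z = observed /
null_sd (so null loci have z ~ Normal(0, 1) and uniform two-sided
p-values), and q is BH-adjusted within contrast over tested loci. No read
counts, FPKM magnitudes, library sizes or replicate pooling are modelled.

All randomness flows from ``SimParams.seed`` through one generator in a
fixed stream order (class directions, effect sizes, z-scores contrast 1,
z-scores contrast 2, untested masks), so outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from . import overlap
from .coreset import DOWN, UP, overlap_counts
from .errors import DomainError
from .io import NOTEST, TESTED, AnnotationMap, ContrastTable

CLASS_CORE = "core"
CLASS_SPEC1 = "spec1"
CLASS_SPEC2 = "spec2"
CLASS_SPEC_BOTH = "spec_both"
CLASS_NULL = "null"


@dataclass(frozen=True)
class SimParams:
    """Study-condition knobs for the dual-contrast generator.

    Defaults are the strong-parallelism scenario used throughout the test
    suite: 10,000 loci, a 2% planted core, 5% lineage-specific DEGs per
    contrast, planted |log2 fold change| ~ |Normal(4, 0.5)| (a ~16-fold
    change) observed with standard error ``null_sd`` = 0.25, 2% untestable
    loci per contrast, and DEG calling at alpha = 0.05.
    """

    n_genes: int = 10_000
    f_core: float = 0.02
    f_spec1: float = 0.05
    f_spec2: float = 0.05
    p_up: float = 0.5
    effect_mean: float = 4.0
    effect_sd: float = 0.5
    null_sd: float = 0.25
    f_untested: float = 0.02
    alpha: float = 0.05
    concordance: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise DomainError("n_genes must be >= 1")
        for name in ("f_core", "f_spec1", "f_spec2", "p_up", "f_untested",
                     "concordance"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise DomainError(f"{name} must be in [0,1], got {v}")
        if self.f_core + self.f_spec1 > 1 or self.f_core + self.f_spec2 > 1:
            raise DomainError("f_core + f_spec exceeds 1")
        if self.effect_mean <= 0:
            raise DomainError("effect_mean must be > 0")
        if not 0 < self.alpha < 1:
            raise DomainError("alpha must be in (0,1)")


@dataclass(frozen=True)
class TruthLabels:
    """Per-locus simulation truth: class and true direction per contrast."""

    frame: pd.DataFrame = field(repr=False)  # locus_id, cls, dir1, dir2

    @property
    def core_loci(self) -> frozenset[str]:
        f = self.frame
        return frozenset(f.loc[f["cls"] == CLASS_CORE, "locus_id"])

    @property
    def concordant_core(self) -> dict[str, str]:
        """Core loci whose two true directions agree, with that direction."""
        f = self.frame
        sel = (f["cls"] == CLASS_CORE) & (f["dir1"] == f["dir2"])
        return dict(zip(f.loc[sel, "locus_id"], f.loc[sel, "dir1"]))


@dataclass(frozen=True)
class RecoveryMetrics:
    """Precision/recall of a detected core set against the planted truth."""

    precision: float | None
    recall: float
    detected_r: int
    true_core: int


@dataclass(frozen=True)
class CalibrationResult:
    """Observed type-I error of the overlap test under the simulated null."""

    n_reps: int
    alpha: float
    n_rejections: int
    rate: float
    ci_low: float
    ci_high: float


def _locus_ids(n: int) -> np.ndarray:
    return np.array([f"g{i:06d}" for i in range(n)])


def simulate_dual_contrast(
    params: SimParams,
) -> tuple[ContrastTable, ContrastTable, TruthLabels]:
    """Generate the two contrast tables and the truth labels.

    Effect magnitudes are |Normal(effect_mean, effect_sd)| log2 units (a
    truncation to positive values; negligible mass is reflected at the
    defaults). Core loci draw one direction shared by both contrasts with
    probability ``concordance`` (flipped in contrast 2 otherwise);
    non-core loci are marked DE independently per contrast, with
    independent direction draws.
    """
    n = params.n_genes
    rng = np.random.default_rng(params.seed)
    ids = _locus_ids(n)

    n_core = round(params.f_core * n)
    # Stream order: spec masks, directions, effects, z1, z2, untested masks.
    noncore = np.arange(n) >= n_core
    de1 = ~noncore.copy()
    de2 = ~noncore.copy()
    de1[noncore] = rng.random(n - n_core) < params.f_spec1
    de2[noncore] = rng.random(n - n_core) < params.f_spec2

    cls = np.full(n, CLASS_NULL, dtype=object)
    cls[:n_core] = CLASS_CORE
    cls[noncore & de1 & ~de2] = CLASS_SPEC1
    cls[noncore & ~de1 & de2] = CLASS_SPEC2
    cls[noncore & de1 & de2] = CLASS_SPEC_BOTH

    sign_core = np.where(rng.random(n_core) < params.p_up, 1.0, -1.0)
    flip = np.where(rng.random(n_core) < params.concordance, 1.0, -1.0)
    sign_nc1 = np.where(rng.random(n - n_core) < params.p_up, 1.0, -1.0)
    sign_nc2 = np.where(rng.random(n - n_core) < params.p_up, 1.0, -1.0)

    sgn1 = np.zeros(n)
    sgn2 = np.zeros(n)
    sgn1[:n_core] = sign_core
    sgn2[:n_core] = sign_core * flip
    sgn1[noncore] = np.where(de1[noncore], sign_nc1, 0.0)
    sgn2[noncore] = np.where(de2[noncore], sign_nc2, 0.0)

    eff1 = np.abs(rng.normal(params.effect_mean, params.effect_sd, n))
    eff2 = np.abs(rng.normal(params.effect_mean, params.effect_sd, n))
    # z = (true log2fc + Normal(0, null_sd)) / null_sd
    z1 = sgn1 * eff1 / params.null_sd + rng.standard_normal(n)
    z2 = sgn2 * eff2 / params.null_sd + rng.standard_normal(n)
    untested1 = rng.random(n) < params.f_untested
    untested2 = rng.random(n) < params.f_untested

    t1 = _make_table(ids, z1, untested1, params, "contrast1")
    t2 = _make_table(ids, z2, untested2, params, "contrast2")

    dirmap = {1.0: UP, -1.0: DOWN, 0.0: "none"}
    truth = TruthLabels(
        pd.DataFrame(
            {
                "locus_id": ids,
                "cls": cls,
                "dir1": [dirmap[v] for v in sgn1],
                "dir2": [dirmap[v] for v in sgn2],
            }
        )
    )
    return t1, t2, truth


def _make_table(ids, z, untested, params: SimParams, contrast_id: str) -> ContrastTable:
    p = 2.0 * norm.sf(np.abs(z))
    q = np.full_like(p, np.nan)
    tested = ~untested
    if tested.any():
        q[tested] = multipletests(p[tested], method="fdr_bh")[1]
    p = np.where(tested, p, np.nan)
    fc = np.where(tested, params.null_sd * z, np.nan)
    df = pd.DataFrame(
        {
            "locus_id": ids,
            "fpkm_tuber": np.nan,
            "fpkm_thin": np.nan,
            "log2_fold_change": fc,
            "p_value": p,
            "q_value": q,
            "status": np.where(tested, TESTED, NOTEST),
        }
    )
    return ContrastTable(contrast_id, "b", df)


def evaluate_recovery(detected_core, truth: TruthLabels) -> RecoveryMetrics:
    """Precision/recall of a detected core set versus the planted core.

    ``detected_core`` may be a mapping locus -> direction (direction must
    match the planted shared direction to count as a true positive) or a
    bare set (membership only).
    """
    known = set(truth.frame["locus_id"])
    detected = dict(detected_core) if isinstance(detected_core, dict) else {
        g: None for g in detected_core
    }
    if not set(detected) <= known:
        raise DomainError("detected core contains loci absent from the simulation")
    true_core = truth.concordant_core
    tp = sum(
        1
        for g, d in detected.items()
        if g in true_core and (d is None or d == true_core[g])
    )
    precision = tp / len(detected) if detected else None
    recall = tp / len(true_core) if true_core else 0.0
    return RecoveryMetrics(
        precision=precision,
        recall=recall,
        detected_r=len(detected),
        true_core=len(true_core),
    )


def simulate_annotation(
    truth: TruthLabels,
    n_terms: int = 100,
    enrich_terms: int = 5,
    enrich_factor: float = 5.0,
    base_rate: float = 0.05,
    seed: int = 0,
) -> AnnotationMap:
    """Random term annotation with planted core enrichment.

    Every term attaches to each non-core locus with probability
    ``base_rate``. The first ``enrich_terms`` terms (ids ``T000``,
    ``T001``, ...; see :func:`planted_terms`) attach to core loci with
    probability ``min(1, enrich_factor * base_rate)``; the remaining terms
    treat core loci like any other. Loci that end up with no terms are
    omitted from the map.
    """
    if enrich_terms > n_terms:
        raise DomainError("enrich_terms exceeds n_terms")
    if enrich_factor < 1:
        raise DomainError("enrich_factor must be >= 1")
    rate_hi = enrich_factor * base_rate
    if rate_hi > 1:
        import logging
        logging.getLogger(__name__).warning(
            "enrich_factor * base_rate = %.3f > 1; clamping to 1", rate_hi
        )
        rate_hi = 1.0
    rng = np.random.default_rng(seed)
    ids = truth.frame["locus_id"].to_numpy()
    is_core = (truth.frame["cls"] == CLASS_CORE).to_numpy()
    assignments: dict[str, set[str]] = {}
    for j in range(n_terms):
        term = f"T{j:03d}"
        rate = np.where(is_core & (j < enrich_terms), rate_hi, base_rate)
        hit = rng.random(len(ids)) < rate
        for locus in ids[hit]:
            assignments.setdefault(locus, set()).add(term)
    return AnnotationMap(
        "SIM", {k: frozenset(v) for k, v in assignments.items()}
    )


def planted_terms(enrich_terms: int) -> frozenset[str]:
    """Term ids that :func:`simulate_annotation` planted as enriched."""
    return frozenset(f"T{j:03d}" for j in range(enrich_terms))


def replicate_seeds(seed: int, n_reps: int) -> np.ndarray:
    """Deterministic per-replicate child seeds (< 2**31) from one master seed."""
    return np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)


def null_calibration(
    params: SimParams, n_reps: int = 2000, alpha: float = 0.05, seed: int = 0
) -> CalibrationResult:
    """Observed type-I error of the directional overlap test under the null.

    Requires ``params.f_core == 0``. For each replicate, a fresh null
    dataset is generated, the (N, k1, k2, r) counts are taken at
    ``params.alpha``, and the directional p-value is computed; the returned
    rate is the fraction of replicates with p <= ``alpha``, with a
    Clopper–Pearson 95% interval.
    """
    if params.f_core != 0:
        raise DomainError("null_calibration requires f_core = 0")
    if n_reps < 100:
        raise DomainError("n_reps must be >= 100")
    seeds = replicate_seeds(seed, n_reps)
    hits = 0
    for s in seeds:
        t1, t2, _ = simulate_dual_contrast(replace(params, seed=int(s)))
        N, k1, k2, r = overlap_counts(t1, t2, params.alpha)
        p = overlap.directional_overlap_test(r, k1, k2, N).p_value
        if p <= alpha:
            hits += 1
    lo, hi = proportion_confint(hits, n_reps, alpha=0.05, method="beta")
    return CalibrationResult(
        n_reps=n_reps, alpha=alpha, n_rejections=hits,
        rate=hits / n_reps, ci_low=float(lo), ci_high=float(hi),
    )
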
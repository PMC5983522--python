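# Methods

## The directional overlap model

Two differential-expression contrasts are compared over a common universe Ω
of N loci. A locus is a DEG in a contrast when its BH-adjusted q-value is at
or below the significance level α (closed threshold, q ≤ α) and its log2
fold change is non-zero; the direction of the fold change (anchored so that
positive means higher in the storage-organ cultivar) labels it up- or
down-regulated. With k₁ and k₂ DEGs per contrast, the core set is the r
loci significant in both with the same direction.

Under the null of independent recruitment, one DEG list is a uniform random
sample of Ω with respect to the other, so the plain list overlap is
hypergeometric with population N. Direction concordance is modelled by
doubling the sample space to 2N — each drawn DEG carries an equiprobable
up/down label — and the p-value is the upper hypergeometric tail at r with
population 2N, successes k₁, draws k₂. This doubling is an approximation
that is very good for large gene samples; its operational accuracy is
measured here rather than assumed (see Calibration).

Numerics: every term is evaluated as a log-gamma expression and the tail is
accumulated with log-sum-exp, so the p-value is computed accurately down to
(and its log10 reported below) the double-precision underflow limit. The
tail is symmetric in (k₁, k₂); the implementation canonicalizes the argument
order so exchangeability holds bit-exactly. If r falls at or below the lower
support bound max(0, k₁ + k₂ − population), the event is certain and p = 1.
An exact rational-arithmetic enumeration (`brute_force_overlap_pvalue`,
populations ≤ 60) serves as the independent oracle in the test suite, and
the tail is also cross-checked against `scipy.stats.hypergeom.sf`.

## Universe, Venn partition, α sweep

The default universe is `tested_in_both`: loci whose test status is TESTED
in both contrasts (Cuffdiff `NOTEST` and `FAIL` both excluded; the two
causes are not distinguishable in deposited tables and are treated alike).
`tested_in_either` and an explicit locus list are available because
published universe definitions are often ambiguous. Over Ω the two
direction calls partition loci into eight disjoint regions (concordant
up/down, discordant, four exclusive regions, neither); k₁, k₂ and r are
region sums, and discordant loci count toward k₁ and k₂ but never r. A
locus with a significant q but a fold change of exactly 0 has no direction
and is demoted to non-significant by default (configurable to an error);
it therefore enters neither the DEG counts nor the core set. The α sweep
re-thresholds both contrasts over a descending grid (default 0.05 down to
10⁻⁹) with the universe held fixed, so N is constant and k₁, k₂, r are
non-increasing.

## Term enrichment

For each annotation term, core and reference loci are cross-tabulated as a
2×2 table (annotated loci only: loci with no term at all are dropped from
both sets first) and tested with Fisher's exact test — two-sided by default
(minimum-likelihood convention), since terms may be over- or
under-represented — followed by BH adjustment within the namespace. The
reference set is a uniform seeded sample of the universe (default 10,000
loci, core loci *not* excluded, matching the common protocol; exclusion is
an option). Terms with fewer than 2 annotated loci across both sets are
skipped: they cannot reach significance and only inflate the BH
denominator. When a child→parent term hierarchy is supplied, testing is
restricted to the most specific annotated terms (no annotated proper
descendant). Odds ratios use a 0.5 continuity correction only for display
when a zero cell occurs; p-values never do. Fisher's test and BH are
delegated to scipy and statsmodels respectively and are pinned by
exact-enumeration and hand-derived oracles in the tests.

Note that BH step-up is *not* idempotent (re-adjusting adjusted values
inflates them again); the invariants that do hold — adjusted values dominate
the p-values and are monotone in sorted-p order — are what the tests assert.

## The synthetic generator

`simulate_dual_contrast` emulates a parallel-evolution scenario at the
summary-statistic level:

| parameter | meaning | default |
|---|---|---|
| `n_genes` | universe size before untested filtering | 10,000 |
| `f_core` | fraction planted as direction-concordant core DEGs | 0.02 |
| `f_spec1`, `f_spec2` | per-contrast lineage-specific DEG probability | 0.05 |
| `p_up` | probability a planted direction is up | 0.5 |
| `effect_mean`, `effect_sd` | planted \|log2 fold change\| ~ \|Normal(m, s)\| | 4.0, 0.5 |
| `null_sd` | per-locus standard error of the observed log2 fold change | 0.25 |
| `f_untested` | per-contrast probability of NOTEST status | 0.02 |
| `alpha` | DEG q-threshold used downstream | 0.05 |
| `concordance` | probability a core locus keeps its direction in contrast 2 | 1.0 |

Each locus/contrast observes log2fc = true effect + Normal(0, null_sd),
tested with z = log2fc / null_sd, two-sided normal p, and BH q within the
contrast over tested loci. Null loci thus have z ~ Normal(0, 1) and uniform
p-values. An effect_mean of 4 log2 units (~16-fold) with null_sd 0.25 gives
essentially certain per-contrast detection, so recall at the defaults is
governed by the untested fraction — (1 − f_untested)² ≈ 0.96 is the ceiling,
which is why f_untested defaults to a modest 0.02.

Two structural choices matter:

* **Lineage-specific DE is drawn independently per contrast**, so two loci
  lists overlap at the product rate and a locus can be DE in both contrasts
  by chance with independently drawn directions (truth class `spec_both`).
  Without this independence the generated DEG lists would avoid each other
  and the f_core = 0 configuration would *not* realize the hypergeometric
  null the test assumes — the null-calibration study would be meaningless.
* **Core loci draw one shared direction** (flipped in contrast 2 with
  probability 1 − concordance), the parallelism assumption itself.

All draws flow from one `numpy` Generator seeded by `SimParams.seed` in a
fixed stream order (spec masks, directions, effect sizes, z-scores contrast
1, z-scores contrast 2, untested masks), so outputs are bit-reproducible;
replicate studies derive child seeds from a master seed via
`numpy.random.SeedSequence`.

What the generator does **not** model: read counts, FPKM magnitudes,
library size, isoforms, replicate pooling, or correlated effect sizes.
Passing calibration and recovery tests therefore demonstrate correctness of
the statistical machinery under the stated sampling model, not robustness
to count-level artefacts of real RNA-seq.

## Calibration and power (what the suite measures)

* **Type-I error.** With f_core = 0 and 5% lineage-specific DEGs, the
  directional test rejects ~3% of null replicates at α = 0.05 (500-replicate
  driver: rate 0.030, 95% CI 0.017–0.049; the acceptance suite runs 2,000
  replicates). The slight conservatism reflects the discreteness of the
  tail statistic and the doubled-sample-space approximation.
* **Recovery.** At the defaults the full pipeline recovers the planted core
  with precision ≈ 0.93 and recall ≈ 0.95; residual false positives are
  dominated by chance-concordant `spec_both` loci, which is the behaviour
  the statistic's null predicts. Recall rises with effect size (mean recall
  0.45 / 0.93 / 0.95 at effect_mean 1 / 2 / 4 in the 5,000-locus power
  driver).

Problem sizes in the shipped studies (10,000-locus replicates, 2,000
calibration replicates, 100 recovery replicates, 200 enrichment replicates,
exhaustive oracle sweeps at N ≤ 15 and 2×2 totals ≤ 40) were chosen so each
study estimates its quantity to well within the asserted tolerance.

## I/O conventions

The Cuffdiff `gene_exp.diff` dialect signs fold changes as
log2(value_2/value_1); the reader re-anchors the sign to the declared
storage-organ sample (`tuber_side`) so positive always means higher in the
tuber. Missing fold changes are recomputed from FPKMs with a configurable
pseudocount ε = 10⁻⁶. Dashes and non-OK statuses map to NOTEST/FAIL with
absent test results. Loci present in only one table are kept at read time —
universe filtering is an explicit analysis step, not an I/O side effect.
Generated tables are written in the generic dialect with shortest-repr
floats, so write→read round-trips are exact.

## Known limitations

* The directional 2N null is the approximation itself; no exact
  direction-thinned analytic test is provided (the generator plays that
  role empirically).
* Per-gene q-values are consumed as given; the package never re-derives
  q from p when a q column exists.
* Enrichment results depend entirely on the supplied annotation; no
  ontology download, propagation to ancestors, or annotation inference is
  performed.
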
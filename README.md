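# coredeg

Direction-aware core-DEG overlap analysis for paired differential-expression
contrasts.

## The problem

When two independent lineages evolve the same phenotype — e.g. the swollen
stem of kohlrabi (*Brassica oleracea*) and the swollen hypocotyl/root of
turnip (*B. rapa*) — a natural transcriptomic question is whether they did it
with the *same genes*. Given a differential-expression contrast in each
lineage (storage-organ cultivar vs thin-organ cultivar), the "core set" is
the set of homologous loci that are differentially expressed in **both**
contrasts **with the same direction of change**. coredeg answers: is that
core set larger than chance, and what is it enriched for?

## The statistic

Let Ω be the universe of N loci testable in both contrasts, and let the two
contrasts yield k₁ and k₂ DEGs (q ≤ α after Benjamini–Hochberg adjustment).
Under the null, one DEG list is a random sample of Ω with respect to the
other, so the plain overlap is hypergeometric with population N. Requiring
the *direction* of change to agree as well doubles the sample space — each
drawn DEG carries an up/down label — giving population 2N. The p-value for
an observed concordant overlap r is the upper tail

```
p = Σ_{i=r}^{min(k1,k2)}  C(k1, i) · C(2N − k1, k2 − i) / C(2N, k2)
```

(equivalently `sum(dhyper(r:min(k1,k2), k1, 2*N−k1, k2))` in R), which is
exchangeable in (k₁, k₂). coredeg evaluates it in log space with log-gamma
terms, so tails near 10⁻¹⁶⁰ come out exact to the displayed precision
instead of underflowing. The classic non-directional (population N) variant,
the null mean k₁k₂/(2N), and an exact rational-arithmetic oracle for tiny
instances are included.

Downstream, the core set is profiled for functional-term enrichment
(GO/KEGG-style annotations) against a seeded random reference sample of the
universe using Fisher's exact test with BH FDR, optionally restricted to the
most specific terms of a term hierarchy.

A synthetic dual-contrast generator plants a known parallel core plus
lineage-specific DEGs and untestable loci, so calibration (type-I error of
the directional test) and power (planted-core recovery) are measurable
without any external data.

## Worked example

The headline statistic needs only four integers. With the counts of the
*Brassica* tuber study — r = 841 concordant shared DEGs out of k₁ = 3709 and
k₂ = 6521 DEGs over N = 38192 testable loci:

```
$ coredeg overlap-test --r 841 --k1 3709 --k2 6521 --N 38192 --variant directional
{
  "r": 841,
  "k1": 3709,
  "k2": 6521,
  "N": 38192,
  "variant": "directional_2N",
  "p_value": 8.608809545046859e-161,
  "log10_p": -160.06505690008666,
  "expected_r": 316.64208472978635,
  "fold_enrichment": 2.6559956511077365
}
```

Read: under the directional null one expects ~317 concordant shared DEGs by
chance; 841 is a 2.66-fold excess with p ≈ 8.6 × 10⁻¹⁶¹ — overwhelming
evidence that the two lineages recruited overlapping expression changes.

The full pipeline runs from two DE tables (Cuffdiff `gene_exp.diff` or a
minimal generic TSV):

```
$ coredeg coreset --table1 contrast1.tsv --table2 contrast2.tsv --outdir out/
$ coredeg report --summary out/summary.json
```

## Analysis scripts

`analysis/` contains numbered drivers that exercise the whole workflow on
synthetic data and write their tables under `results/`:

| script | what it does |
|---|---|
| `01_simulate_contrasts.py` | generate the baseline planted-parallelism dataset |
| `02_coreset_analysis.py` | direction calls → Venn partition → overlap tests → α sweep → enrichment |
| `03_headline_overlap_test.py` | the four-integer directional test above |
| `04_null_calibration.py` | type-I error of the directional test under the null |
| `05_power_study.py` | core-set recovery across planted effect sizes |

On the baseline dataset (seed 1), `02_coreset_analysis.py` prints:

```
universe N = 9584; k1 = 699, k2 = 721, r = 206
directional p = 3.19e-131 (log10 p = -130.5), expected r = 26.3, fold enrichment = 7.83
enrichment: 6 of 100 terms significant at FDR <= 0.05
```

— the 200-locus planted core is recovered (206 detected, ~7.8-fold excess
over the null mean of 26), and the 5 planted annotation terms are among the
6 significant ones.

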
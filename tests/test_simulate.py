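"""Synthetic dual-contrast generator: determinism, null fidelity, recovery."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from coredeg import coreset, io, simulate
from coredeg.errors import DomainError
from coredeg.simulate import (
    CLASS_CORE,
    CLASS_SPEC1,
    CLASS_SPEC_BOTH,
    SimParams,
    evaluate_recovery,
    null_calibration,
    simulate_annotation,
    simulate_dual_contrast,
)


class TestParams:
    def test_infeasible_fractions(self):
        with pytest.raises(DomainError):
            SimParams(f_core=0.6, f_spec1=0.5)

    def test_effect_must_be_positive(self):
        with pytest.raises(DomainError):
            SimParams(effect_mean=0.0)


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        p = SimParams(n_genes=500, seed=9)
        a1, a2, at = simulate_dual_contrast(p)
        b1, b2, bt = simulate_dual_contrast(p)
        pd.testing.assert_frame_equal(a1.data, b1.data)
        pd.testing.assert_frame_equal(a2.data, b2.data)
        pd.testing.assert_frame_equal(at.frame, bt.frame)
        io.write_de_table(a1, tmp_path / "a.tsv")
        io.write_de_table(b1, tmp_path / "b.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_different_seed_differs(self):
        a1, _, _ = simulate_dual_contrast(SimParams(n_genes=500, seed=1))
        b1, _, _ = simulate_dual_contrast(SimParams(n_genes=500, seed=2))
        assert not a1.data.equals(b1.data)


class TestTruthStructure:
    def test_core_shares_direction_and_spec_is_one_sided(self):
        _, _, truth = simulate_dual_contrast(SimParams(n_genes=3000, seed=4))
        f = truth.frame
        core = f[f["cls"] == CLASS_CORE]
        assert (core["dir1"] == core["dir2"]).all()
        assert set(core["dir1"]) <= {"UP", "DOWN"}
        spec1 = f[f["cls"] == CLASS_SPEC1]
        assert (spec1["dir2"] == "none").all()
        assert (spec1["dir1"] != "none").all()

    def test_partial_concordance(self):
        _, _, truth = simulate_dual_contrast(
            SimParams(n_genes=4000, f_core=0.1, concordance=0.5, seed=4))
        f = truth.frame
        core = f[f["cls"] == CLASS_CORE]
        agree = (core["dir1"] == core["dir2"]).mean()
        assert 0.3 < agree < 0.7
        assert set(truth.concordant_core) < set(core["locus_id"])

    def test_spec_status_independent_across_contrasts(self):
        """Lineage-specific DE marks must overlap at the product rate, not
        avoid each other — otherwise the generator breaks the null."""
        _, _, truth = simulate_dual_contrast(
            SimParams(n_genes=20000, f_core=0.0, f_spec1=0.1, f_spec2=0.1, seed=8))
        f = truth.frame
        both = (f["cls"] == CLASS_SPEC_BOTH).mean()
        assert both == pytest.approx(0.01, abs=0.003)

    def test_untested_fraction(self):
        t1, _, _ = simulate_dual_contrast(
            SimParams(n_genes=10000, f_untested=0.2, seed=3))
        frac = (t1.data["status"] == io.NOTEST).mean()
        assert frac == pytest.approx(0.2, abs=0.02)


def test_null_pvalues_uniform():
    """With nothing planted, p-values pass a KS test against Uniform(0,1)."""
    t1, t2, truth = simulate_dual_contrast(
        SimParams(n_genes=10000, f_core=0.0, f_spec1=0.0, f_spec2=0.0,
                  f_untested=0.0, seed=13))
    assert truth.core_loci == frozenset()
    for t in (t1, t2):
        stat = kstest(t.data["p_value"], "uniform")
        assert stat.pvalue > 0.01


class TestRecovery:
    def truth_with_core(self, dirs):
        frame = pd.DataFrame(
            {"locus_id": list(dirs), "cls": CLASS_CORE,
             "dir1": list(dirs.values()), "dir2": list(dirs.values())}
        )
        return simulate.TruthLabels(frame)

    def test_perfect_detection(self):
        truth = self.truth_with_core({"g1": "UP", "g2": "DOWN"})
        m = evaluate_recovery({"g1": "UP", "g2": "DOWN"}, truth)
        assert m.precision == 1.0 and m.recall == 1.0

    def test_empty_detection(self):
        truth = self.truth_with_core({"g1": "UP"})
        m = evaluate_recovery(set(), truth)
        assert m.precision is None and m.recall == 0.0

    def test_half_detected_no_false_positives(self):
        truth = self.truth_with_core({"g1": "UP", "g2": "DOWN"})
        m = evaluate_recovery({"g1": "UP"}, truth)
        assert m.precision == 1.0 and m.recall == 0.5

    def test_direction_mismatch_is_false_positive(self):
        truth = self.truth_with_core({"g1": "UP"})
        m = evaluate_recovery({"g1": "DOWN"}, truth)
        assert m.precision == 0.0 and m.recall == 0.0

    def test_unknown_locus_rejected(self):
        truth = self.truth_with_core({"g1": "UP"})
        with pytest.raises(DomainError):
            evaluate_recovery({"zz": "UP"}, truth)


class TestAnnotationSim:
    def test_planted_rate_ratio(self):
        _, _, truth = simulate_dual_contrast(
            SimParams(n_genes=5000, f_core=0.2, seed=21))
        ann = simulate_annotation(truth, n_terms=20, enrich_terms=1,
                                  enrich_factor=5.0, base_rate=0.1, seed=21)
        core = truth.core_loci
        others = frozenset(truth.frame["locus_id"]) - core
        rate_core = np.mean([1 if "T000" in ann.assignments.get(g, ()) else 0
                             for g in core])
        rate_other = np.mean([1 if "T000" in ann.assignments.get(g, ()) else 0
                              for g in others])
        assert rate_core == pytest.approx(0.5, abs=0.05)
        assert rate_other == pytest.approx(0.1, abs=0.02)

    def test_zero_terms_empty_map_breaks_downstream(self):
        from coredeg.coreset import Universe
        from coredeg.enrichment import ReferenceSet, term_enrichment
        from coredeg.errors import ValidationError

        _, _, truth = simulate_dual_contrast(SimParams(n_genes=100, seed=1))
        ann = simulate_annotation(truth, n_terms=0, enrich_terms=0, seed=1)
        assert ann.assignments == {}
        ref = ReferenceSet(frozenset(truth.frame["locus_id"]), seed=0)
        with pytest.raises(ValidationError):
            term_enrichment(truth.core_loci, ref, ann)

    def test_rate_clamped(self, caplog):
        import logging

        _, _, truth = simulate_dual_contrast(SimParams(n_genes=200, seed=1))
        with caplog.at_level(logging.WARNING, logger="coredeg.simulate"):
            simulate_annotation(truth, n_terms=2, enrich_terms=1,
                                enrich_factor=30.0, base_rate=0.1, seed=1)
        assert any("clamp" in r.message for r in caplog.records)

    def test_determinism(self):
        _, _, truth = simulate_dual_contrast(SimParams(n_genes=300, seed=5))
        a = simulate_annotation(truth, seed=7)
        b = simulate_annotation(truth, seed=7)
        assert a.assignments == b.assignments


def test_null_fidelity_mean_overlap():
    """With f_core = 0 the mean observed r tracks the k1*k2/(2N) null mean."""
    params = SimParams(n_genes=4000, f_core=0.0, seed=0)
    rs, exps = [], []
    for s in simulate.replicate_seeds(100, 200):
        t1, t2, _ = simulate_dual_contrast(replace(params, seed=int(s)))
        N, k1, k2, r = coreset.overlap_counts(t1, t2, params.alpha)
        rs.append(r)
        exps.append(k1 * k2 / (2 * N))
    rs = np.asarray(rs, dtype=float)
    se = rs.std(ddof=1) / np.sqrt(len(rs))
    assert abs(rs.mean() - np.mean(exps)) <= 3 * se


def test_power_monotone_in_effect_size():
    """Core recall never decreases as the planted effect grows."""
    recalls = []
    for effect in (1.0, 2.0, 4.0):
        batch = []
        for s in simulate.replicate_seeds(5, 5):
            params = SimParams(n_genes=3000, effect_mean=effect, seed=int(s))
            t1, t2, truth = simulate_dual_contrast(params)
            u = coreset.build_universe(t1, t2)
            part = coreset.venn_partition(
                coreset.call_directions(t1, params.alpha),
                coreset.call_directions(t2, params.alpha), u)
            m = evaluate_recovery(coreset.extract_core_set(part), truth)
            batch.append(m.recall)
        recalls.append(np.mean(batch))
    assert recalls[0] <= recalls[1] + 1e-9
    assert recalls[1] <= recalls[2] + 1e-9


def test_bh_false_discovery_proportion_controlled():
    """Realized per-contrast FDP among q <= 0.05 calls averages <= 0.07."""
    fdps = []
    for s in simulate.replicate_seeds(17, 200):
        t1, _, truth = simulate_dual_contrast(
            replace(SimParams(), seed=int(s)))
        truly_de = (truth.frame["dir1"] != "none").to_numpy()
        d = t1.data
        called = ((d["status"] == io.TESTED) & (d["q_value"] <= 0.05)
                  & (d["log2_fold_change"] != 0)).to_numpy()
        if called.sum():
            fdps.append((called & ~truly_de).sum() / called.sum())
    assert np.mean(fdps) <= 0.07


class TestNullCalibration:
    def test_requires_null_params(self):
        with pytest.raises(DomainError):
            null_calibration(SimParams(f_core=0.01), n_reps=100)

    def test_requires_enough_reps(self):
        with pytest.raises(DomainError):
            null_calibration(SimParams(f_core=0.0), n_reps=10)

    def test_alpha_one_rejects_everything(self):
        res = null_calibration(SimParams(n_genes=400, f_core=0.0, seed=1),
                               n_reps=100, alpha=1.0, seed=2)
        assert res.rate == 1.0

    def test_interval_brackets_point_estimate(self):
        res = null_calibration(SimParams(n_genes=1000, f_core=0.0, seed=1),
                               n_reps=150, seed=3)
        assert res.ci_low <= res.rate <= res.ci_high
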
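"""Normalisation, FPKM, dispersion estimation and the NB Wald contrast."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import hifmimic as hm
from hifmimic.diffexp import (
    bh_adjust,
    call_regulated,
    compute_fpkm,
    estimate_dispersions,
    estimate_size_factors,
    log_expression,
    nb_contrast_test,
)
from hifmimic.simdata import null_preset

from conftest import make_counts


def two_group_table(n_per_group, conditions=("normoxia", "hypoxia")):
    rows = [
        {"sample": f"{c}_{r+1}", "condition": c, "replicate": r + 1}
        for c in conditions
        for r in range(n_per_group)
    ]
    return hm.SampleTable(pd.DataFrame(rows))


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        cm = make_counts([[5, 5, 5], [9, 9, 9], [2, 2, 2]])
        s = estimate_size_factors(cm).size_factors
        assert np.allclose(s, 1.0)

    def test_hand_computed_two_sample_case(self):
        cm = make_counts([[2, 4], [4, 8], [6, 12]])
        s = estimate_size_factors(cm).size_factors
        assert np.allclose(s, [0.7071067811865476, 1.4142135623730951])

    def test_scaling_one_column_scales_its_factor(self):
        base = make_counts([[10, 10], [20, 20], [7, 7], [100, 100]])
        scaled = make_counts([[10, 40], [20, 80], [7, 28], [100, 400]])
        s0 = estimate_size_factors(base).size_factors
        s1 = estimate_size_factors(scaled).size_factors
        assert s1.iloc[1] / s1.iloc[0] == pytest.approx(4 * s0.iloc[1] / s0.iloc[0])

    def test_invariant_to_gene_and_sample_permutation(self, rng):
        x = rng.poisson(50, size=(40, 5)) + 1
        cm = make_counts(x)
        gperm = rng.permutation(40)
        sperm = rng.permutation(5)
        cm_p = hm.CountMatrix(cm.counts.iloc[gperm, sperm])
        s = estimate_size_factors(cm).size_factors
        s_p = estimate_size_factors(cm_p).size_factors
        assert np.allclose(s_p.to_numpy(), s.iloc[sperm].to_numpy())

    def test_no_common_positive_gene_fails(self):
        cm = make_counts([[3, 0], [0, 4]])
        with pytest.raises(ValueError, match="no gene"):
            estimate_size_factors(cm)


class TestFpkm:
    def test_formula_identity(self):
        cm = make_counts([[10]], lengths=[1000])
        fpkm = compute_fpkm(cm, mapped_totals={"s0": 1e6})
        assert fpkm.values.iloc[0, 0] == pytest.approx(10.0)

    def test_doubling_length_halves_fpkm(self):
        a = compute_fpkm(make_counts([[10]], lengths=[1000]), {"s0": 1e6})
        b = compute_fpkm(make_counts([[10]], lengths=[2000]), {"s0": 1e6})
        assert b.values.iloc[0, 0] == pytest.approx(a.values.iloc[0, 0] / 2)

    def test_small_matrix_matches_direct_evaluation(self):
        cm = make_counts([[3, 7], [11, 2]], lengths=[500, 2500])
        totals = {"s0": 2e5, "s1": 3e5}
        fpkm = compute_fpkm(cm, totals).values.to_numpy()
        expected = np.array(
            [[3 * 1e9 / (500 * 2e5), 7 * 1e9 / (500 * 3e5)],
             [11 * 1e9 / (2500 * 2e5), 2 * 1e9 / (2500 * 3e5)]]
        )
        assert np.allclose(fpkm, expected)

    def test_all_zero_gene_has_zero_fpkm_everywhere(self):
        cm = make_counts([[0, 0], [5, 8]], lengths=[1000, 1000])
        fpkm = compute_fpkm(cm)
        assert (fpkm.values.iloc[0] == 0).all()

    def test_missing_lengths_rejected(self):
        with pytest.raises(ValueError, match="lengths"):
            compute_fpkm(make_counts([[1]]))

    def test_log_transform_tags_unit(self):
        cm = make_counts([[10]], lengths=[1000])
        le = log_expression(compute_fpkm(cm, {"s0": 1e6}), pseudocount=1.0)
        assert le.unit == "log2(FPKM+1)"
        assert le.values.iloc[0, 0] == pytest.approx(np.log2(11.0))


class TestDispersions:
    def _estimate_single(self, counts_row, n, alpha_kwargs=None):
        samples = two_group_table(n, conditions=("normoxia",))
        cm = make_counts([counts_row], samples=samples.sample_ids.tolist())
        norm = hm.NormalizationResult(
            pd.Series(1.0, index=cm.sample_ids), method="unit"
        )
        return estimate_dispersions(
            cm, norm, samples, **(alpha_kwargs or {"genewise_weight": 1.0})
        ).iloc[0]

    def test_poisson_gene_hits_floor(self, rng):
        # high mean keeps the moment-estimator noise well below the floor,
        # so the (variance - mean) numerator clamps to alpha_floor
        row = rng.poisson(10000, size=400)
        assert self._estimate_single(row, 400) == pytest.approx(1e-4)

    def test_nb_gene_recovers_dispersion(self, rng):
        mu, alpha = 200.0, 0.2
        r = 1 / alpha
        row = rng.negative_binomial(r, r / (r + mu), size=200)
        est = self._estimate_single(row, 200)
        assert 0.1 <= est <= 0.3

    def test_constant_gene_hits_floor_without_failure(self):
        assert self._estimate_single([7] * 6, 6) == pytest.approx(1e-4)

    def test_sharing_never_drops_below_global(self, default_experiment):
        _, counts, samples, _ = default_experiment
        norm = estimate_size_factors(counts)
        raw = estimate_dispersions(counts, norm, samples, genewise_weight=1.0)
        shared = estimate_dispersions(counts, norm, samples, genewise_weight=0.3)
        from scipy.stats import trim_mean
        global_alpha = trim_mean(raw, 0.01)
        assert (shared >= global_alpha - 1e-12).all()

    def test_requires_replication(self):
        cm = make_counts([[5, 6]])
        samples = hm.SampleTable(pd.DataFrame(
            {"sample": ["s0", "s1"], "condition": ["a", "b"], "replicate": [1, 1]}
        ))
        norm = hm.NormalizationResult(pd.Series(1.0, index=cm.sample_ids), "unit")
        with pytest.raises(ValueError, match="replicates"):
            estimate_dispersions(cm, norm, samples)


class TestContrast:
    def _setup(self, x, n):
        samples = two_group_table(n)
        cm = make_counts(x, samples=samples.sample_ids.tolist())
        norm = estimate_size_factors(cm)
        alpha = pd.Series(0.05, index=cm.gene_ids)
        return cm, samples, norm, alpha

    def test_identical_groups_give_zero_lfc_and_p_one(self, rng):
        half = rng.poisson(100, size=(20, 3))
        x = np.concatenate([half, half], axis=1)
        cm, samples, norm, alpha = self._setup(x, 3)
        de = nb_contrast_test(cm, norm, alpha, samples, "hypoxia")
        assert (de["log2FC"] == 0).all()
        assert (de["pvalue"] == 1.0).all()

    def test_swapping_groups_negates_lfc_keeps_p(self, rng):
        x = rng.poisson(80, size=(30, 6))
        cm, samples, norm, alpha = self._setup(x, 3)
        fwd = nb_contrast_test(cm, norm, alpha, samples, "hypoxia", reference="normoxia")
        rev = nb_contrast_test(cm, norm, alpha, samples, "normoxia", reference="hypoxia")
        assert np.allclose(fwd["log2FC"], -rev["log2FC"])
        assert np.allclose(fwd["pvalue"], rev["pvalue"])

    def test_unknown_condition_rejected(self, rng):
        cm, samples, norm, alpha = self._setup(rng.poisson(80, size=(5, 6)), 3)
        with pytest.raises(KeyError):
            nb_contrast_test(cm, norm, alpha, samples, "nonsense")

    def test_null_type_one_error_calibrated(self):
        cfg = null_preset(seed=12)
        counts, samples, _ = hm.simulate_experiment(cfg)
        de = hm.de_analysis(counts, samples)["hypoxia"]
        frac = (de["pvalue"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_stepup_case(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @staticmethod
    def brute_force_bh(p):
        """Step-up definition computed directly: q_(i) = min over j >= i of
        min(1, m * p_(j) / j)."""
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        q_sorted = np.minimum.accumulate(
            (m * p[order] / np.arange(1, m + 1))[::-1]
        )[::-1]
        q = np.empty(m)
        q[order] = np.minimum(q_sorted, 1.0)
        return q

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
    def test_matches_stepup_definition(self, p):
        assert np.allclose(bh_adjust(p), self.brute_force_bh(p))

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=40))
    def test_min_q_at_least_min_p(self, p):
        assert bh_adjust(p).min() >= np.min(p) - 1e-15


class TestCallRegulated:
    def _de(self):
        return pd.DataFrame(
            {
                "log2FC": [np.log2(2.5), np.log2(3.0), np.log2(1.9), -np.log2(4.0)],
                "qvalue": [0.04, 0.06, 0.01, 0.001],
                "condition": "hypoxia",
            },
            index=["passes", "fails_fdr", "fails_fc", "down"],
        )

    def test_gate_combinations(self):
        up = call_regulated(self._de(), direction="up")
        assert set(up.genes) == {"passes"}
        down = call_regulated(self._de(), direction="down")
        assert set(down.genes) == {"down"}
        both = call_regulated(self._de(), direction="both")
        assert set(both.genes) == {"passes", "down"}

    def test_invalid_direction_rejected(self):
        with pytest.raises(ValueError, match="direction"):
            call_regulated(self._de(), direction="sideways")


class TestRecoveryOnDefaultPreset:
    def test_recall_and_fdr(self, default_experiment, default_de):
        _, _, _, truth = default_experiment
        tp = fp = pos = calls = 0
        for cond, tab in default_de.items():
            true_eff = truth.effects[cond]
            positives = true_eff.abs() >= 1.0
            called = tab["significant"]
            pos += positives.sum()
            tp += (called & positives).sum()
            fp += (called & (true_eff == 0)).sum()
            calls += called.sum()
        assert tp / pos >= 0.9
        assert fp / calls <= 0.1
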
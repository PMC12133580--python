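"""KDE density, the leave-one-out classifier, MCC and the DE routes."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rareaml import (
    DEThresholds,
    DifferentialExpressionModel,
    classic_test,
    kde_density,
    kernel_mcc,
    log2_fold_change,
    loo_kde_classify,
    mcc,
)
from rareaml._errors import DimensionError, InsufficientDataError
from rareaml.kernelmcc import silverman_bandwidth

from ._oracles import oracle_loo_kde_classify


class TestKDEDensity:
    def test_mass_concentrates_at_data_with_floor_bandwidth(self):
        d0 = kde_density([0.0, 0.0, 0.0, 0.0], 0.0)
        d10 = kde_density([0.0, 0.0, 0.0, 0.0], 10.0)
        assert d0 > 1e4 * max(d10, 1e-300)

    def test_symmetric_pair_matches_closed_form(self):
        values = [-1.0, 1.0]
        h = silverman_bandwidth(np.array(values))
        expected = 2.0 / (2.0 * h * math.sqrt(2 * math.pi)) * math.exp(-1.0 / (2 * h * h))
        assert kde_density(values, 0.0) == pytest.approx(expected, rel=1e-12)

    def test_integrates_to_one(self, rng):
        from scipy.integrate import quad

        values = rng.normal(2.0, 1.5, size=25)
        total, _ = quad(lambda q: kde_density(values, q), -30, 30, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(shift=st.floats(-50, 50, allow_nan=False))
    def test_translation_equivariance(self, shift):
        values = np.array([0.3, -1.2, 2.4, 0.9, -0.5])
        assert kde_density(values + shift, 1.0 + shift) == pytest.approx(
            kde_density(values, 1.0), rel=1e-9
        )

    def test_rejects_single_point(self):
        with pytest.raises(InsufficientDataError):
            kde_density([1.0], 0.0)


class TestLOOClassifier:
    def test_perfect_separation_reproduces_labels(self):
        v = np.array([0.0, 0.1, -0.1, 0.05, 10.0, 10.1, 9.9])
        lab = np.array([0, 0, 0, 0, 1, 1, 1], dtype=bool)
        assert np.array_equal(loo_kde_classify(v, lab), lab)

    def test_constant_data_predicts_reference_everywhere(self):
        v = np.full(10, 5.0)
        lab = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0], dtype=bool)
        assert not loo_kde_classify(v, lab).any()

    def test_matches_bruteforce_on_interleaved_toy(self):
        v = np.array([0.1, 1.0, 0.4, 2.0, 0.7, 1.4, 0.2, 1.8, 0.9, 1.1])
        lab = np.array([1, 0, 1, 0, 1, 0, 0, 0, 0, 0], dtype=bool)
        assert np.array_equal(loo_kde_classify(v, lab), oracle_loo_kde_classify(v, lab))

    def test_small_class_rejected(self):
        with pytest.raises(InsufficientDataError):
            loo_kde_classify(np.arange(8.0), np.array([1, 1, 0, 0, 0, 0, 0, 0], dtype=bool))


class TestMCC:
    def test_perfect_and_inverted_predictions(self):
        a = np.array([1, 1, 0, 0, 1], dtype=bool)
        assert mcc(a, a) == 1.0
        assert mcc(~a, a) == -1.0

    def test_hand_computed_confusion(self):
        # TP=2, TN=5, FP=2, FN=1 -> 8/sqrt(504)
        pred = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0], dtype=bool)
        act = np.array([1, 1, 0, 0, 1, 0, 0, 0, 0, 0], dtype=bool)
        assert mcc(pred, act) == pytest.approx(8.0 / math.sqrt(504.0), rel=1e-12)

    def test_degenerate_confusion_returns_zero(self):
        assert mcc([1, 1, 1], [1, 0, 1]) == 0.0

    def test_matches_sklearn_on_random_vectors(self, rng):
        sk = pytest.importorskip("sklearn.metrics")
        for _ in range(50):
            n = int(rng.integers(2, 40))
            pred = rng.integers(0, 2, n).astype(bool)
            act = rng.integers(0, 2, n).astype(bool)
            assert mcc(pred, act) == pytest.approx(
                sk.matthews_corrcoef(act, pred), abs=1e-12
            )

    def test_invariant_under_simultaneous_label_swap(self, rng):
        pred = rng.integers(0, 2, 30).astype(bool)
        act = rng.integers(0, 2, 30).astype(bool)
        assert mcc(pred, act) == pytest.approx(mcc(~pred, ~act), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(DimensionError):
            mcc([1, 0], [1, 0, 1])


class TestKernelMCC:
    def test_wide_gap_gives_one(self):
        v = np.r_[np.linspace(0, 1, 20), np.linspace(100, 101, 5)]
        lab = np.r_[np.zeros(20, bool), np.ones(5, bool)]
        assert kernel_mcc(v, lab) == 1.0

    def test_permutation_null_centers_at_zero(self, rng):
        v = rng.normal(0, 1, 30)
        vals = []
        for _ in range(200):
            lab = np.zeros(30, bool)
            lab[rng.choice(30, 6, replace=False)] = True
            vals.append(kernel_mcc(v, lab))
        assert abs(float(np.mean(vals))) < 0.05

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(20):
            v = rng.normal(0, 1, 16)
            lab = np.zeros(16, bool)
            lab[:5] = True
            assert -1.0 <= kernel_mcc(v, lab) <= 1.0

    def test_monotone_power_in_effect_size(self):
        effects = [0.0, 0.5, 1.0, 1.5, 2.0]
        means = []
        for effect in effects:
            vals = []
            for seed in range(50):
                r = np.random.default_rng(seed)
                v = np.r_[r.normal(0, 0.5, 60), r.normal(effect, 0.5, 7)]
                lab = np.r_[np.zeros(60, bool), np.ones(7, bool)]
                vals.append(kernel_mcc(v, lab))
            means.append(float(np.mean(vals)))
        assert all(b >= a - 1e-12 for a, b in zip(means, means[1:]))


class TestFoldChangeAndClassicTest:
    def test_l2fc_is_mean_difference(self):
        v = np.array([2.0, 2.0, 2.0, 8.0, 8.0])
        lab = np.array([0, 0, 0, 1, 1], dtype=bool)
        assert log2_fold_change(v, lab) == 6.0
        assert log2_fold_change(v, ~lab) == -6.0

    def test_identical_groups_give_zero_l2fc_and_p_one(self):
        v = np.array([3.0, 3.0, 3.0, 3.0])
        lab = np.array([0, 0, 1, 1], dtype=bool)
        assert log2_fold_change(v, lab) == 0.0
        assert classic_test(v, lab) == 1.0

    def test_strong_separation_is_significant(self, rng):
        v = np.r_[rng.normal(0, 1, 10), rng.normal(5, 1, 10)]
        lab = np.r_[np.zeros(10, bool), np.ones(10, bool)]
        assert classic_test(v, lab) < 1e-6

    def test_type_one_error_calibrated(self):
        r = np.random.default_rng(123)
        hits = 0
        n_genes = 1000
        for _ in range(n_genes):
            v = r.normal(0, 1, 20)
            lab = np.r_[np.zeros(13, bool), np.ones(7, bool)]
            hits += classic_test(v, lab) < 0.05
        assert abs(hits / n_genes - 0.05) < 0.015

    def test_zero_variance_unequal_means_is_significant(self):
        v = np.array([1.0, 1.0, 2.0, 2.0])
        lab = np.array([0, 0, 1, 1], dtype=bool)
        assert classic_test(v, lab) < 1e-12


class TestDifferentialExpressionModel:
    def test_tiny_frame_pass_flags_and_directions(self, tiny_de_frame):
        values, groups = tiny_de_frame
        res = DifferentialExpressionModel(values, groups).fit(route="both")
        t = res.table.set_index("gene_id")
        assert bool(t.loc["up1", "passes_kmcc"]) and t.loc["up1", "direction"] == "up"
        assert bool(t.loc["down1", "passes_kmcc"]) and t.loc["down1", "direction"] == "down"
        assert not t.loc[["null1", "null2"], "passes_kmcc"].any()
        assert res.n_pass == 2 and res.n_up == 1 and res.n_down == 1

    def test_pass_set_equals_bruteforce_threshold_filter(self, tiny_de_frame):
        values, groups = tiny_de_frame
        thr = DEThresholds()
        res = DifferentialExpressionModel(values, groups, thr).fit(route="both")
        t = res.table
        brute = set()
        for _, row in t.iterrows():
            if row["kernel_mcc"] > thr.mcc_threshold and abs(row["l2fc"]) > thr.l2fc_threshold:
                brute.add(row["gene_id"])
        assert res.pass_genes("kmcc") == brute

    def test_table_sorted_by_abs_l2fc_with_gene_tiebreak(self, tiny_de_frame):
        values, groups = tiny_de_frame
        res = DifferentialExpressionModel(values, groups).fit(route="classic")
        a = np.abs(res.table["l2fc"].to_numpy())
        assert all(a[i] >= a[i + 1] - 1e-12 for i in range(len(a) - 1))

    def test_lazy_kmcc_preserves_pass_flags(self, tiny_de_frame):
        values, groups = tiny_de_frame
        model = DifferentialExpressionModel(values, groups)
        eager = model.fit(route="kmcc")
        lazy = model.fit(route="kmcc", lazy_kmcc=True)
        pd.testing.assert_series_equal(eager.table["passes_kmcc"], lazy.table["passes_kmcc"])

    def test_missing_values_rejected(self, tiny_de_frame):
        values, groups = tiny_de_frame
        values = values.copy()
        values.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            DifferentialExpressionModel(values, groups)

    def test_threshold_gate_invariant(self, small_config):
        from rareaml import simulate_expression

        data, _ = simulate_expression(small_config)
        res = DifferentialExpressionModel(data.values, data.groups).fit(route="both")
        t = res.table[res.table["passes_kmcc"]]
        assert (t["kernel_mcc"] > 0.105).all()
        assert (t["l2fc"].abs() > 0.58).all()

    def test_summary_mentions_counts(self, tiny_de_frame):
        values, groups = tiny_de_frame
        res = DifferentialExpressionModel(values, groups).fit()
        assert "pass: 2" in res.summary()
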
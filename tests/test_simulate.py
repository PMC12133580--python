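"""Ground-truth consistency and determinism of the synthetic generators."""

import numpy as np
import pandas as pd
import pytest

from rareaml import (
    SimConfig,
    build_promoters,
    fit_4pl,
    simulate_annotation,
    simulate_dose_response,
    simulate_expression,
    simulate_peaks,
    simulate_qpcr,
    simulate_treatment,
)
from rareaml._errors import SimConfigError

from ._oracles import oracle_interval_assignment


class TestSimConfig:
    def test_spike_overflow_names_bound(self):
        with pytest.raises(SimConfigError, match="n_genes"):
            SimConfig(n_genes=10, n_up_spiked=8, n_down_spiked=8,
                      n_bound_genes=5, n_bound_and_de=2, n_rewired=5)

    def test_rewired_bounded_by_up_spiked(self):
        with pytest.raises(SimConfigError, match="n_rewired"):
            SimConfig(n_up_spiked=5, n_down_spiked=0, n_rewired=6,
                      n_bound_genes=5, n_bound_and_de=2)

    def test_selective_bounded_by_drugs(self):
        with pytest.raises(SimConfigError, match="n_selective_drugs"):
            SimConfig(n_drugs=3, n_selective_drugs=4)

    def test_negative_count_rejected(self):
        with pytest.raises(SimConfigError, match=">= 0"):
            SimConfig(n_genes=-1)


class TestExpression:
    def test_null_design_has_no_true_effects(self):
        cfg = SimConfig(seed=1, n_genes=50, n_samples_reference=20, n_samples_group=5,
                        n_up_spiked=0, n_down_spiked=0, effect_l2fc_mean=0.0,
                        n_rewired=0, n_bound_genes=10, n_bound_and_de=0)
        _, truth = simulate_expression(cfg)
        assert all(v == 0.0 for v in truth.true_l2fc.values())

    def test_equal_seeds_bit_identical(self, small_config):
        a, _ = simulate_expression(small_config)
        b, _ = simulate_expression(small_config)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_different_seeds_differ(self, small_config):
        import dataclasses

        other = dataclasses.replace(small_config, seed=small_config.seed + 1)
        a, _ = simulate_expression(small_config)
        b, _ = simulate_expression(other)
        assert not a.values.equals(b.values)

    def test_spiked_group_means_recover_effect(self):
        cfg = SimConfig(seed=3, n_genes=2000, n_up_spiked=104, n_down_spiked=62,
                        effect_l2fc_mean=1.5, effect_l2fc_sd=0.0, noise_sd=0.5)
        data, truth = simulate_expression(cfg)
        case = data.values.loc[:, data.groups == "case"]
        ref = data.values.loc[:, data.groups == "reference"]
        obs = (case.mean(axis=1) - ref.mean(axis=1)).loc[sorted(truth.spiked_up)]
        # SE of the mean of 104 spiked-gene l2fcs at noise 0.5, 7-vs-741 samples
        se = 0.5 * np.sqrt(1 / 7 + 1 / 741) / np.sqrt(104)
        assert abs(obs.mean() - 1.5) < 3 * se

    def test_truth_sets_consistent(self, small_config):
        _, truth = simulate_expression(small_config)
        assert truth.rewired_genes <= truth.spiked_up
        assert not (truth.spiked_up & truth.spiked_down)
        assert truth.bound_and_de_genes <= truth.bound_genes
        assert len(truth.spiked_up) == small_config.n_up_spiked
        assert len(truth.bound_genes) == small_config.n_bound_genes


class TestDoseResponse:
    def test_inactive_drug_has_zero_true_dss(self):
        cfg = SimConfig(seed=2, n_drugs=5, n_selective_drugs=0,
                        n_screen_case=2, n_screen_reference=3,
                        response_noise_sd_pct=0.0)
        plate, truth = simulate_dose_response(cfg)
        # drugs generated with top asymptote near zero score near zero
        tops = plate.groupby("drug_id")["response_pct"].max()
        for drug, top in tops.items():
            if top < 5.0:
                assert truth.true_dss[(drug, "reference")] < 2.0

    def test_selective_drug_has_group_dss_gap(self):
        cfg = SimConfig(seed=2, n_drugs=10, n_selective_drugs=2,
                        n_screen_case=2, n_screen_reference=3,
                        response_noise_sd_pct=0.0)
        _, truth = simulate_dose_response(cfg)
        for drug in truth.selective_drugs:
            assert truth.true_dss[(drug, "case")] > truth.true_dss[(drug, "reference")]

    def test_noise_free_curves_refit_to_generating_parameters(self):
        cfg = SimConfig(seed=4, n_drugs=6, n_selective_drugs=1,
                        n_screen_case=1, n_screen_reference=2,
                        response_noise_sd_pct=0.0)
        plate, truth = simulate_dose_response(cfg)
        for (drug, sample), g in plate.groupby(["drug_id", "sample_id"]):
            fit = fit_4pl(g["dose_nM"].to_numpy(), g["response_pct"].to_numpy())
            group = "case" if sample.startswith("scase") else "reference"
            from rareaml.drugscreen import dss_from_fit

            refit_dss = dss_from_fit(fit, cfg.dose_min_nM, cfg.dose_max_nM)
            assert refit_dss == pytest.approx(truth.true_dss[(drug, group)], abs=1e-3)

    def test_plate_determinism(self):
        cfg = SimConfig(seed=9, n_drugs=4, n_screen_case=2, n_screen_reference=3,
                        n_selective_drugs=1)
        a, _ = simulate_dose_response(cfg)
        b, _ = simulate_dose_response(cfg)
        pd.testing.assert_frame_equal(a, b)


class TestPeaks:
    def _promoters(self, cfg):
        return build_promoters(simulate_annotation(cfg))

    def test_bound_genes_have_promoter_peak_by_bruteforce(self, small_config):
        promoters = self._promoters(small_config)
        tracks, truth = simulate_peaks(small_config, promoters)
        bound = oracle_interval_assignment(tracks["antibody_dmso"], promoters)
        assert truth.bound_genes <= bound

    def test_igg_tracks_never_touch_promoters(self, small_config):
        promoters = self._promoters(small_config)
        tracks, _ = simulate_peaks(small_config, promoters)
        for track in ("igg_dmso", "igg_treated"):
            assert oracle_interval_assignment(tracks[track], promoters) == set()

    def test_rewired_bound_genes_lose_peak_on_treatment(self, small_config):
        promoters = self._promoters(small_config)
        tracks, truth = simulate_peaks(small_config, promoters)
        after = oracle_interval_assignment(tracks["antibody_treated"], promoters)
        lost = truth.bound_genes - after
        assert lost == truth.bound_genes & truth.rewired_genes

    def test_zero_bound_genes_gives_background_only(self):
        cfg = SimConfig(seed=5, n_genes=50, n_up_spiked=5, n_down_spiked=5,
                        n_rewired=2, n_bound_genes=0, n_bound_and_de=0,
                        n_background_peaks=10)
        promoters = self._promoters(cfg)
        tracks, _ = simulate_peaks(cfg, promoters)
        assert oracle_interval_assignment(tracks["antibody_dmso"], promoters) == set()

    def test_more_bound_than_promoters_rejected(self, small_config):
        promoters = self._promoters(small_config).iloc[:10]
        with pytest.raises(SimConfigError, match="promoters"):
            simulate_peaks(small_config, promoters)


class TestTreatment:
    def test_rewired_genes_drop_only_in_case_inhibitor(self):
        cfg = SimConfig(seed=6, n_genes=300, n_up_spiked=30, n_down_spiked=10,
                        n_rewired=12, n_bound_genes=50, n_bound_and_de=6,
                        noise_sd=0.0, effect_l2fc_sd=0.0)
        comparisons, truth = simulate_treatment(cfg)
        for name, data in comparisons.items():
            treated = data.values.loc[:, data.groups == "case"].mean(axis=1)
            dmso = data.values.loc[:, data.groups == "reference"].mean(axis=1)
            delta = (treated - dmso).loc[sorted(truth.rewired_genes)]
            if name == "case_inhibitor":
                assert np.allclose(delta, -1.5)
            else:
                assert np.allclose(delta, 0.0)

    def test_replicate_column_count(self, small_config):
        comparisons, _ = simulate_treatment(small_config)
        data = comparisons["case_inhibitor"]
        expected = 2 * small_config.n_treated_per_cohort * small_config.replicates_per_condition
        assert data.values.shape[1] == expected


class TestQpcr:
    def test_encoded_knockdown_shifts_target_ct(self):
        cfg = SimConfig(seed=8, ct_noise_sd=0.0)
        expr_ct, _, _ = simulate_qpcr(cfg, knockdown_efficiency=0.5)
        m = expr_ct.groupby(["condition", "target_id"])["ct"].mean()
        assert m[("knockdown", "TARGET")] - m[("scramble", "TARGET")] == pytest.approx(1.0)

    def test_encoded_fold_enrichment_in_ct_gap(self):
        cfg = SimConfig(seed=8, ct_noise_sd=0.0)
        _, enrich_ct, _ = simulate_qpcr(cfg, fold_enrichments={"case_antibody": 4.0})
        m = enrich_ct.groupby(["condition", "target_id"])["ct"].mean()
        assert m[("case_igg", "locus_1")] - m[("case_antibody", "locus_1")] == pytest.approx(2.0)

    def test_determinism(self, small_config):
        a = simulate_qpcr(small_config)[0]
        b = simulate_qpcr(small_config)[0]
        pd.testing.assert_frame_equal(a, b)
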
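"""Summation models, phase/latency conversion, RM-ANOVA and model selection."""

import numpy as np
import pytest

from melsum.summation import (
    SummationDataset,
    classify_summation,
    db_to_index,
    fit_global_summation,
    fit_probability_summation,
    latency_to_phase,
    phase_to_latency,
    rm_anova_oneway,
    summation_index_db,
    summation_square,
    tr_probability,
    tr_vector,
)

PHASES = np.array([0.0, 30.0, 60.0, 90.0, 120.0])


def make_datasets(model, rng, noise=0.05, n_obs=3, n_rep=3, **params):
    """TR-level synthetic studies with SEM-scale multiplicative noise."""
    datasets = []
    for o in range(n_obs):
        if model == "linear":
            tr_true = tr_vector(PHASES, params["x"], params["y"], params["phi"])
        else:
            tr_true = tr_probability(params["n"], PHASES)
        matrix = tr_true[:, None] * np.exp(rng.normal(0.0, noise, (PHASES.size, n_rep)))
        datasets.append(SummationDataset.from_matrix(f"O{o + 1}", PHASES, matrix))
    return datasets


class TestClosedForms:
    def test_probability_tr_is_phase_flat(self):
        tr = tr_probability(0.5, PHASES)
        np.testing.assert_allclose(tr, 0.5)

    def test_db_conversion(self):
        assert summation_index_db(1.0) == 0.0
        assert summation_index_db(0.9) == pytest.approx(0.915, abs=1e-3)
        assert db_to_index(summation_index_db(0.73)) == pytest.approx(0.73)

    def test_vector_tr_extremes_at_table_sensitivities(self):
        # x = 1, y = 0.2: destructive interference 1/(1 - 0.2), constructive 1/1.2
        assert tr_vector(30.4, 1.0, 0.2, 30.4) == pytest.approx(1.25)
        assert tr_vector(210.4, 1.0, 0.2, 30.4) == pytest.approx(1 / 1.2)

    def test_single_pathway_reduces_to_constant(self):
        tr = tr_vector(PHASES, 1.0, 0.0, 45.0)
        np.testing.assert_allclose(tr, 1.0)
        np.testing.assert_allclose(tr_vector(PHASES, 0.8, 0.0, 0.0),
                                   tr_probability(1 / 0.8, PHASES))

    def test_periodic_and_symmetric_about_phi(self):
        phi = 37.0
        grid = np.linspace(-180, 540, 121)
        tr = tr_vector(grid, 1.0, 0.4, phi)
        np.testing.assert_allclose(tr, tr_vector(grid + 360.0, 1.0, 0.4, phi))
        d = np.linspace(0, 180, 50)
        np.testing.assert_allclose(
            tr_vector(phi + d, 1.0, 0.4, phi), tr_vector(phi - d, 1.0, 0.4, phi)
        )

    def test_exact_cancellation_returns_infinity(self):
        assert np.isinf(tr_vector(30.0, 0.7, 0.7, 30.0))

    def test_squared_denominator_variant(self):
        v_sqrt = tr_vector(90.0, 1.0, 0.3, 0.0, sqrt_form=True)
        v_sq = tr_vector(90.0, 1.0, 0.3, 0.0, sqrt_form=False)
        assert v_sq == pytest.approx(v_sqrt**2)


class TestPhaseLatency:
    def test_published_phase_to_latency_values(self):
        assert phase_to_latency(45.7, 1.0) == pytest.approx(126.9, abs=0.1)
        assert phase_to_latency(30.4, 1.0) == pytest.approx(84.4, abs=0.1)
        assert phase_to_latency(360.0, 1.0) == pytest.approx(1000.0)

    def test_latency_round_trip(self):
        # rod-melanopsin latency gap of 250 - 80 = 170 ms at 1 Hz
        assert latency_to_phase(170.0, 1.0) == pytest.approx(61.2)
        assert phase_to_latency(latency_to_phase(93.0, 2.0), 2.0) == pytest.approx(93.0)


class TestGlobalFit:
    def test_phase_recovery_at_table_effect_sizes(self, rng):
        datasets = make_datasets("linear", rng, x=1.0, y=0.2, phi=30.4)
        fit = fit_global_summation(datasets)
        assert fit.converged
        assert fit.phi_xy_deg == pytest.approx(30.4, abs=5.0)
        for x, y in fit.sensitivities.values():
            hi, lo = max(x, y), min(x, y)
            assert hi == pytest.approx(1.0, rel=0.15)
            assert lo == pytest.approx(0.2, abs=0.1)

    def test_single_observer_equals_global(self, rng):
        datasets = make_datasets("linear", rng, n_obs=1, x=1.0, y=0.3, phi=60.0)
        fit = fit_global_summation(datasets)
        assert fit.phi_xy_deg == pytest.approx(60.0, abs=8.0)

    def test_zero_second_sensitivity_matches_probability_fit(self):
        flat = np.full(PHASES.size, 0.8)
        ds = [SummationDataset("O1", PHASES, flat)]
        prob = fit_probability_summation(ds)
        assert prob.n["O1"] == pytest.approx(0.8)
        pred = tr_vector(PHASES, 1 / 0.8, 0.0, 0.0)
        np.testing.assert_allclose(pred, prob.predict("O1", PHASES))

    def test_latency_derived_from_shared_phase(self, rng):
        datasets = make_datasets("linear", rng, x=1.0, y=0.2, phi=45.7)
        fit = fit_global_summation(datasets)
        assert fit.latency_ms == pytest.approx(
            phase_to_latency(fit.phi_xy_deg, 1.0)
        )


class TestRMAnova:
    def test_matches_definitional_sums_of_squares(self, rng):
        m = rng.normal(0.0, 1.0, (5, 3))
        res = rm_anova_oneway(m, pairwise=False)
        grand = m.mean()
        ss_cond = m.shape[1] * np.sum((m.mean(axis=1) - grand) ** 2)
        ss_block = m.shape[0] * np.sum((m.mean(axis=0) - grand) ** 2)
        ss_err = np.sum((m - grand) ** 2) - ss_cond - ss_block
        F = (ss_cond / 4) / (ss_err / 8)
        assert res.ss_condition == pytest.approx(ss_cond, abs=1e-10)
        assert res.ss_error == pytest.approx(ss_err, abs=1e-10)
        assert res.F == pytest.approx(F, abs=1e-10)
        assert res.df == (4, 8)

    def test_identical_condition_means_give_zero_f(self):
        block_effects = np.array([0.0, 0.5, -0.2])
        m = np.tile(block_effects, (5, 1)) + 1.0
        m = m + np.random.default_rng(0).normal(0, 1e-9, m.shape)
        res = rm_anova_oneway(m, pairwise=False)
        assert res.F < 1e-3 or res.p > 0.99

    def test_mauchly_flagged_invalid_for_few_blocks(self, rng):
        res = rm_anova_oneway(rng.normal(0, 1, (5, 3)), pairwise=False)
        assert not res.mauchly_valid  # covariance singular with 3 blocks
        res_ok = rm_anova_oneway(rng.normal(0, 1, (3, 8)), pairwise=False)
        assert res_ok.mauchly_valid
        assert np.isfinite(res_ok.mauchly_w)

    def test_bonferroni_pairwise_table_size(self, rng):
        res = rm_anova_oneway(rng.normal(0, 1, (4, 6)))
        assert res.pairwise is not None
        assert len(res.pairwise) == 6  # 4 choose 2

    def test_missing_cells_rejected(self, rng):
        m = rng.normal(0, 1, (5, 3))
        m[0, 0] = np.nan
        with pytest.raises(ValueError):
            rm_anova_oneway(m)


class TestClassification:
    def test_phase_flat_data_classified_as_probability(self, rng):
        datasets = make_datasets("probability", rng, n=0.9)
        res = classify_summation(datasets)
        assert res.model == "probability"
        assert res.fit.n is not None

    def test_vector_data_classified_as_linear(self, rng):
        datasets = make_datasets("linear", rng, x=1.0, y=0.2, phi=30.4)
        res = classify_summation(datasets)
        assert res.model == "linear"
        assert res.fit.phi_xy_deg is not None

    def test_degenerate_variance_rejected(self):
        flat = np.ones((PHASES.size, 3))
        ds = [SummationDataset.from_matrix("O1", PHASES, flat)]
        with pytest.raises(ValueError):
            classify_summation(ds)


class TestSummationSquare:
    def test_inhibition_band_from_contrast_paradigm(self):
        # combined thresholds rising to 1.13-1.5 TU indicate inhibition
        for tu in (1.13, 1.3, 1.5):
            assert summation_square((tu, tu))["label"] == "inhibition"

    def test_on_initial_ratio_lines_no_interaction(self):
        assert summation_square((1.0, 1.0))["label"] == "no interaction"
        assert summation_square((1.2, 1.0), initial_ratio=(1.2, 1.0))["label"] == \
            "no interaction"

    def test_facilitation_below_unity(self):
        out = summation_square((0.8, 0.8))
        assert out["label"] == "facilitation"
        assert out["diagonal_deviation"] == pytest.approx(0.0)
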
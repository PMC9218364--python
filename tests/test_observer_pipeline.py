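"""Synthetic observer and the end-to-end analysis pipeline."""

import numpy as np
import pytest

from melsum.io import RunConfig, SchemaError, read_trials, run_pipeline, write_trials
from melsum.observer import (
    StudyDesign,
    default_sim_truth,
    generate_study,
    simulate_trials,
)
from melsum.psychometrics import FoSData
from pydantic import ValidationError


class TestSimulateTrials:
    def test_seed_reproducibility(self):
        design = StudyDesign()
        t1 = simulate_trials(9.9, 2.2, 0.03, design, np.random.default_rng(5))
        t2 = simulate_trials(9.9, 2.2, 0.03, design, np.random.default_rng(5))
        assert t1.equals(t2)

    def test_default_design_counts(self):
        design = StudyDesign()
        t = simulate_trials(9.9, 2.2, 0.03, design, np.random.default_rng(0))
        assert len(t) == 7 * (24 + 6)
        assert t["catch"].sum() == 7 * 6

    def test_catch_false_alarm_rate_converges(self):
        design = StudyDesign(trials_per_level=5, catch_per_level=2000,
                             level_spread=(1.0,))
        t = simulate_trials(10.0, 2.0, 0.08, design, np.random.default_rng(1))
        data = FoSData.from_trials(t)
        assert data.false_alarm_rate == pytest.approx(0.08, abs=0.02)


class TestGenerateStudy:
    def test_full_study_reproducible_and_shaped(self):
        truth = default_sim_truth(design=StudyDesign(
            observers=("O1",), illuminances_td=(200.0,),
            conditions=("i", "R", "i+R"),
        ))
        t1 = generate_study(truth, seed=3)
        t2 = generate_study(truth, seed=3)
        assert t1.equals(t2)
        # individual conditions carry no phase; combined span five phases
        assert t1.loc[t1["condition"] == "i", "phase_deg"].isna().all()
        phases = sorted(t1.loc[t1["condition"] == "i+R", "phase_deg"].unique())
        assert phases == [0.0, 30.0, 60.0, 90.0, 120.0]

    def test_melanopsin_absent_at_10hz(self):
        truth = default_sim_truth(design=StudyDesign(
            observers=("O1",), illuminances_td=(200.0,),
            frequencies_hz=(10.0,), conditions=("i", "R"),
        ))
        t = generate_study(truth, seed=0)
        assert set(t["condition"]) == {"R"}


class TestTrialIO(object):
    def test_round_trip(self, tmp_path):
        truth = default_sim_truth(design=StudyDesign(
            observers=("O1",), illuminances_td=(200.0,), conditions=("i",),
            repeats=1,
        ))
        trials = generate_study(truth, seed=2)
        path = tmp_path / "trials.csv"
        write_trials(trials, path)
        back = read_trials(path)
        assert back.shape == trials.shape
        assert back["response"].equals(trials["response"].astype(bool))

    def test_receptor_set_round_trip(self, tmp_path, receptors):
        from melsum.io import load_receptor_set, save_receptor_set

        path = tmp_path / "receptors.csv"
        save_receptor_set(receptors, path)
        back = load_receptor_set(path)
        np.testing.assert_allclose(back.sensitivities, receptors.sensitivities)
        np.testing.assert_allclose(back.norms, receptors.norms)
        assert back.lambda_max == receptors.lambda_max

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("observer,contrast_pct\nO1,5.0\n")
        with pytest.raises(SchemaError, match="missing columns"):
            read_trials(path)

    def test_catch_with_contrast_rejected(self, tmp_path):
        path = tmp_path / "bad2.csv"
        header = ("observer,illum_td,frequency_hz,condition,phase_deg,repeat,"
                  "contrast_pct,response,catch\n")
        path.write_text(header + "O1,200,1.0,i,,0,5.0,True,True\n")
        with pytest.raises(SchemaError, match="catch"):
            read_trials(path)


class TestRunConfig:
    def test_unknown_keys_rejected(self):
        with pytest.raises(ValidationError):
            RunConfig(seed=1, bogus_knob=3)

    def test_invalid_alpha_level_rejected(self):
        with pytest.raises(ValidationError):
            RunConfig(alpha_level=1.5)

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValidationError):
            RunConfig(conditions=["i", "X+Y"])


@pytest.fixture(scope="module")
def report():
    cfg = RunConfig(seed=7, illuminances_td=[200.0],
                    conditions=["i", "R", "i+R"])
    return run_pipeline(cfg)


class TestPipeline:
    def test_rm_anova_df_matches_design(self, report):
        key = (200.0, 1.0, "i+R")
        result = report.classifications[key]
        for anova in result.anovas.values():
            assert anova.df == (4, 8)  # 5 phases x 3 repeats

    def test_linear_truth_recovered(self, report):
        # generative truth for 1 Hz i+R at 200 Td is vector summation with
        # phi = 30.4 deg, x = 1.0, y = 0.2
        result = report.classifications[(200.0, 1.0, "i+R")]
        assert result.model == "linear"
        assert result.fit.phi_xy_deg == pytest.approx(30.4, abs=10.0)
        xs = [max(v) for v in result.fit.sensitivities.values()]
        ys = [min(v) for v in result.fit.sensitivities.values()]
        assert np.mean(xs) == pytest.approx(1.0, rel=0.15)
        assert np.mean(ys) == pytest.approx(0.2, abs=0.1)

    def test_probability_truth_recovered(self):
        cfg = RunConfig(seed=19, illuminances_td=[200.0],
                        conditions=["i", "LMS", "i+LMS"])
        report = run_pipeline(cfg)
        result = report.classifications[(200.0, 1.0, "i+LMS")]
        assert result.model == "probability"
        n_mean = np.mean(list(result.fit.n.values()))
        assert n_mean == pytest.approx(0.9, abs=0.1)

    def test_report_files_written(self, tmp_path):
        cfg = RunConfig(seed=5, observers=["O1"], illuminances_td=[200.0],
                        conditions=["i", "R", "i+R"], outdir=str(tmp_path))
        run_pipeline(cfg)
        for name in ("trials.csv", "psychometric_fits.csv",
                     "threshold_ratios.csv", "summation_summary.csv",
                     "run_meta.json"):
            assert (tmp_path / name).exists()

    def test_identical_config_reproduces_outputs(self):
        cfg = RunConfig(seed=21, observers=["O1"], illuminances_td=[200.0],
                        conditions=["i", "R", "i+R"])
        r1 = run_pipeline(cfg)
        r2 = run_pipeline(cfg)
        assert r1.psychometric_fits.equals(r2.psychometric_fits)
        assert r1.threshold_ratios.equals(r2.threshold_ratios)
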
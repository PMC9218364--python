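"""Trial-table IO, run configuration, and the end-to-end analysis pipeline.

Tabular data are CSV, configurations and fit reports JSON; everything is
plain text and inspectable.  All randomness flows from a single master seed
through named substreams so that identical configurations reproduce byte-
identical numerical output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import observer as obs_mod
from .observer import (
    COMBINED_CONDITIONS,
    INDIVIDUAL_CONDITIONS,
    StudyDesign,
    default_sim_truth,
    generate_study,
)
from .psychometrics import FitError, FoSData, fit_weibull
from .summation import (
    ClassificationResult,
    SummationDataset,
    classify_summation,
    summation_index_db,
)

__all__ = [
    "SchemaError",
    "TRIAL_COLUMNS",
    "read_trials",
    "write_trials",
    "save_receptor_set",
    "load_receptor_set",
    "RunConfig",
    "PipelineReport",
    "run_pipeline",
]

log = logging.getLogger("melsum")

TRIAL_COLUMNS = (
    "observer",
    "illum_td",
    "frequency_hz",
    "condition",
    "phase_deg",
    "repeat",
    "contrast_pct",
    "response",
    "catch",
)


class SchemaError(ValueError):
    """A trial table violates the expected schema."""


def _validate_trials(df: pd.DataFrame) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trial table is missing columns: {missing}")
    bad = df.index[df["contrast_pct"] < 0].tolist()
    if bad:
        raise SchemaError(f"negative contrast in rows {bad[:10]}")
    catch = df["catch"].astype(bool)
    bad = df.index[catch & (df["contrast_pct"] != 0)].tolist()
    if bad:
        raise SchemaError(f"catch trials with non-zero contrast in rows {bad[:10]}")


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial table CSV."""
    df = pd.read_csv(path)
    _validate_trials(df)
    df["response"] = df["response"].astype(bool)
    df["catch"] = df["catch"].astype(bool)
    return df


def write_trials(df: pd.DataFrame, path: str | Path) -> None:
    """Validate and write a trial table CSV (lossless round trip)."""
    _validate_trials(df)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def save_receptor_set(receptors, path: str | Path) -> None:
    """Write sensitivities as CSV plus a JSON sidecar of normalisation constants."""
    from .spectral import CLASSES

    path = Path(path)
    receptors.to_frame().to_csv(path, index=False)
    sidecar = {
        "norms": dict(zip(CLASSES, receptors.norms.tolist())),
        "lambda_max": dict(zip(CLASSES, receptors.lambda_max)),
        "observer_scaling": dict(zip(CLASSES, receptors.observer_scaling.tolist())),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_receptor_set(path: str | Path):
    """Read a receptor set written by :func:`save_receptor_set`."""
    from .spectral import CLASSES, ReceptorSet

    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in ("wavelength_nm",) + CLASSES if c not in df.columns]
    if missing:
        raise SchemaError(f"receptor CSV is missing columns: {missing}")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return ReceptorSet(
        wavelengths=df["wavelength_nm"].to_numpy(float),
        sensitivities=np.stack([df[k].to_numpy(float) for k in CLASSES]),
        norms=np.array([sidecar["norms"][k] for k in CLASSES]),
        lambda_max=tuple(sidecar["lambda_max"][k] for k in CLASSES),
        observer_scaling=np.array(
            [sidecar.get("observer_scaling", {}).get(k, 1.0) for k in CLASSES]
        ),
    )


class RunConfig(BaseModel):
    """Schema-validated configuration for a full synthetic-study run."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 1234
    observers: list[str] = Field(default=["O1", "O2", "O3"])
    illuminances_td: list[float] = Field(default=[200.0, 2000.0])
    frequencies_hz: list[float] = Field(default=[1.0])
    conditions: list[str] = Field(
        default=list(INDIVIDUAL_CONDITIONS + COMBINED_CONDITIONS)
    )
    phases_deg: list[float] = Field(default=[0.0, 30.0, 60.0, 90.0, 120.0])
    repeats: int = 3
    trials_per_level: int = 24
    catch_per_level: int = 6
    level_spread: list[float] = Field(default=[0.4, 0.6, 0.8, 1.0, 1.25, 1.6, 2.0])
    guess_rate: float = 0.03
    alpha_cv: float = 0.10
    alpha_level: float = 0.05
    eq2_sqrt: bool = True  # vector-magnitude (sqrt) reading of the summation model
    outdir: str | None = None

    @field_validator("alpha_level")
    @classmethod
    def _check_alpha(cls, v: float) -> float:
        if not 0 < v < 1:
            raise ValueError("alpha_level must lie strictly between 0 and 1")
        return v

    @field_validator("conditions")
    @classmethod
    def _check_conditions(cls, v: list[str]) -> list[str]:
        known = set(INDIVIDUAL_CONDITIONS + COMBINED_CONDITIONS)
        unknown = [c for c in v if c not in known]
        if unknown:
            raise ValueError(f"unknown conditions: {unknown}")
        return v

    def design(self) -> StudyDesign:
        return StudyDesign(
            observers=tuple(self.observers),
            illuminances_td=tuple(self.illuminances_td),
            frequencies_hz=tuple(self.frequencies_hz),
            conditions=tuple(self.conditions),
            phases_deg=tuple(self.phases_deg),
            repeats=self.repeats,
            trials_per_level=self.trials_per_level,
            catch_per_level=self.catch_per_level,
            level_spread=tuple(self.level_spread),
        )


@dataclass
class PipelineReport:
    """Outputs of one end-to-end run: fits and summary tables."""

    trials: pd.DataFrame
    psychometric_fits: pd.DataFrame
    threshold_ratios: pd.DataFrame
    classifications: dict[tuple[float, float, str], ClassificationResult]
    summary: pd.DataFrame
    seed: int
    failures: list[dict] = field(default_factory=list)


def fit_all_psychometrics(trials: pd.DataFrame) -> tuple[pd.DataFrame, list[dict]]:
    """Fit one Weibull per (observer, illum, frequency, condition, phase, repeat)."""
    keys = ["observer", "illum_td", "frequency_hz", "condition", "phase_deg", "repeat"]
    rows, failures = [], []
    for key, cell in trials.groupby(keys, dropna=False):
        data = FoSData.from_trials(cell)
        rec = dict(zip(keys, key))
        try:
            fit = fit_weibull(data)
        except FitError as exc:
            failures.append({**rec, "error": str(exc)})
            continue
        rec.update(
            alpha=fit.alpha,
            beta=fit.beta,
            guess=fit.guess,
            deviance=fit.deviance,
            converged=fit.converged,
        )
        rows.append(rec)
    return pd.DataFrame(rows), failures


def threshold_ratios(fits: pd.DataFrame) -> pd.DataFrame:
    """Per-repeat TR = combined threshold / matched individual threshold.

    The denominator is the same observer/illumination/frequency/repeat fit of
    the combination's abscissa pathway (rod for i+R and R+LMS, cones for
    i+LMS).
    """
    ind = fits[fits["condition"].isin(INDIVIDUAL_CONDITIONS)].set_index(
        ["observer", "illum_td", "frequency_hz", "condition", "repeat"]
    )["alpha"]
    rows = []
    comb = fits[fits["condition"].isin(COMBINED_CONDITIONS)]
    for _, row in comb.iterrows():
        denom_cond = obs_mod.COMBINED_DENOMINATOR[row["condition"]]
        key = (row["observer"], row["illum_td"], row["frequency_hz"], denom_cond,
               row["repeat"])
        if key not in ind.index:
            continue
        rows.append(
            {
                "observer": row["observer"],
                "illum_td": row["illum_td"],
                "frequency_hz": row["frequency_hz"],
                "condition": row["condition"],
                "phase_deg": row["phase_deg"],
                "repeat": row["repeat"],
                "tr": row["alpha"] / ind.loc[key],
                "denominator": denom_cond,
            }
        )
    return pd.DataFrame(rows)


def _tr_datasets(tr: pd.DataFrame) -> dict[tuple[float, float, str], list[SummationDataset]]:
    out: dict[tuple[float, float, str], list[SummationDataset]] = {}
    for (illum, freq, cond), grp in tr.groupby(["illum_td", "frequency_hz", "condition"]):
        datasets = []
        for obs, og in grp.groupby("observer"):
            pivot = og.pivot_table(index="phase_deg", columns="repeat", values="tr")
            pivot = pivot.dropna()
            if pivot.shape[0] < 3 or pivot.shape[1] < 2:
                continue
            datasets.append(
                SummationDataset.from_matrix(
                    observer=str(obs),
                    phases_deg=pivot.index.to_numpy(float),
                    tr_matrix=pivot.to_numpy(float),
                    condition=cond,
                    frequency_hz=float(freq),
                    illuminance_td=float(illum),
                    denominator=obs_mod.COMBINED_DENOMINATOR[cond],
                )
            )
        if datasets:
            out[(float(illum), float(freq), cond)] = datasets
    return out


def run_pipeline(config: RunConfig) -> PipelineReport:
    """simulate -> fit psychometric functions -> threshold ratios -> classify.

    Produces a summary table mirroring the study's parameter table (threshold
    and slope per condition; summation model, sensitivities, shared phase,
    index in dB and implied latency per combination).
    """
    log.info("pipeline start: seed=%d", config.seed)
    truth = default_sim_truth(
        guess_rate=config.guess_rate,
        alpha_cv=config.alpha_cv,
        design=config.design(),
    )
    trials = generate_study(truth, seed=config.seed)
    log.info("simulated %d trials", len(trials))
    fits, failures = fit_all_psychometrics(trials)
    if failures:
        log.warning("%d psychometric cells failed to fit", len(failures))
    tr = threshold_ratios(fits)
    classifications = {}
    summary_rows = []
    for key, datasets in _tr_datasets(tr).items():
        illum, freq, cond = key
        result = classify_summation(datasets, alpha=config.alpha_level,
                                    sqrt_form=config.eq2_sqrt)
        classifications[key] = result
        rec = {
            "illum_td": illum,
            "frequency_hz": freq,
            "condition": cond,
            "model": result.model,
            "gof_chi2": result.gof_chi2,
            "gof_p": result.gof_p,
        }
        if result.model == "linear":
            rec["phi_xy_deg"] = result.fit.phi_xy_deg
            rec["latency_ms"] = result.fit.latency_ms
            xs = [v[0] for v in result.fit.sensitivities.values()]
            ys = [v[1] for v in result.fit.sensitivities.values()]
            rec["x_mean"] = float(np.mean(xs))
            rec["y_mean"] = float(np.mean(ys))
        else:
            ns = list(result.fit.n.values())
            rec["n_mean"] = float(np.mean(ns))
            rec["index_db_mean"] = float(
                np.mean([summation_index_db(v) for v in ns])
            )
        summary_rows.append(rec)
    summary = pd.DataFrame(summary_rows)
    report = PipelineReport(
        trials=trials,
        psychometric_fits=fits,
        threshold_ratios=tr,
        classifications=classifications,
        summary=summary,
        seed=config.seed,
        failures=failures,
    )
    if config.outdir:
        _write_report(report, config)
    return report


def _write_report(report: PipelineReport, config: RunConfig) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_trials(report.trials, out / "trials.csv")
    report.psychometric_fits.to_csv(out / "psychometric_fits.csv", index=False)
    report.threshold_ratios.to_csv(out / "threshold_ratios.csv", index=False)
    report.summary.to_csv(out / "summation_summary.csv", index=False)
    meta = {
        "seed": report.seed,
        "config": config.model_dump(),
        "n_trials": int(len(report.trials)),
        "n_fit_failures": len(report.failures),
    }
    (out / "run_meta.json").write_text(json.dumps(meta, indent=2))
    log.info("report written to %s", out)
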
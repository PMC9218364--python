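"""Generative model of the phase-summation study.

Simulates trial-level yes/no data with the statistical structure the
analysis assumes: Weibull psychometric functions per condition, combined-
condition thresholds derived from the configured summation model (vector or
probability summation), catch-trial guessing, and the study's default design
(3 observers x {200, 2000} Td x six photoreceptor-directed conditions x
five relative phases x 3 repeats, 24 + 6 trials at each of 7 contrast
levels).  Group-mean parameter defaults follow the published estimates for
the 1 Hz and 10 Hz conditions; between-observer variability is log-normal
jitter on the thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .psychometrics import weibull_probability
from .summation import tr_probability, tr_vector

__all__ = [
    "WeibullTruth",
    "SummationTruth",
    "StudyDesign",
    "SimTruth",
    "default_sim_truth",
    "simulate_trials",
    "generate_study",
    "INDIVIDUAL_CONDITIONS",
    "COMBINED_CONDITIONS",
    "COMBINED_DENOMINATOR",
]

INDIVIDUAL_CONDITIONS = ("i", "R", "LMS")
COMBINED_CONDITIONS = ("i+R", "i+LMS", "R+LMS")

#: Denominator convention for threshold ratios: the abscissa of the combined
#: psychometric function carries the rod contrast for i+R and R+LMS and the
#: LMS-cone contrast for i+LMS.
COMBINED_DENOMINATOR = {"i+R": "R", "i+LMS": "LMS", "R+LMS": "R"}
_DENOM = COMBINED_DENOMINATOR


@dataclass(frozen=True)
class WeibullTruth:
    alpha: float  # % Michelson threshold
    beta: float


@dataclass(frozen=True)
class SummationTruth:
    model: str  # "linear" | "probability"
    n: float | None = None  # probability-summation scaling
    x: float | None = None  # denominator-pathway sensitivity
    y: float | None = None  # other-pathway sensitivity
    phi_deg: float | None = None  # shared phase difference

    def tr(self, phase_deg: np.ndarray, sqrt_form: bool = True) -> np.ndarray:
        if self.model == "probability":
            assert self.n is not None
            return tr_probability(self.n, phase_deg)
        assert None not in (self.x, self.y, self.phi_deg)
        return tr_vector(phase_deg, self.x, self.y, self.phi_deg, sqrt_form=sqrt_form)


# Group-mean Weibull and summation parameters per (frequency, illuminance).
# 10 Hz rows have no melanopsin-directed entry (imperceptible at that rate).
_WEIBULL_MEANS: dict[tuple[float, float, str], WeibullTruth] = {
    (1.0, 200.0, "i"): WeibullTruth(9.9, 2.2),
    (1.0, 200.0, "R"): WeibullTruth(7.6, 2.4),
    (1.0, 200.0, "LMS"): WeibullTruth(5.3, 2.8),
    (1.0, 2000.0, "i"): WeibullTruth(10.2, 2.1),
    (1.0, 2000.0, "R"): WeibullTruth(7.7, 2.5),
    (1.0, 2000.0, "LMS"): WeibullTruth(4.64, 2.9),
    (10.0, 200.0, "R"): WeibullTruth(6.9, 2.5),
    (10.0, 200.0, "LMS"): WeibullTruth(3.8, 3.2),
    (10.0, 2000.0, "R"): WeibullTruth(7.7, 2.5),
    (10.0, 2000.0, "LMS"): WeibullTruth(3.3, 3.2),
}

_COMBINED_BETA: dict[tuple[float, float, str], float] = {
    (1.0, 200.0, "i+R"): 2.3,
    (1.0, 200.0, "i+LMS"): 1.9,
    (1.0, 200.0, "R+LMS"): 2.8,
    (1.0, 2000.0, "i+R"): 2.7,
    (1.0, 2000.0, "i+LMS"): 2.3,
    (1.0, 2000.0, "R+LMS"): 3.0,
    (10.0, 200.0, "i+R"): 3.0,
    (10.0, 200.0, "i+LMS"): 2.4,
    (10.0, 200.0, "R+LMS"): 2.8,
    (10.0, 2000.0, "i+R"): 3.2,
    (10.0, 2000.0, "i+LMS"): 2.5,
    (10.0, 2000.0, "R+LMS"): 3.0,
}

_SUMMATION_MEANS: dict[tuple[float, float, str], SummationTruth] = {
    (1.0, 200.0, "i+R"): SummationTruth("linear", x=1.0, y=0.2, phi_deg=30.4),
    (1.0, 2000.0, "i+R"): SummationTruth("linear", x=1.2, y=0.3, phi_deg=45.7),
    (1.0, 200.0, "i+LMS"): SummationTruth("probability", n=0.9),
    (1.0, 2000.0, "i+LMS"): SummationTruth("probability", n=0.8),
    (1.0, 200.0, "R+LMS"): SummationTruth("linear", x=0.6, y=1.8, phi_deg=24.7),
    (1.0, 2000.0, "R+LMS"): SummationTruth("linear", x=0.6, y=1.9, phi_deg=28.1),
    (10.0, 200.0, "i+R"): SummationTruth("probability", n=0.8),
    (10.0, 2000.0, "i+R"): SummationTruth("probability", n=0.8),
    (10.0, 200.0, "i+LMS"): SummationTruth("probability", n=0.9),
    (10.0, 2000.0, "i+LMS"): SummationTruth("probability", n=0.8),
    (10.0, 200.0, "R+LMS"): SummationTruth("linear", x=1.1, y=2.3, phi_deg=163.4),
    (10.0, 2000.0, "R+LMS"): SummationTruth("linear", x=1.2, y=2.5, phi_deg=170.0),
}


@dataclass(frozen=True)
class StudyDesign:
    """Method-of-constant-stimuli layout of the study."""

    observers: tuple[str, ...] = ("O1", "O2", "O3")
    illuminances_td: tuple[float, ...] = (200.0, 2000.0)
    frequencies_hz: tuple[float, ...] = (1.0,)
    conditions: tuple[str, ...] = INDIVIDUAL_CONDITIONS + COMBINED_CONDITIONS
    phases_deg: tuple[float, ...] = (0.0, 30.0, 60.0, 90.0, 120.0)
    repeats: int = 3
    trials_per_level: int = 24
    catch_per_level: int = 6
    #: contrast levels as multiples of the cell's true threshold
    level_spread: tuple[float, ...] = (0.4, 0.6, 0.8, 1.0, 1.25, 1.6, 2.0)


@dataclass(frozen=True)
class SimTruth:
    """Generative parameters of a synthetic study."""

    weibull: dict[tuple[float, float, str], WeibullTruth]
    combined_beta: dict[tuple[float, float, str], float]
    summation: dict[tuple[float, float, str], SummationTruth]
    guess_rate: float = 0.03
    lapse_rate: float = 0.0
    alpha_cv: float = 0.10  # between-observer log-normal jitter on thresholds
    design: StudyDesign = field(default_factory=StudyDesign)

    def __post_init__(self) -> None:
        if not 0 <= self.guess_rate < 1:
            raise ValueError("guess rate must lie in [0, 1)")
        if self.lapse_rate != 0.0:
            raise ValueError("the lapse rate is fixed at zero in this paradigm")
        if self.alpha_cv < 0:
            raise ValueError("alpha_cv must be non-negative")


def default_sim_truth(**overrides) -> SimTruth:
    """Study-faithful generative defaults (group-mean parameters)."""
    return SimTruth(
        weibull=dict(_WEIBULL_MEANS),
        combined_beta=dict(_COMBINED_BETA),
        summation=dict(_SUMMATION_MEANS),
        **overrides,
    )


def _observer_alpha(
    base_alpha: float, truth: SimTruth, rng: np.random.Generator
) -> float:
    if truth.alpha_cv == 0:
        return base_alpha
    sigma = np.sqrt(np.log(1.0 + truth.alpha_cv**2))
    return float(base_alpha * rng.lognormal(-0.5 * sigma**2, sigma))


def simulate_trials(
    alpha: float,
    beta: float,
    guess_rate: float,
    design: StudyDesign,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """One MOCS block: Bernoulli yes/no responses at each contrast level.

    Stimulus trials respond "yes" with the Weibull probability (guessing
    floor included); catch trials respond "yes" with the guessing rate.
    """
    levels = alpha * np.asarray(design.level_spread)
    rows = []
    for lv in levels:
        p = weibull_probability(lv, alpha, beta, guess_rate, 0.0)
        yes = rng.random(design.trials_per_level) < p
        rows.extend(
            {"contrast_pct": float(lv), "catch": False, "response": bool(y)} for y in yes
        )
        yes_c = rng.random(design.catch_per_level) < guess_rate
        rows.extend(
            {"contrast_pct": 0.0, "catch": True, "response": bool(y)} for y in yes_c
        )
    df = pd.DataFrame(rows)
    order = rng.permutation(len(df))
    return df.iloc[order].reset_index(drop=True)


def _cell_truth(
    truth: SimTruth,
    freq: float,
    illum: float,
    condition: str,
    phase_deg: float | None,
    obs_scale: float,
) -> tuple[float, float] | None:
    """(alpha, beta) for one design cell; None if the cell does not exist."""
    if condition in INDIVIDUAL_CONDITIONS:
        wt = truth.weibull.get((freq, illum, condition))
        if wt is None:
            return None
        return wt.alpha * obs_scale, wt.beta
    st = truth.summation.get((freq, illum, condition))
    if st is None:
        return None
    denom = _DENOM[condition]
    wt = truth.weibull.get((freq, illum, denom))
    if wt is None:
        return None
    tr = float(st.tr(np.asarray(phase_deg if phase_deg is not None else 0.0)))
    beta = truth.combined_beta.get((freq, illum, condition), wt.beta)
    return wt.alpha * obs_scale * tr, beta


def generate_study(
    truth: SimTruth | None = None,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate the full synthetic study as a trial table.

    Columns: observer, illum_td, frequency_hz, condition, phase_deg, repeat,
    contrast_pct, response, catch.  Individual (single-pathway) conditions
    carry phase NaN.  Fully reproducible from the seed.
    """
    truth = truth or default_sim_truth()
    rng = np.random.default_rng(seed)
    design = truth.design
    frames = []
    for obs in design.observers:
        obs_scale = _observer_alpha(1.0, truth, rng)
        for illum in design.illuminances_td:
            for freq in design.frequencies_hz:
                for cond in design.conditions:
                    phases: tuple[float | None, ...]
                    if cond in INDIVIDUAL_CONDITIONS:
                        phases = (None,)
                    else:
                        phases = design.phases_deg
                    for phase in phases:
                        ab = _cell_truth(truth, freq, illum, cond, phase, obs_scale)
                        if ab is None:
                            continue
                        alpha, beta = ab
                        for rep in range(design.repeats):
                            block = simulate_trials(
                                alpha, beta, truth.guess_rate, design, rng
                            )
                            block.insert(0, "observer", obs)
                            block.insert(1, "illum_td", illum)
                            block.insert(2, "frequency_hz", freq)
                            block.insert(3, "condition", cond)
                            block.insert(4, "phase_deg",
                                         np.nan if phase is None else phase)
                            block.insert(5, "repeat", rep)
                            frames.append(block)
    return pd.concat(frames, ignore_index=True)


def small_design(**overrides) -> StudyDesign:
    """A reduced design for quick end-to-end runs (same structure, fewer cells)."""
    defaults = dict(
        observers=("O1", "O2", "O3"),
        illuminances_td=(200.0,),
        frequencies_hz=(1.0,),
        conditions=("i", "R", "i+R"),
    )
    defaults.update(overrides)
    return StudyDesign(**defaults)
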
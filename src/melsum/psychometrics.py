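"""Method-of-constant-stimuli design and Weibull psychometric estimation.

Frequency-of-seeing data are fitted with a two-parameter Weibull,

    F(x) = 1 - exp(-(x / alpha) ** beta),

after guessing correction of the observed proportions (Abbott's formula,
with the guessing rate estimated from pooled catch trials).  The lapse rate
is fixed at zero and threshold is reported at the 63.21 % point of the
corrected function, i.e. x = alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "FitError",
    "FoSData",
    "PsychometricFit",
    "weibull_probability",
    "guessing_correct",
    "fit_weibull",
    "mocs_design",
]

_EPS = 1e-9


class FitError(RuntimeError):
    """Psychometric fit could not be computed (degenerate data or no convergence)."""


def weibull_probability(
    x: np.ndarray | float,
    alpha: float,
    beta: float,
    guess: float = 0.0,
    lapse: float = 0.0,
) -> np.ndarray | float:
    """Weibull yes-probability P = guess + (1 - guess - lapse) F(x)."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    if not 0 <= guess < 1 or not 0 <= lapse < 1:
        raise ValueError("guess and lapse rates must lie in [0, 1)")
    x = np.asarray(x, dtype=float)
    F = 1.0 - np.exp(-np.power(np.clip(x, 0, None) / alpha, beta))
    p = guess + (1.0 - guess - lapse) * F
    return float(p) if p.ndim == 0 else p


def guessing_correct(p: np.ndarray | float, guess: float) -> np.ndarray | float:
    """Abbott's correction for guessing: p_adj = (p - guess) / (1 - guess)."""
    if not 0 <= guess < 1:
        raise ValueError("guess rate must lie in [0, 1)")
    return (np.asarray(p, dtype=float) - guess) / (1.0 - guess)


@dataclass(frozen=True)
class FoSData:
    """Frequency-of-seeing counts per contrast level, plus catch-trial totals."""

    levels: np.ndarray  # % Michelson, strictly increasing
    n_yes: np.ndarray
    n_total: np.ndarray
    n_catch_yes: int = 0
    n_catch: int = 0

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels, dtype=float)
        ny = np.asarray(self.n_yes, dtype=float)
        nt = np.asarray(self.n_total, dtype=float)
        if not (lv.shape == ny.shape == nt.shape):
            raise ValueError("levels, n_yes and n_total must have equal length")
        if np.any(np.diff(lv) <= 0):
            raise ValueError("contrast levels must be strictly increasing")
        if np.any(lv < 0):
            raise ValueError("contrast levels must be non-negative")
        if np.any(ny < 0) or np.any(ny > nt):
            raise ValueError("need 0 <= n_yes <= n_total at every level")
        object.__setattr__(self, "levels", lv)
        object.__setattr__(self, "n_yes", ny)
        object.__setattr__(self, "n_total", nt)

    @property
    def false_alarm_rate(self) -> float:
        """Guessing rate estimated from pooled catch trials."""
        return self.n_catch_yes / self.n_catch if self.n_catch > 0 else 0.0

    @property
    def proportions(self) -> np.ndarray:
        return self.n_yes / self.n_total

    @classmethod
    def from_trials(cls, trials: pd.DataFrame) -> "FoSData":
        """Aggregate a trial table (columns contrast_pct, response, catch)."""
        catch = trials["catch"].astype(bool)
        stim = trials.loc[~catch]
        grouped = stim.groupby("contrast_pct")["response"]
        levels = np.array(sorted(grouped.groups))
        agg = grouped.agg(["sum", "count"]).loc[levels]
        return cls(
            levels=levels,
            n_yes=agg["sum"].to_numpy(float),
            n_total=agg["count"].to_numpy(float),
            n_catch_yes=int(trials.loc[catch, "response"].sum()),
            n_catch=int(catch.sum()),
        )


@dataclass(frozen=True)
class PsychometricFit:
    """Two-parameter Weibull fit with guessing correction applied beforehand."""

    alpha: float  # threshold (% Michelson) at the 63.21 % criterion
    beta: float  # slope
    guess: float
    lapse: float
    deviance: float
    converged: bool
    n_levels: int
    method: str
    message: str = ""

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        """Raw (uncorrected) yes-probability, including the guessing floor."""
        return weibull_probability(x, self.alpha, self.beta, self.guess, self.lapse)


def _corrected_counts(data: FoSData) -> tuple[np.ndarray, np.ndarray]:
    gamma = data.false_alarm_rate
    p_adj = np.clip(guessing_correct(data.proportions, gamma), 0.0, 1.0)
    return p_adj * data.n_total, data.n_total


def fit_weibull(data: FoSData, method: str = "ml") -> PsychometricFit:
    """Fit threshold and slope to frequency-of-seeing data.

    method="ml" maximises the Bernoulli likelihood of the guessing-corrected
    counts; method="ls" minimises squared error on the corrected proportions.
    """
    if data.levels.size < 4:
        raise FitError("need at least 4 contrast levels to fit threshold and slope")
    if np.any(data.n_total <= 0):
        raise FitError("every level must have at least one trial")
    y_adj, n = _corrected_counts(data)
    p_adj = y_adj / n
    if np.all(y_adj <= 0):
        raise FitError("all responses are 'no' after correction; threshold not identifiable")
    if np.all(y_adj >= n):
        raise FitError("all responses are 'yes'; threshold not identifiable")

    # Initial threshold: where the corrected proportion crosses 1 - 1/e.
    crit = 1.0 - np.exp(-1.0)
    alpha0 = float(np.interp(crit, p_adj, data.levels,
                             left=data.levels[0], right=data.levels[-1]))
    alpha0 = max(alpha0, _EPS)

    def nll(theta: np.ndarray) -> float:
        alpha, beta = np.exp(theta)
        F = 1.0 - np.exp(-np.power(data.levels / alpha, beta))
        F = np.clip(F, _EPS, 1.0 - _EPS)
        return float(-np.sum(y_adj * np.log(F) + (n - y_adj) * np.log(1.0 - F)))

    def sse(theta: np.ndarray) -> float:
        alpha, beta = np.exp(theta)
        F = 1.0 - np.exp(-np.power(data.levels / alpha, beta))
        return float(np.sum((p_adj - F) ** 2))

    objective = nll if method == "ml" else sse
    best = None
    for beta0 in (1.0, 2.0, 4.0):
        res = optimize.minimize(
            objective,
            x0=np.log([alpha0, beta0]),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    if not best.success:
        raise FitError(f"psychometric fit did not converge: {best.message}")
    alpha, beta = np.exp(best.x)

    # Deviance against the saturated model, on the corrected counts.
    F = np.clip(1.0 - np.exp(-np.power(data.levels / alpha, beta)), _EPS, 1.0 - _EPS)
    p_obs = np.clip(p_adj, _EPS, 1.0 - _EPS)
    dev = 2.0 * float(
        np.sum(
            y_adj * np.log(p_obs / F)
            + (n - y_adj) * np.log((1.0 - p_obs) / (1.0 - F))
        )
    )
    return PsychometricFit(
        alpha=float(alpha),
        beta=float(beta),
        guess=data.false_alarm_rate,
        lapse=0.0,
        deviance=dev,
        converged=bool(best.success),
        n_levels=int(data.levels.size),
        method=method,
        message=str(best.message),
    )


def mocs_design(
    levels: np.ndarray,
    trials_per_level: int = 24,
    catch_per_level: int = 6,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Randomised method-of-constant-stimuli trial skeleton.

    The study default is 24 stimulus trials (80 %) plus 6 catch trials (20 %)
    at each of 6-7 contrast levels; catch trials carry zero contrast.
    """
    levels = np.asarray(levels, dtype=float)
    if levels.size == 0:
        raise ValueError("need at least one contrast level")
    if trials_per_level <= 0 or catch_per_level < 0:
        raise ValueError("trial counts must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for lv in levels:
        rows.extend({"contrast_pct": lv, "catch": False} for _ in range(trials_per_level))
        rows.extend({"contrast_pct": 0.0, "catch": True} for _ in range(catch_per_level))
    df = pd.DataFrame(rows)
    order = rng.permutation(len(df))
    df = df.iloc[order].reset_index(drop=True)
    df.insert(0, "trial", np.arange(len(df)))
    return df
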
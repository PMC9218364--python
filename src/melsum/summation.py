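"""Phase-summation models: probability vs. linear (vector) summation.

The phase paradigm measures the threshold ratio TR = combined threshold /
individual threshold as a function of the relative phase between two
photoreceptor-directed components.  Two candidate models are compared:

* probability summation — independent detection in parallel pathways; the
  TR is a phase-independent constant n, reported as 20 log10(1/n) dB;
* linear (vector) summation — the pathway signals add as phasors, so the
  detected amplitude is sqrt(x^2 + y^2 - 2 x y cos(phi - phi_xy)) and

      TR(phi) = 1 / sqrt(x^2 + y^2 - 2 x y cos(phi - phi_xy)),

  maximal threshold elevation (destructive interference) at phi = phi_xy and
  facilitation half a cycle away.  x and y are per-observer pathway
  sensitivities; phi_xy is the temporal phase difference between the
  pathways, shared across observers (a global phase estimate) and
  convertible to a latency difference at the stimulus frequency.

Classification follows the study's rule: a one-way repeated-measures ANOVA
of TR across phase per observer; phase-independence (p >= alpha) selects
probability summation, otherwise linear summation; goodness of fit of the
selected model is assessed with a chi-square test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "tr_probability",
    "summation_index_db",
    "db_to_index",
    "tr_vector",
    "phase_to_latency",
    "latency_to_phase",
    "SummationDataset",
    "SummationFit",
    "fit_probability_summation",
    "fit_global_summation",
    "RMAnovaResult",
    "rm_anova_oneway",
    "ClassificationResult",
    "classify_summation",
    "summation_square",
]


# --------------------------------------------------------------------------- #
# closed-form model pieces


def tr_probability(n: float, phase_deg: np.ndarray | float | None = None):
    """Probability-summation threshold ratio: TR = n at every phase."""
    if n <= 0:
        raise ValueError("summation index n must be positive")
    if phase_deg is None:
        return float(n)
    phase_deg = np.asarray(phase_deg, dtype=float)
    return np.full_like(phase_deg, float(n))


def summation_index_db(n: float) -> float:
    """Summation index in dB: 20 log10(1/n)."""
    if n <= 0:
        raise ValueError("summation index n must be positive")
    return float(20.0 * np.log10(1.0 / n))


def db_to_index(db: float) -> float:
    """Inverse of :func:`summation_index_db`."""
    return float(10.0 ** (-db / 20.0))


def tr_vector(
    phase_deg: np.ndarray | float,
    x: float,
    y: float,
    phi_xy_deg: float,
    sqrt_form: bool = True,
) -> np.ndarray | float:
    """Vector-summation threshold ratio.

    ``sqrt_form=True`` (default) uses the phasor-magnitude denominator
    sqrt(x^2 + y^2 - 2 x y cos(phi - phi_xy)); ``sqrt_form=False`` uses the
    squared-magnitude reading.  At exact cancellation (x = y and
    phi = phi_xy) the TR is unbounded and returned as +inf.
    """
    if x < 0 or y < 0:
        raise ValueError("sensitivities must be non-negative")
    phase = np.asarray(phase_deg, dtype=float)
    amp2 = x * x + y * y - 2.0 * x * y * np.cos(np.deg2rad(phase - phi_xy_deg))
    amp2 = np.clip(amp2, 0.0, None)
    with np.errstate(divide="ignore"):
        tr = 1.0 / np.sqrt(amp2) if sqrt_form else 1.0 / amp2
    return float(tr) if tr.ndim == 0 else tr


def phase_to_latency(phase_deg: float, frequency_hz: float) -> float:
    """Phase difference (degrees) to latency difference (ms) at a frequency."""
    if frequency_hz <= 0:
        raise ValueError("frequency must be positive")
    return phase_deg / 360.0 * 1000.0 / frequency_hz


def latency_to_phase(latency_ms: float, frequency_hz: float) -> float:
    """Latency difference (ms) to phase difference (degrees) at a frequency."""
    if frequency_hz <= 0:
        raise ValueError("frequency must be positive")
    return latency_ms * frequency_hz * 360.0 / 1000.0


# --------------------------------------------------------------------------- #
# data containers


@dataclass
class SummationDataset:
    """Per-observer threshold ratios across relative phase.

    ``tr_matrix`` (n_phase, n_repeat), when available, feeds the
    repeated-measures ANOVA; ``tr_mean``/``tr_sem`` summarise it for the
    model fits.  ``denominator`` records the convention: the rod threshold
    for i+R and R+LMS combinations, the cone threshold for i+LMS.
    """

    observer: str
    phases_deg: np.ndarray
    tr_mean: np.ndarray
    tr_sem: np.ndarray | None = None
    tr_matrix: np.ndarray | None = None
    condition: str = ""
    frequency_hz: float = 1.0
    illuminance_td: float = 200.0
    denominator: str = ""

    def __post_init__(self) -> None:
        self.phases_deg = np.asarray(self.phases_deg, dtype=float)
        self.tr_mean = np.asarray(self.tr_mean, dtype=float)
        if self.phases_deg.size < 3:
            raise ValueError("need at least 3 phase levels")
        if np.any(self.tr_mean[np.isfinite(self.tr_mean)] <= 0):
            raise ValueError("threshold ratios must be positive")
        if self.tr_sem is not None:
            self.tr_sem = np.asarray(self.tr_sem, dtype=float)
        if self.tr_matrix is not None:
            self.tr_matrix = np.asarray(self.tr_matrix, dtype=float)

    @classmethod
    def from_matrix(cls, observer: str, phases_deg, tr_matrix, **kwargs) -> "SummationDataset":
        m = np.asarray(tr_matrix, dtype=float)
        sem = m.std(axis=1, ddof=1) / np.sqrt(m.shape[1]) if m.shape[1] > 1 else None
        return cls(
            observer=observer,
            phases_deg=phases_deg,
            tr_mean=m.mean(axis=1),
            tr_sem=sem,
            tr_matrix=m,
            **kwargs,
        )


@dataclass
class SummationFit:
    """Fitted summation model for one condition across observers."""

    model: str  # "probability" | "linear"
    observers: list[str]
    phi_xy_deg: float | None  # shared phase difference (linear model)
    sensitivities: dict[str, tuple[float, float]] | None  # per observer (x, y)
    n: dict[str, float] | None  # per observer scaling (probability model)
    frequency_hz: float
    cost: float
    converged: bool
    covariance: np.ndarray | None = None
    gof_chi2: float | None = None
    gof_df: int | None = None
    gof_p: float | None = None
    flags: dict = field(default_factory=dict)

    @property
    def latency_ms(self) -> float | None:
        """Latency difference implied by the shared phase at the stimulus frequency."""
        if self.phi_xy_deg is None:
            return None
        return phase_to_latency(self.phi_xy_deg, self.frequency_hz)

    @property
    def summation_index_db(self) -> dict[str, float] | None:
        if self.n is None:
            return None
        return {obs: summation_index_db(v) for obs, v in self.n.items()}

    def predict(self, observer: str, phase_deg: np.ndarray) -> np.ndarray:
        phase_deg = np.asarray(phase_deg, dtype=float)
        if self.model == "probability":
            assert self.n is not None
            return tr_probability(self.n[observer], phase_deg)
        assert self.sensitivities is not None and self.phi_xy_deg is not None
        x, y = self.sensitivities[observer]
        return tr_vector(phase_deg, x, y, self.phi_xy_deg,
                         sqrt_form=self.flags.get("sqrt_form", True))


# --------------------------------------------------------------------------- #
# model fitting


def fit_probability_summation(datasets: list[SummationDataset]) -> SummationFit:
    """Least-squares constant TR per observer (the probability-summation fit)."""
    if not datasets:
        raise ValueError("need at least one observer dataset")
    n = {}
    cost = 0.0
    for ds in datasets:
        finite = np.isfinite(ds.tr_mean)
        n[ds.observer] = float(ds.tr_mean[finite].mean())
        cost += float(np.sum((ds.tr_mean[finite] - n[ds.observer]) ** 2))
    return SummationFit(
        model="probability",
        observers=[ds.observer for ds in datasets],
        phi_xy_deg=None,
        sensitivities=None,
        n=n,
        frequency_hz=datasets[0].frequency_hz,
        cost=cost,
        converged=True,
    )


def fit_global_summation(
    datasets: list[SummationDataset],
    sqrt_form: bool = True,
    weight_by_sem: bool = False,
) -> SummationFit:
    """Damped least-squares fit of the vector-summation model.

    One phase difference phi_xy is shared across observers; sensitivities
    (x, y) vary per observer.  Non-finite TRs (flagged cancellation points)
    are excluded from the residuals.  Raises on non-convergence or when a
    dataset has fewer phases than free parameters.
    """
    if not datasets:
        raise ValueError("need at least one observer dataset")
    for ds in datasets:
        if ds.phases_deg.size < 3:
            raise ValueError(f"observer {ds.observer}: fewer phase levels than parameters")

    n_obs = len(datasets)

    def unpack(theta: np.ndarray):
        phi = theta[0]
        xy = theta[1:].reshape(n_obs, 2)
        return phi, xy

    def residuals(theta: np.ndarray) -> np.ndarray:
        phi, xy = unpack(theta)
        res = []
        for ds, (x, y) in zip(datasets, xy):
            finite = np.isfinite(ds.tr_mean)
            pred = tr_vector(ds.phases_deg[finite], x, y, phi, sqrt_form=sqrt_form)
            r = pred - ds.tr_mean[finite]
            if weight_by_sem and ds.tr_sem is not None:
                sem = np.clip(ds.tr_sem[finite], 1e-6, None)
                r = r / sem
            res.append(r)
        return np.concatenate(res)

    # Multi-start over the shared phase to dodge local minima.
    best = None
    for phi0 in (0.0, 30.0, 60.0, 90.0, 120.0, 180.0, 270.0):
        theta0 = np.concatenate([[phi0], np.tile([1.0, 0.3], n_obs)])
        lb = np.concatenate([[-360.0], np.zeros(2 * n_obs)])
        ub = np.concatenate([[720.0], np.full(2 * n_obs, np.inf)])
        try:
            res = optimize.least_squares(residuals, theta0, bounds=(lb, ub),
                                         xtol=1e-12, ftol=1e-12)
        except Exception:  # pragma: no cover - pathological start
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success:
        raise RuntimeError("global summation fit did not converge "
                           f"(status={'none' if best is None else best.status})")
    phi, xy = unpack(best.x)
    phi = float(phi % 360.0)
    # Covariance from the Gauss-Newton approximation, when well conditioned.
    J = best.jac
    dof = max(best.fun.size - best.x.size, 1)
    try:
        cov = np.linalg.inv(J.T @ J) * 2.0 * best.cost / dof
    except np.linalg.LinAlgError:
        cov = None
    return SummationFit(
        model="linear",
        observers=[ds.observer for ds in datasets],
        phi_xy_deg=phi,
        sensitivities={ds.observer: (float(x), float(y)) for ds, (x, y) in zip(datasets, xy)},
        n=None,
        frequency_hz=datasets[0].frequency_hz,
        cost=float(2.0 * best.cost),
        converged=bool(best.success),
        covariance=cov,
        flags={"sqrt_form": sqrt_form},
    )


# --------------------------------------------------------------------------- #
# statistical machinery


@dataclass
class RMAnovaResult:
    F: float
    df: tuple[int, int]
    p: float
    ss_condition: float
    ss_error: float
    mauchly_w: float
    mauchly_chi2: float
    mauchly_df: int
    mauchly_p: float
    mauchly_valid: bool
    pairwise: pd.DataFrame | None


def rm_anova_oneway(matrix: np.ndarray, pairwise: bool = True) -> RMAnovaResult:
    """One-way repeated-measures ANOVA on a (conditions x blocks) matrix.

    Blocks (subjects or repeats) are the repeated-measures unit; df are
    (k - 1, (k - 1)(n - 1)).  Mauchly's sphericity statistic is reported
    when the block-level covariance allows it (it is undefined for n - 1 < k
    blocks, flagged via ``mauchly_valid``); pairwise comparisons use paired
    t-tests with Bonferroni correction.
    """
    import pingouin as pg  # deferred: heavyweight import

    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 3 or m.shape[1] < 2:
        raise ValueError("need a complete (>=3 conditions x >=2 blocks) matrix")
    if not np.all(np.isfinite(m)):
        raise ValueError("matrix contains missing cells")
    k, n = m.shape
    long = pd.DataFrame(
        {
            "score": m.ravel(),
            "condition": np.repeat(np.arange(k), n),
            "block": np.tile(np.arange(n), k),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.rm_anova(data=long, dv="score", within="condition",
                          subject="block", detailed=True)
    row = aov.loc[aov["Source"] == "condition"].iloc[0]
    err = aov.loc[aov["Source"] == "Error"].iloc[0]
    mauchly_valid = n - 1 >= k  # sample covariance otherwise singular
    mauchly = (np.nan, np.nan, np.nan, np.nan)
    if mauchly_valid:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sph = pg.sphericity(data=long, dv="score", subject="block",
                                    within="condition")
            mauchly = (float(sph.W), float(sph.chi2), int(sph.dof), float(sph.pval))
        except Exception:
            mauchly_valid = False
    pw = None
    if pairwise:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pw = pg.pairwise_tests(data=long, dv="score", within="condition",
                                   subject="block", padjust="bonf")
    return RMAnovaResult(
        F=float(row["F"]),
        df=(int(row["DF"]), int(err["DF"])),
        p=float(row["p_unc"]),
        ss_condition=float(row["SS"]),
        ss_error=float(err["SS"]),
        mauchly_w=mauchly[0],
        mauchly_chi2=mauchly[1],
        mauchly_df=int(mauchly[2]) if mauchly_valid else (k * (k - 1)) // 2 - 1,
        mauchly_p=mauchly[3],
        mauchly_valid=mauchly_valid,
        pairwise=pw,
    )


@dataclass
class ClassificationResult:
    model: str  # "probability" | "linear"
    per_observer_p: dict[str, float]
    anovas: dict[str, RMAnovaResult]
    fit: SummationFit
    probability_fit: SummationFit
    linear_fit: SummationFit | None
    gof_chi2: float
    gof_df: int
    gof_p: float
    gof_ok: bool


def _gof_chisquare(
    datasets: list[SummationDataset], fit: SummationFit
) -> tuple[float, int, float]:
    """Chi-square goodness of fit of a summation model to the TR means."""
    chi2 = 0.0
    n_points = 0
    for ds in datasets:
        finite = np.isfinite(ds.tr_mean)
        pred = fit.predict(ds.observer, ds.phases_deg[finite])
        if ds.tr_sem is not None:
            sigma = np.clip(ds.tr_sem[finite], 1e-6, None)
        else:
            sigma = np.full(finite.sum(), max(np.std(ds.tr_mean[finite]), 1e-6))
        chi2 += float(np.sum(((ds.tr_mean[finite] - pred) / sigma) ** 2))
        n_points += int(finite.sum())
    n_params = (1 + 2 * len(datasets)) if fit.model == "linear" else len(datasets)
    df = max(n_points - n_params, 1)
    return chi2, df, float(stats.chi2.sf(chi2, df))


def classify_summation(
    datasets: list[SummationDataset],
    alpha: float = 0.05,
    sqrt_form: bool = True,
) -> ClassificationResult:
    """Select probability vs. linear summation for one condition.

    Per observer, a repeated-measures ANOVA tests whether TR depends on
    phase (repeats are the blocks).  If the majority of observers show no
    phase dependence (p >= alpha), the condition is described by probability
    summation; otherwise by the vector-summation model with a global phase.
    Goodness of fit of the selected model is reported as a chi-square.
    """
    per_p: dict[str, float] = {}
    anovas: dict[str, RMAnovaResult] = {}
    for ds in datasets:
        if ds.tr_matrix is None:
            raise ValueError(f"observer {ds.observer}: classification needs per-repeat TRs")
        if np.allclose(ds.tr_matrix.var(axis=1), 0.0):
            raise ValueError(f"observer {ds.observer}: degenerate (zero-variance) repeats")
        res = rm_anova_oneway(ds.tr_matrix, pairwise=False)
        per_p[ds.observer] = res.p
        anovas[ds.observer] = res
    n_dep = sum(p < alpha for p in per_p.values())
    model = "linear" if n_dep > len(per_p) / 2 else "probability"
    prob_fit = fit_probability_summation(datasets)
    lin_fit = None
    if model == "linear":
        lin_fit = fit_global_summation(datasets, sqrt_form=sqrt_form)
        fit = lin_fit
    else:
        fit = prob_fit
    chi2, df, p = _gof_chisquare(datasets, fit)
    return ClassificationResult(
        model=model,
        per_observer_p=per_p,
        anovas=anovas,
        fit=fit,
        probability_fit=prob_fit,
        linear_fit=lin_fit,
        gof_chi2=chi2,
        gof_df=df,
        gof_p=p,
        gof_ok=p > alpha,
    )


# --------------------------------------------------------------------------- #
# summation squares (contrast-ratio paradigm)


def summation_square(
    combined_tu: tuple[float, float],
    initial_ratio: tuple[float, float] = (1.0, 1.0),
    tolerance: float = 0.05,
) -> dict:
    """Classify one summation-square point.

    ``combined_tu`` is the measured combined threshold in threshold units on
    the two axes (e.g. melanopsin, rod); ``initial_ratio`` is the nominal TU
    ratio at which the components were mixed.  Points within ``tolerance``
    of the initial-ratio lines show no interaction; higher thresholds mean
    inhibition, lower mean facilitation.  The deviation from the 45-degree
    diagonal indicates which pathway is affected more.
    """
    tu = np.asarray(combined_tu, dtype=float)
    init = np.asarray(initial_ratio, dtype=float)
    rel_dev = (tu - init) / init
    if np.all(np.abs(rel_dev) <= tolerance):
        label = "no interaction"
    elif np.mean(rel_dev) > 0:
        label = "inhibition"
    else:
        label = "facilitation"
    return {
        "label": label,
        "relative_deviation": rel_dev.tolist(),
        "diagonal_deviation": float((tu[0] - tu[1]) / np.sqrt(2.0)),
    }
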
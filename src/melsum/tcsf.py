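"""Temporal contrast sensitivity, adaptation and flicker-fusion analyses.

Sensitivity versus temporal frequency is summarised with a difference-of-
Gaussians (DoG) on log10 frequency,

    S(f) = A [ G(u; mu, sigma) - w G(u; mu, c sigma) ],  u = log10 f,

with fixed surround weight w and width ratio c and three free parameters
(amplitude A, centre mu, spread sigma); the surround turns the shape from
low-pass into band-pass.  Critical flicker frequency (CFF) is read off the
fitted curve at a criterion contrast; adaptation behaviour is summarised by
Weber (TVI) slopes W = d log dI / d log I and the Ferry-Porter line
CFF ~ log10 I.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "amplitude_sensitivity",
    "dog_sensitivity",
    "DoGFit",
    "fit_dog_tcsf",
    "cff_from_model",
    "TviFit",
    "tvi_weber_slope",
    "FerryPorterFit",
    "ferry_porter_fit",
]

DEFAULT_SURROUND_WEIGHT = 0.3
DEFAULT_SURROUND_RATIO = 2.0


def amplitude_sensitivity(threshold_contrast: float, illuminance_td: float) -> float:
    """Convert threshold contrast at an adaptation level to amplitude sensitivity.

    The threshold excitation swing is dI = C * I trolands; amplitude
    sensitivity is its reciprocal (troland^-1).  Contrast is fractional
    (0 < C <= 1).
    """
    C = np.asarray(threshold_contrast, dtype=float)
    if np.any(C <= 0) or np.any(C > 1):
        raise ValueError("threshold contrast must lie in (0, 1]")
    if illuminance_td <= 0:
        raise ValueError("illuminance must be positive")
    out = 1.0 / (C * illuminance_td)
    return float(out) if out.ndim == 0 else out


def dog_sensitivity(
    frequency_hz: np.ndarray | float,
    amplitude: float,
    center_logf: float,
    sigma: float,
    surround_weight: float = DEFAULT_SURROUND_WEIGHT,
    surround_ratio: float = DEFAULT_SURROUND_RATIO,
) -> np.ndarray | float:
    """DoG sensitivity model on log10 frequency."""
    u = np.log10(np.asarray(frequency_hz, dtype=float))
    d2 = (u - center_logf) ** 2
    s = amplitude * (
        np.exp(-d2 / (2.0 * sigma**2))
        - surround_weight * np.exp(-d2 / (2.0 * (surround_ratio * sigma) ** 2))
    )
    return float(s) if s.ndim == 0 else s


@dataclass(frozen=True)
class DoGFit:
    amplitude: float
    center_logf: float
    sigma: float
    surround_weight: float
    surround_ratio: float
    residual: float
    converged: bool

    def predict(self, frequency_hz: np.ndarray | float) -> np.ndarray | float:
        return dog_sensitivity(
            frequency_hz,
            self.amplitude,
            self.center_logf,
            self.sigma,
            self.surround_weight,
            self.surround_ratio,
        )


def fit_dog_tcsf(
    frequencies_hz: np.ndarray,
    sensitivities: np.ndarray,
    surround_weight: float = DEFAULT_SURROUND_WEIGHT,
    surround_ratio: float = DEFAULT_SURROUND_RATIO,
) -> DoGFit:
    """Damped least-squares DoG fit over (amplitude, centre, spread).

    Residuals are relative (model/data - 1) so that sensitivities spanning
    decades are weighted evenly.
    """
    f = np.asarray(frequencies_hz, dtype=float)
    s = np.asarray(sensitivities, dtype=float)
    if f.size < 5:
        raise ValueError("need at least 5 frequencies for a 3-parameter fit")
    if np.any(f <= 0) or np.any(s <= 0):
        raise ValueError("frequencies and sensitivities must be positive")

    def residuals(theta: np.ndarray) -> np.ndarray:
        A, mu, sigma = theta
        pred = dog_sensitivity(f, A, mu, sigma, surround_weight, surround_ratio)
        return pred / s - 1.0

    A0 = float(s.max() / max(1.0 - surround_weight, 1e-3))
    mu0 = float(np.log10(f[np.argmax(s)]))
    best = None
    for sigma0 in (0.3, 0.6, 1.0):
        res = optimize.least_squares(
            residuals,
            x0=[A0, mu0, sigma0],
            bounds=([1e-12, -3.0, 1e-3], [np.inf, 4.0, 5.0]),
            xtol=1e-12,
            ftol=1e-12,
        )
        if best is None or res.cost < best.cost:
            best = res
    assert best is not None
    if not best.success:
        raise RuntimeError(f"DoG fit did not converge (status={best.status})")
    A, mu, sigma = best.x
    return DoGFit(
        amplitude=float(A),
        center_logf=float(mu),
        sigma=float(sigma),
        surround_weight=surround_weight,
        surround_ratio=surround_ratio,
        residual=float(2.0 * best.cost),
        converged=bool(best.success),
    )


def cff_from_model(fit: DoGFit, criterion_contrast: float) -> float | None:
    """Critical flicker frequency at a criterion contrast.

    Returns the highest frequency at which the modelled contrast sensitivity
    still reaches 1/criterion, or None if the model never reaches it.
    """
    if not 0 < criterion_contrast <= 1:
        raise ValueError("criterion contrast must lie in (0, 1]")
    target = 1.0 / criterion_contrast
    grid = np.logspace(np.log10(0.05), np.log10(500.0), 4000)
    vals = np.asarray(fit.predict(grid))
    above = vals >= target
    if not above.any():
        return None
    last = int(np.max(np.nonzero(above)))
    if last == grid.size - 1:
        return float(grid[-1])
    lo, hi = grid[last], grid[last + 1]
    root = optimize.brentq(lambda f: fit.predict(f) - target, lo, hi)
    return float(root)


@dataclass(frozen=True)
class TviFit:
    """Branch-wise Weber slopes of a threshold-versus-intensity function."""

    slopes: tuple[float, ...]  # W per branch: d log10 dI / d log10 I
    intercepts: tuple[float, ...]
    branches: tuple[tuple[float, float], ...]  # (lo, hi) illuminance per branch
    breakpoint_td: float | None
    sse: float


def _branch_fit(log_i: np.ndarray, log_di: np.ndarray) -> tuple[float, float, float]:
    res = stats.linregress(log_i, log_di)
    pred = res.intercept + res.slope * log_i
    return float(res.slope), float(res.intercept), float(np.sum((log_di - pred) ** 2))


def tvi_weber_slope(
    illuminances_td: np.ndarray,
    thresholds_di_td: np.ndarray,
    branches: list[tuple[float, float]] | None = None,
) -> TviFit:
    """Weber slopes W of log10 dI against log10 I, per illumination branch.

    ``branches`` gives (lo, hi) illuminance ranges; with ``None`` a single
    branch is fitted, and with ``branches="auto"``-like behaviour use
    :func:`tvi_two_branch`.  Each branch needs at least two points.
    """
    I = np.asarray(illuminances_td, dtype=float)
    dI = np.asarray(thresholds_di_td, dtype=float)
    if np.any(I <= 0) or np.any(dI <= 0):
        raise ValueError("illuminances and thresholds must be positive")
    if branches is None:
        branches = [(float(I.min()), float(I.max()))]
    slopes, intercepts, ranges = [], [], []
    sse = 0.0
    for lo, hi in branches:
        mask = (I >= lo) & (I <= hi)
        if mask.sum() < 2:
            raise ValueError(f"branch ({lo}, {hi}) has fewer than two points")
        sl, ic, e = _branch_fit(np.log10(I[mask]), np.log10(dI[mask]))
        slopes.append(sl)
        intercepts.append(ic)
        ranges.append((lo, hi))
        sse += e
    return TviFit(tuple(slopes), tuple(intercepts), tuple(ranges), None, sse)


def tvi_two_branch(
    illuminances_td: np.ndarray, thresholds_di_td: np.ndarray
) -> TviFit:
    """Two-segment TVI fit with the breakpoint found by least squares."""
    I = np.asarray(illuminances_td, dtype=float)
    dI = np.asarray(thresholds_di_td, dtype=float)
    order = np.argsort(I)
    I, dI = I[order], dI[order]
    if I.size < 4:
        raise ValueError("need at least 4 points for a two-branch fit")
    best: TviFit | None = None
    for split in range(2, I.size - 1):
        lo_fit = _branch_fit(np.log10(I[:split]), np.log10(dI[:split]))
        hi_fit = _branch_fit(np.log10(I[split:]), np.log10(dI[split:]))
        sse = lo_fit[2] + hi_fit[2]
        if best is None or sse < best.sse:
            best = TviFit(
                slopes=(lo_fit[0], hi_fit[0]),
                intercepts=(lo_fit[1], hi_fit[1]),
                branches=(
                    (float(I[0]), float(I[split - 1])),
                    (float(I[split]), float(I[-1])),
                ),
                breakpoint_td=float(np.sqrt(I[split - 1] * I[split])),
                sse=sse,
            )
    assert best is not None
    return best


@dataclass(frozen=True)
class FerryPorterFit:
    slope: float  # Hz per log10 troland
    intercept: float
    rvalue: float

    def predict(self, illuminance_td: np.ndarray | float) -> np.ndarray | float:
        return self.intercept + self.slope * np.log10(illuminance_td)


def ferry_porter_fit(
    illuminances_td: np.ndarray, cff_hz: np.ndarray
) -> FerryPorterFit:
    """Linear fit of CFF against log illuminance (the Ferry-Porter law)."""
    I = np.asarray(illuminances_td, dtype=float)
    cff = np.asarray(cff_hz, dtype=float)
    if I.size < 2:
        raise ValueError("need at least two points")
    if np.any(I <= 0):
        raise ValueError("illuminances must be positive")
    x = np.log10(I)
    if np.ptp(x) == 0:
        raise ValueError("degenerate illuminance range")
    res = stats.linregress(x, cff)
    return FerryPorterFit(float(res.slope), float(res.intercept), float(res.rvalue))
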
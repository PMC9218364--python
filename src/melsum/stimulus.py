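"""Time-domain stimulus construction: sinusoids, phase-offset combinations, TWN.

All stimuli are defined in receptor-contrast space and rendered to per-frame
primary weights through the silent-substitution solver, so the excitation of
every non-targeted class is constant over time.  Durations follow the study
protocol: 1000 ms for frequencies >= 1 Hz, one full period below 1 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectral import CLASSES, PrimaryBasis, ReceptorSet
from .substitution import GamutError, excitation_matrix, solve_modulation

__all__ = [
    "Waveform",
    "CombinedCondition",
    "stimulus_duration_ms",
    "sinusoidal_condition",
    "combined_condition",
    "twn_frames",
    "recover_phase",
]


def stimulus_duration_ms(frequency_hz: float) -> float:
    """1000 ms for f >= 1 Hz, the reciprocal of the frequency below 1 Hz."""
    if frequency_hz <= 0:
        raise ValueError("frequency must be positive")
    return 1000.0 if frequency_hz >= 1.0 else 1000.0 / frequency_hz


@dataclass
class Waveform:
    """A rendered stimulus: per-frame primary weights and receptor excitations."""

    time_ms: np.ndarray  # (T,)
    primary_weights: np.ndarray  # (T, 5)
    excitations: np.ndarray  # (T, 5), troland-referenced
    background_excitations: np.ndarray  # (5,)
    frequency_hz: float | None
    phase_deg: float
    frame_rate_hz: float
    duration_ms: float
    metadata: dict = field(default_factory=dict)

    def contrast_trajectory(self) -> np.ndarray:
        """(T, 5) instantaneous contrast relative to the background."""
        return self.excitations / self.background_excitations[None, :] - 1.0

    def time_averaged_excitations(self) -> np.ndarray:
        return self.excitations.mean(axis=0)

    def achieved_contrast(self, class_key: str) -> float:
        """Michelson contrast amplitude recovered by quadrature projection."""
        amp, _ = recover_phase(self, class_key)
        return amp

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_ms": self.time_ms})
        for j, k in enumerate(CLASSES):
            df[f"weight_p{j + 1}"] = self.primary_weights[:, j]
        for j, k in enumerate(CLASSES):
            df[f"excitation_{k}"] = self.excitations[:, j]
        return df


def _frame_times(duration_ms: float, frame_rate_hz: float) -> np.ndarray:
    n = int(round(duration_ms / 1000.0 * frame_rate_hz))
    if n < 2:
        raise ValueError("duration and frame rate give fewer than two frames")
    return 1000.0 * np.arange(n) / frame_rate_hz


def sinusoidal_condition(
    primaries: PrimaryBasis,
    receptors: ReceptorSet,
    background_weights: np.ndarray,
    target_class: str,
    contrast: float,
    frequency_hz: float,
    phase_deg: float = 0.0,
    frame_rate_hz: float = 200.0,
) -> Waveform:
    """Photoreceptor-directed sinusoidal flicker.

    The targeted class's excitation follows background * (1 + C sin(2 pi f t
    + phase)); every other class is held at its background excitation.
    """
    if not 0.2 <= frequency_hz <= 70.0:
        raise ValueError("frequency must lie in the instrument range 0.2-70 Hz")
    if not 0 < abs(contrast) <= 1:
        raise ValueError("contrast must be non-zero with magnitude <= 1")
    targets = np.zeros(5)
    targets[CLASSES.index(target_class)] = contrast
    peak = solve_modulation(primaries, receptors, background_weights, targets)
    if peak.max_scale < 1.0:
        raise GamutError(
            f"{abs(contrast):.4f} {target_class}-contrast exceeds the gamut; "
            f"max feasible is {abs(contrast) * peak.max_scale:.4f}",
            max_feasible_contrast=abs(contrast) * peak.max_scale,
        )
    duration_ms = stimulus_duration_ms(frequency_hz)
    t = _frame_times(duration_ms, frame_rate_hz)
    s = np.sin(2.0 * np.pi * frequency_hz * t / 1000.0 + np.deg2rad(phase_deg))
    weights = peak.background_weights[None, :] + s[:, None] * peak.modulation[None, :]
    E = excitation_matrix(primaries, receptors)
    return Waveform(
        time_ms=t,
        primary_weights=weights,
        excitations=weights @ E.T,
        background_excitations=peak.background_excitations,
        frequency_hz=frequency_hz,
        phase_deg=phase_deg,
        frame_rate_hz=frame_rate_hz,
        duration_ms=duration_ms,
        metadata={"target_class": target_class, "contrast": contrast},
    )


@dataclass
class CombinedCondition:
    """Two photoreceptor-directed components with a relative phase offset.

    Component contrasts are specified in threshold units (multiples of the
    observer's own detection threshold per class) and rendered as percent
    Michelson contrast.
    """

    class_x: str
    class_y: str
    contrast_x: float  # Michelson fraction
    contrast_y: float
    tu_x: float
    tu_y: float
    phase_offset_deg: float
    frequency_hz: float
    waveform: Waveform


def combined_condition(
    primaries: PrimaryBasis,
    receptors: ReceptorSet,
    background_weights: np.ndarray,
    class_x: str,
    class_y: str,
    threshold_x_pct: float,
    threshold_y_pct: float,
    frequency_hz: float,
    phase_offset_deg: float,
    tu_ratio: tuple[float, float] = (1.0, 1.0),
    frame_rate_hz: float = 200.0,
) -> CombinedCondition:
    """Combined two-class modulation scaled in threshold units.

    With individual thresholds of e.g. 10 % (melanopsin) and 8 % (rod) and a
    1:1 TU ratio, the combination is 10 % i + 8 % R; the second component is
    phase-delayed by ``phase_offset_deg``.
    """
    if threshold_x_pct <= 0 or threshold_y_pct <= 0:
        raise ValueError("individual thresholds must be positive")
    cx = threshold_x_pct / 100.0 * tu_ratio[0]
    cy = threshold_y_pct / 100.0 * tu_ratio[1]
    tx = np.zeros(5)
    tx[CLASSES.index(class_x)] = cx
    ty = np.zeros(5)
    ty[CLASSES.index(class_y)] = cy
    sol_x = solve_modulation(primaries, receptors, background_weights, tx)
    sol_y = solve_modulation(primaries, receptors, background_weights, ty)
    duration_ms = stimulus_duration_ms(frequency_hz)
    t = _frame_times(duration_ms, frame_rate_hz)
    wt = 2.0 * np.pi * frequency_hz * t / 1000.0
    sx = np.sin(wt)
    sy = np.sin(wt - np.deg2rad(phase_offset_deg))
    weights = (
        sol_x.background_weights[None, :]
        + sx[:, None] * sol_x.modulation[None, :]
        + sy[:, None] * sol_y.modulation[None, :]
    )
    if weights.min() < -1e-12 or weights.max() > 1 + 1e-12:
        raise GamutError("combined modulation demand leaves the primary output range")
    E = excitation_matrix(primaries, receptors)
    wf = Waveform(
        time_ms=t,
        primary_weights=weights,
        excitations=weights @ E.T,
        background_excitations=sol_x.background_excitations,
        frequency_hz=frequency_hz,
        phase_deg=0.0,
        frame_rate_hz=frame_rate_hz,
        duration_ms=duration_ms,
        metadata={
            "class_x": class_x,
            "class_y": class_y,
            "phase_offset_deg": phase_offset_deg,
        },
    )
    return CombinedCondition(
        class_x=class_x,
        class_y=class_y,
        contrast_x=cx,
        contrast_y=cy,
        tu_x=tu_ratio[0],
        tu_y=tu_ratio[1],
        phase_offset_deg=phase_offset_deg,
        frequency_hz=frequency_hz,
        waveform=wf,
    )


def twn_frames(
    primaries: PrimaryBasis,
    receptors: ReceptorSet,
    background_weights: np.ndarray,
    duration_ms: float = 2000.0,
    frame_rate_hz: float = 50.0,
    max_contrast: float = 0.40,
    seed: int | np.random.Generator | None = None,
    max_resamples: int = 1000,
) -> Waveform:
    """Melanopsin-silent temporal white noise.

    Each frame draws independent uniform contrasts on (l, m, s, r) within
    +/- ``max_contrast`` while the melanopsin contrast is exactly zero, so
    the noise masks rod/cone intrusion without modulating melanopsin.
    Frames whose rendering would leave the primary range are resampled; the
    count is recorded in the metadata.
    """
    rng = np.random.default_rng(seed)
    E = excitation_matrix(primaries, receptors)
    w = np.asarray(background_weights, dtype=float)
    b = E @ w
    n = int(round(duration_ms / 1000.0 * frame_rate_hz))
    t = 1000.0 * np.arange(n) / frame_rate_hz
    weights = np.empty((n, 5))
    resamples = 0
    i_mel = CLASSES.index("i")
    for frame in range(n):
        for attempt in range(max_resamples + 1):
            c = rng.uniform(-max_contrast, max_contrast, size=5)
            c[i_mel] = 0.0
            dp = np.linalg.solve(E, c * b)
            cand = w + dp
            if cand.min() >= -1e-12 and cand.max() <= 1 + 1e-12:
                weights[frame] = cand
                resamples += attempt
                break
        else:
            raise GamutError(
                "could not render a TWN frame within the primary range; "
                "lower max_contrast or move the background off the range edge"
            )
    return Waveform(
        time_ms=t,
        primary_weights=weights,
        excitations=weights @ E.T,
        background_excitations=b,
        frequency_hz=None,
        phase_deg=0.0,
        frame_rate_hz=frame_rate_hz,
        duration_ms=duration_ms,
        metadata={"kind": "twn", "max_contrast": max_contrast, "resamples": resamples},
    )


def recover_phase(waveform: Waveform, class_key: str) -> tuple[float, float]:
    """Amplitude and phase of one class's contrast trajectory.

    Projects the trajectory onto quadrature sinusoids at the waveform's
    frequency; exact for pure sinusoids sampled over a whole number of
    cycles.  Returns (Michelson amplitude, phase in degrees in [0, 360)).
    """
    if waveform.frequency_hz is None:
        raise ValueError("waveform has no defining frequency")
    idx = CLASSES.index(class_key)
    x = waveform.contrast_trajectory()[:, idx]
    wt = 2.0 * np.pi * waveform.frequency_hz * waveform.time_ms / 1000.0
    a = 2.0 * np.mean(x * np.sin(wt))
    b = 2.0 * np.mean(x * np.cos(wt))
    amp = float(np.hypot(a, b))
    phase = float(np.rad2deg(np.arctan2(b, a)) % 360.0)
    return amp, phase
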
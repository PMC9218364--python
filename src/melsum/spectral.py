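"""Spectral front end: primary SPDs, photoreceptor sensitivities and troland units.

The five-primary photostimulator is modelled by Gaussian spectral power
distributions (peak wavelength and full width at half maximum are the only
published characteristics of the LED + interference-filter primaries).
Photoreceptor spectral sensitivities for the five human classes
(L-, M-, S-cones, rods, melanopsin) are generated from the Govardovskii A1
visual-pigment nomogram and normalised so that an equal-energy spectrum at
1 photopic troland produces the canonical excitation vector

    (l, m, s, r, i) = (2/3, 1/3, 1, 1, 1),

i.e. photopic retinal illuminance is *defined* as the sum of L- and M-cone
excitations with a 2:1 L:M weighting.  All downstream excitation values are
therefore troland-referenced and template-independent at the level of the
normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CLASSES",
    "CLASS_NAMES",
    "DEFAULT_LAMBDA_MAX",
    "CANONICAL_EE_VECTOR",
    "PRIMARY_PEAKS_NM",
    "PRIMARY_FWHM_NM",
    "SpectralFunction",
    "PrimaryBasis",
    "ReceptorSet",
    "ExcitationVector",
    "BleachModel",
    "default_grid",
    "govardovskii_a1",
    "make_primary_spd",
    "default_primary_basis",
    "build_receptor_set",
    "excitation_vector",
    "equal_energy_spd",
    "excitations_at_td",
    "scotopic_from_photopic",
    "steady_state_bleach",
]

#: Photoreceptor class keys, in the fixed ordering used throughout the package.
CLASSES: tuple[str, ...] = ("l", "m", "s", "r", "i")
CLASS_NAMES = {
    "l": "L-cone",
    "m": "M-cone",
    "s": "S-cone",
    "r": "rod",
    "i": "melanopsin",
}

#: Pigment template peak wavelengths (nm) per class.
DEFAULT_LAMBDA_MAX = {"l": 558.0, "m": 530.0, "s": 420.0, "r": 500.0, "i": 480.0}

#: Excitations of an equal-energy spectrum at 1 photopic troland.
CANONICAL_EE_VECTOR = np.array([2.0 / 3.0, 1.0 / 3.0, 1.0, 1.0, 1.0])

#: Five-primary photostimulator: peak nm / FWHM nm.
PRIMARY_PEAKS_NM = (456.0, 488.0, 540.0, 594.0, 633.0)
PRIMARY_FWHM_NM = (10.0, 11.0, 10.0, 14.0, 15.0)

#: Default anchor pair tying photopic to scotopic trolands for the adapting
#: background chromaticity (orange background: 200 Ph Td <-> 498 Sc Td).
DEFAULT_SCOTOPIC_ANCHOR = (200.0, 498.0)

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...


def default_grid(start: float = 380.0, stop: float = 780.0, step: float = 1.0) -> np.ndarray:
    """Standard colorimetric wavelength grid, 380-780 nm at 1 nm."""
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


@dataclass(frozen=True)
class SpectralFunction:
    """A sampled spectral function (SPD or sensitivity) on a uniform nm grid."""

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or v.shape != wl.shape:
            raise ValueError("wavelengths and values must be 1-D arrays of equal length")
        steps = np.diff(wl)
        if wl.size < 2 or np.any(steps <= 0):
            raise ValueError("wavelength grid must be strictly ascending")
        if not np.allclose(steps, steps[0]):
            raise ValueError("wavelength grid must be uniform")
        if np.any(v < 0):
            raise ValueError("spectral values must be non-negative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", v)

    @property
    def step(self) -> float:
        return float(self.wavelengths[1] - self.wavelengths[0])

    def same_grid(self, other: "SpectralFunction") -> bool:
        return self.wavelengths.shape == other.wavelengths.shape and np.array_equal(
            self.wavelengths, other.wavelengths
        )

    def scaled(self, factor: float) -> "SpectralFunction":
        return SpectralFunction(self.wavelengths, self.values * factor)


def _require_same_grid(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape or not np.array_equal(a, b):
        raise ValueError("spectral functions are defined on different wavelength grids")


def govardovskii_a1(wavelengths: np.ndarray, lambda_max: float) -> np.ndarray:
    """Govardovskii et al. A1 visual-pigment nomogram, peak-normalised.

    Alpha band plus beta band; returns relative quantal sensitivity with unit
    peak.  Valid for lambda_max roughly 350-600 nm, which covers all five
    human photopigments.
    """
    wl = np.asarray(wavelengths, dtype=float)
    x = lambda_max / wl
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    lmb = 189.0 + 0.315 * lambda_max  # beta-band peak
    b = -40.5 + 0.195 * lambda_max  # beta-band width
    beta = 0.26 * np.exp(-(((wl - lmb) / b) ** 2))
    s = alpha + beta
    return s / s.max()


def make_primary_spd(
    peak_nm: float, fwhm_nm: float, grid: np.ndarray | None = None
) -> SpectralFunction:
    """Gaussian-shaped primary SPD with unit peak and half-maximum at peak +/- fwhm/2."""
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    if not (grid[0] <= peak_nm <= grid[-1]):
        raise ValueError(f"primary peak {peak_nm} nm lies outside the grid "
                         f"[{grid[0]}, {grid[-1]}] nm")
    if fwhm_nm <= 0:
        raise ValueError("fwhm must be positive")
    sigma = fwhm_nm / _FWHM_TO_SIGMA
    values = np.exp(-0.5 * ((grid - peak_nm) / sigma) ** 2)
    return SpectralFunction(grid, values)


@dataclass(frozen=True)
class PrimaryBasis:
    """The five instrument primaries on a common grid."""

    spds: tuple[SpectralFunction, ...]
    peaks_nm: tuple[float, ...] = PRIMARY_PEAKS_NM
    fwhm_nm: tuple[float, ...] = PRIMARY_FWHM_NM

    def __post_init__(self) -> None:
        if len(self.spds) != 5:
            raise ValueError("a primary basis needs exactly five SPDs")
        for s in self.spds[1:]:
            if not self.spds[0].same_grid(s):
                raise ValueError("all primaries must share one wavelength grid")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.spds[0].wavelengths

    def as_matrix(self) -> np.ndarray:
        """(n_wavelength, 5) matrix of SPD values."""
        return np.stack([s.values for s in self.spds], axis=1)

    def scaled(self, factors: np.ndarray) -> "PrimaryBasis":
        factors = np.asarray(factors, dtype=float)
        return PrimaryBasis(
            tuple(s.scaled(f) for s, f in zip(self.spds, factors)),
            self.peaks_nm,
            self.fwhm_nm,
        )


def default_primary_basis(grid: np.ndarray | None = None) -> PrimaryBasis:
    """The photostimulator's five primaries (456/488/540/594/633 nm)."""
    if grid is None:
        grid = default_grid()
    spds = tuple(
        make_primary_spd(p, w, grid) for p, w in zip(PRIMARY_PEAKS_NM, PRIMARY_FWHM_NM)
    )
    return PrimaryBasis(spds)


@dataclass(frozen=True)
class ReceptorSet:
    """Five photoreceptor spectral sensitivities with troland normalisation.

    ``sensitivities`` holds the peak-normalised curves, one row per class in
    :data:`CLASSES` order.  ``norms`` are the per-class constants that map the
    integral of (sensitivity x SPD) to troland-referenced excitation;
    ``observer_scaling`` is an optional per-observer diagonal correction (the
    output of heterochromatic flicker photometry), defaulting to ones.
    """

    wavelengths: np.ndarray
    sensitivities: np.ndarray  # (5, n_wavelength)
    norms: np.ndarray  # (5,)
    lambda_max: tuple[float, ...]
    observer_scaling: np.ndarray = field(default_factory=lambda: np.ones(5))

    def __post_init__(self) -> None:
        if self.sensitivities.shape != (5, self.wavelengths.size):
            raise ValueError("sensitivities must be (5, n_wavelength)")
        if np.any(self.sensitivities < 0):
            raise ValueError("sensitivities must be non-negative")

    @property
    def weights(self) -> np.ndarray:
        """(5, n) rows of normalisation- and observer-scaled sensitivity."""
        return (self.norms * self.observer_scaling)[:, None] * self.sensitivities

    def excite(self, spd_values: np.ndarray) -> np.ndarray:
        """Troland-referenced excitations (5,) of an SPD given as values on the grid."""
        return np.trapezoid(self.weights * spd_values[None, :], self.wavelengths, axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"wavelength_nm": self.wavelengths})
        for k, row in zip(CLASSES, self.sensitivities):
            df[k] = row
        return df


def build_receptor_set(
    grid: np.ndarray | None = None,
    lambda_max: dict[str, float] | None = None,
    template: str = "govardovskii",
    observer_scaling: np.ndarray | None = None,
) -> ReceptorSet:
    """Generate the five-class receptor set, normalised to the canonical vector.

    Whatever the template, the normalisation constants are chosen so that a
    flat (equal-energy) spectrum at 1 photopic troland excites the classes by
    exactly (2/3, 1/3, 1, 1, 1).
    """
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    lmax = dict(DEFAULT_LAMBDA_MAX)
    if lambda_max:
        lmax.update(lambda_max)
    for k, v in lmax.items():
        if not (grid[0] <= v <= grid[-1]):
            raise ValueError(f"lambda_max for class {k!r} ({v} nm) outside the grid")
    if template != "govardovskii":
        raise ValueError(f"unknown template family {template!r}")
    sens = np.stack([govardovskii_a1(grid, lmax[k]) for k in CLASSES])
    # The flat spectrum that *defines* 1 Ph Td has unit spectral value per nm.
    raw = np.trapezoid(sens, grid, axis=1)
    norms = CANONICAL_EE_VECTOR / raw
    scaling = np.ones(5) if observer_scaling is None else np.asarray(observer_scaling, float)
    return ReceptorSet(grid, sens, norms, tuple(lmax[k] for k in CLASSES), scaling)


@dataclass(frozen=True)
class ExcitationVector:
    """Per-class troland-referenced excitations."""

    l: float
    m: float
    s: float
    r: float
    i: float

    @property
    def photopic_td(self) -> float:
        """Photopic retinal illuminance: the sum of L- and M-cone excitations."""
        return self.l + self.m

    def as_array(self) -> np.ndarray:
        return np.array([self.l, self.m, self.s, self.r, self.i])

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "ExcitationVector":
        return cls(*(float(x) for x in np.asarray(arr, dtype=float)))


def excitation_vector(spd: SpectralFunction, receptors: ReceptorSet) -> ExcitationVector:
    """Excitations of an SPD; a linear functional of the spectrum per class."""
    _require_same_grid(spd.wavelengths, receptors.wavelengths)
    return ExcitationVector.from_array(receptors.excite(spd.values))


def equal_energy_spd(
    grid: np.ndarray | None = None,
    photopic_td: float = 1.0,
    receptors: ReceptorSet | None = None,
) -> SpectralFunction:
    """Flat spectrum scaled to the requested photopic troland value."""
    if receptors is not None:
        grid = receptors.wavelengths
    elif grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    flat = SpectralFunction(grid, np.ones_like(grid))
    if receptors is None:
        receptors = build_receptor_set(grid)
    exc = excitation_vector(flat, receptors)
    return flat.scaled(photopic_td / exc.photopic_td)


def excitations_at_td(relative: dict[str, float] | np.ndarray, photopic_td: float) -> ExcitationVector:
    """Scale relative per-class excitations (specified at 1 Ph Td) to a light level.

    The relative vector is assumed to be troland-normalised, i.e. l + m = 1.
    """
    if isinstance(relative, dict):
        rel = np.array([relative[k] for k in CLASSES], dtype=float)
    else:
        rel = np.asarray(relative, dtype=float)
    return ExcitationVector.from_array(rel * photopic_td)


def scotopic_from_photopic(
    photopic_td: float, anchor: tuple[float, float] = DEFAULT_SCOTOPIC_ANCHOR
) -> float:
    """Scotopic trolands for a background of fixed chromaticity.

    For a fixed spectrum, scotopic and photopic retinal illuminance are exactly
    proportional; the proportionality constant is supplied as one anchor pair
    (default 200 Ph Td <-> 498 Sc Td for the orange adapting field).
    """
    if photopic_td < 0:
        raise ValueError("photopic troland value must be non-negative")
    ph0, sc0 = anchor
    if ph0 <= 0 or sc0 <= 0:
        raise ValueError("anchor pair must be positive")
    return photopic_td * sc0 / ph0


@dataclass(frozen=True)
class BleachModel:
    """Saturating steady-state photopigment bleach, p = I / (I + I0).

    ``half_bleach_td`` is the retinal illuminance at which half the pigment is
    bleached in the steady state; the default 10**4.5 Ph Td reproduces the
    canonical rhodopsin values for indoor through high-photopic lights.
    """

    half_bleach_td: float = 10.0 ** 4.5

    def __post_init__(self) -> None:
        if self.half_bleach_td <= 0:
            raise ValueError("half-bleach constant must be positive")


def steady_state_bleach(illuminance_td: float, model: BleachModel | None = None) -> float:
    """Fraction of pigment bleached at steady state for a given illuminance."""
    if model is None:
        model = BleachModel()
    I = np.asarray(illuminance_td, dtype=float)
    if np.any(I < 0):
        raise ValueError("illuminance must be non-negative")
    out = I / (I + model.half_bleach_td)
    return float(out) if out.ndim == 0 else out
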
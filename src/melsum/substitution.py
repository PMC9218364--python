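"""Silent-substitution solver for the five-primary photostimulator.

With five independent primaries and five photoreceptor classes, the linear
system  E @ dp = c * (E @ w)  has a unique solution: ``E`` is the 5x5
class-by-primary excitation matrix, ``w`` the background primary weights,
``c`` the requested signed Michelson contrast per class and ``dp`` the
primary-domain modulation.  Up to four classes can be silenced exactly for
the nominal observer; what a *perturbed* observer (shifted pigment peaks,
individual pre-receptoral filtering) sees instead is the residual intrusion.

Primary outputs are normalised to [0, 1]; infeasible modulations are flagged,
never clipped, since clipping would break the silencing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral import CLASSES, PrimaryBasis, ReceptorSet, build_receptor_set

__all__ = [
    "GamutError",
    "contrast_vector",
    "excitation_matrix",
    "ModulationSolution",
    "solve_modulation",
    "residual_intrusion",
    "gamut_limit",
    "normalize_primaries_to_background",
    "nearest_feasible_background",
    "optimize_background",
    "study_background",
    "BACKGROUND_RELATIVE_EXCITATIONS",
    "intrusion_monte_carlo",
]

_SINGULAR_COND = 1e12


class GamutError(ValueError):
    """A requested modulation leaves the primary output range."""

    def __init__(self, message: str, max_feasible_contrast: float | None = None):
        super().__init__(message)
        self.max_feasible_contrast = max_feasible_contrast


def contrast_vector(**contrasts: float) -> np.ndarray:
    """Build a signed per-class Michelson contrast vector.

    Keyword names are class keys (l, m, s, r, i); unspecified classes are
    silenced (contrast 0).  ``contrast_vector(i=0.17)`` is a 17 % melanopsin-
    directed stimulus silencing rods and all cones.
    """
    vec = np.zeros(5)
    for key, value in contrasts.items():
        if key not in CLASSES:
            raise KeyError(f"unknown photoreceptor class {key!r}")
        if abs(value) > 1:
            raise ValueError("Michelson contrast magnitude cannot exceed 1")
        vec[CLASSES.index(key)] = value
    return vec


def excitation_matrix(primaries: PrimaryBasis, receptors: ReceptorSet) -> np.ndarray:
    """5x5 matrix: entry (class, primary) = excitation of class by a unit-weight primary."""
    if not np.array_equal(primaries.wavelengths, receptors.wavelengths):
        raise ValueError("primaries and receptors are on different wavelength grids")
    E = np.stack([receptors.excite(s.values) for s in primaries.spds], axis=1)
    cond = np.linalg.cond(E)
    if not np.isfinite(cond) or cond > _SINGULAR_COND:
        # Identify the most collinear primary pair for the error message.
        cols = E / np.linalg.norm(E, axis=0, keepdims=True)
        G = cols.T @ cols
        np.fill_diagonal(G, 0.0)
        j, k = np.unravel_index(np.argmax(np.abs(G)), G.shape)
        raise np.linalg.LinAlgError(
            f"excitation matrix is numerically singular (cond={cond:.3g}); "
            f"primaries {primaries.peaks_nm[j]} nm and {primaries.peaks_nm[k]} nm "
            "are near-collinear in receptor space"
        )
    return E


@dataclass(frozen=True)
class ModulationSolution:
    """Primary-domain solution realising a requested receptor-contrast vector."""

    background_weights: np.ndarray  # (5,) in [0, 1]
    modulation: np.ndarray  # (5,) signed primary swing
    targets: np.ndarray  # requested signed contrasts (5,)
    achieved: np.ndarray  # achieved signed contrasts (5,)
    residual: np.ndarray  # achieved contrast on silenced classes (5,), 0 on targeted
    feasible: bool
    max_scale: float  # largest multiplier keeping primaries within [0, 1]
    condition_number: float
    background_excitations: np.ndarray  # (5,)

    @property
    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        w, dp = self.background_weights, self.modulation
        return w + dp, w - dp

    def summary(self) -> dict:
        return {
            "targets": dict(zip(CLASSES, self.targets.tolist())),
            "achieved": dict(zip(CLASSES, self.achieved.tolist())),
            "residual": dict(zip(CLASSES, self.residual.tolist())),
            "modulation": self.modulation.tolist(),
            "background_weights": self.background_weights.tolist(),
            "feasible": self.feasible,
            "max_scale": self.max_scale,
            "condition_number": self.condition_number,
        }


def _michelson(exc_hi: np.ndarray, exc_lo: np.ndarray) -> np.ndarray:
    denom = exc_hi + exc_lo
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom != 0, (exc_hi - exc_lo) / denom, 0.0)
    return c


def solve_modulation(
    primaries: PrimaryBasis,
    receptors: ReceptorSet,
    background_weights: np.ndarray,
    targets: np.ndarray,
) -> ModulationSolution:
    """Solve for the primary modulation producing the requested contrasts.

    The two waveform endpoints are ``w + dp`` and ``w - dp``; achieved signed
    Michelson contrast per class is (Emax - Emin)/(Emax + Emin) evaluated on
    those endpoints, which equals the request exactly for the nominal observer.
    """
    w = np.asarray(background_weights, dtype=float)
    c = np.asarray(targets, dtype=float)
    if w.shape != (5,) or c.shape != (5,):
        raise ValueError("background weights and targets must be 5-vectors")
    if np.any(w < 0) or np.any(w > 1):
        raise ValueError("background weights must lie in [0, 1]")
    E = excitation_matrix(primaries, receptors)
    b = E @ w
    dp = np.linalg.solve(E, c * b)
    hi, lo = w + dp, w - dp
    feasible = bool(np.all(hi <= 1 + 1e-12) and np.all(lo >= -1e-12)
                    and np.all(hi >= -1e-12) and np.all(lo <= 1 + 1e-12))
    with np.errstate(divide="ignore"):
        room = np.where(
            np.abs(dp) > 0,
            np.minimum((1.0 - w) / np.abs(dp), w / np.abs(dp)),
            np.inf,
        )
    max_scale = float(np.min(room))
    achieved = _michelson(E @ hi, E @ lo)
    silenced = c == 0
    residual = np.where(silenced, achieved, 0.0)
    return ModulationSolution(
        background_weights=w,
        modulation=dp,
        targets=c,
        achieved=achieved,
        residual=residual,
        feasible=feasible,
        max_scale=max_scale,
        condition_number=float(np.linalg.cond(E)),
        background_excitations=b,
    )


def residual_intrusion(
    primaries: PrimaryBasis,
    solution: ModulationSolution,
    perturbed_receptors: ReceptorSet,
) -> np.ndarray:
    """Signed contrasts a perturbed observer sees for a nominal-observer solution."""
    E = excitation_matrix(primaries, perturbed_receptors)
    hi, lo = solution.endpoints
    return _michelson(E @ hi, E @ lo)


def gamut_limit(
    primaries: PrimaryBasis,
    receptors: ReceptorSet,
    background_weights: np.ndarray,
    direction: np.ndarray,
) -> float:
    """Largest achievable contrast multiple of a receptor-contrast direction.

    Returns the largest scalar t such that the modulation realising
    t * direction keeps every primary within [0, 1] and every class contrast
    within the physical bound |C| <= 1.
    """
    direction = np.asarray(direction, dtype=float)
    if np.all(direction == 0):
        raise ValueError("direction must be a non-zero contrast vector")
    sol = solve_modulation(primaries, receptors, background_weights, direction)
    t_primary = sol.max_scale
    t_contrast = 1.0 / np.max(np.abs(direction))
    return float(min(t_primary, t_contrast))


def normalize_primaries_to_background(
    primaries: PrimaryBasis,
    receptors: ReceptorSet,
    background_excitations: np.ndarray,
    headroom: float = 0.5,
) -> tuple[PrimaryBasis, np.ndarray]:
    """Rescale primary outputs so a target background sits mid-range.

    Solves for the raw primary weights that realise the requested background
    excitations, then rescales each primary's full-range output so those
    weights equal ``headroom`` (default 0.5, maximising symmetric modulation
    room).  This mirrors how an instrument's per-primary maximum output is
    chosen around its working point.  Returns the rescaled basis and the new
    background weight vector (all equal to ``headroom``).
    """
    if not 0 < headroom < 1:
        raise ValueError("headroom must lie strictly between 0 and 1")
    E = excitation_matrix(primaries, receptors)
    w_raw = np.linalg.solve(E, np.asarray(background_excitations, dtype=float))
    if np.any(w_raw <= 0):
        raise ValueError(
            "background is not realisable with non-negative primary weights: "
            f"{w_raw.tolist()}"
        )
    scaled = primaries.scaled(w_raw / headroom)
    return scaled, np.full(5, headroom)


#: Relative photoreceptor excitations (l, m, s, r, i) of the orange adapting
#: background that maximises the instrument gamut, at photopic_td = 1.
BACKGROUND_RELATIVE_EXCITATIONS = np.array([0.755, 0.244, 0.107, 0.345, 0.265])


def nearest_feasible_background(
    primaries: PrimaryBasis,
    receptors: ReceptorSet,
    target_excitations: np.ndarray,
    photopic_td: float | None = None,
    headroom: float = 0.5,
) -> tuple[PrimaryBasis, np.ndarray, np.ndarray]:
    """Closest realisable background to a target excitation vector.

    The exact primary weights for an arbitrary chromaticity can be negative
    (not all excitation ratios are inside the device gamut for a given
    receptor model); this solves the non-negative least-squares problem
    instead, optionally rescales to an exact photopic troland value, and
    normalises the primaries so the background sits at ``headroom`` of every
    primary's range.  Returns (scaled basis, background weights, achieved
    excitations).
    """
    from scipy.optimize import nnls

    E = excitation_matrix(primaries, receptors)
    w_raw, _ = nnls(E, np.asarray(target_excitations, dtype=float))
    achieved = E @ w_raw
    if photopic_td is not None:
        scale = photopic_td / (achieved[0] + achieved[1])
        w_raw = w_raw * scale
        achieved = achieved * scale
    w_raw = np.clip(w_raw, 1e-9, None)  # keep every primary modulable
    scaled = primaries.scaled(w_raw / headroom)
    return scaled, np.full(5, headroom), achieved


def optimize_background(
    primaries: PrimaryBasis,
    receptors: ReceptorSet,
    directions: tuple[str, ...] = ("i", "r", "lms"),
    n_starts: int = 8,
    seed: int = 12345,
) -> np.ndarray:
    """Background primary weights maximising the isolating-contrast gamut.

    Maximises the smallest achievable single-class contrast over the given
    stimulus directions ("lms" is the joint in-phase cone direction),
    assuming each primary's full output is normalised to twice its
    background contribution (background mid-range).  This mirrors how the
    instrument's adapting chromaticity was chosen; under this receptor
    model the optimum is an orange-appearing background.  Returns raw
    weights scaled so the background photopic illuminance is 1 Td.
    """
    from scipy.optimize import minimize

    E = excitation_matrix(primaries, receptors)
    Einv = np.linalg.inv(E)
    masks = {
        "l": [1.0, 0, 0, 0, 0],
        "m": [0, 1.0, 0, 0, 0],
        "s": [0, 0, 1.0, 0, 0],
        "r": [0, 0, 0, 1.0, 0],
        "i": [0, 0, 0, 0, 1.0],
        "lms": [1.0, 1.0, 1.0, 0, 0],
    }
    mats = [Einv @ np.diag(masks[d]) @ E for d in directions]

    def neg_min_gamut(logw: np.ndarray) -> float:
        w = np.exp(logw)
        worst = np.inf
        for A in mats:
            dp = A @ w
            lim = np.min(np.where(np.abs(dp) > 1e-12, w / np.abs(dp), np.inf))
            worst = min(worst, lim)
        return -worst

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_starts):
        res = minimize(
            neg_min_gamut,
            rng.normal(0.0, 1.0, 5),
            method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-9, "fatol": 1e-11},
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    w = np.exp(best.x)
    b = E @ w
    return w / (b[0] + b[1])


def study_background(
    photopic_td: float = 200.0,
    grid: np.ndarray | None = None,
) -> tuple[PrimaryBasis, ReceptorSet, np.ndarray]:
    """The package's standard working point at a given light level.

    Builds the default primaries and receptors, places the gamut-maximising
    background at the requested photopic illuminance and normalises every
    primary's output range so the background sits mid-range.  Returns
    (primaries, receptors, background weights); the weights are all 0.5.
    """
    receptors = build_receptor_set(grid)
    from .spectral import default_primary_basis

    primaries = default_primary_basis(receptors.wavelengths)
    w_raw = optimize_background(primaries, receptors) * photopic_td
    scaled = primaries.scaled(w_raw / 0.5)
    return scaled, receptors, np.full(5, 0.5)


def intrusion_monte_carlo(
    primaries: PrimaryBasis,
    receptors: ReceptorSet,
    background_weights: np.ndarray,
    targets: np.ndarray,
    n_draws: int = 200,
    lambda_max_sd_nm: float = 1.5,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Distribution of residual contrasts under observer spectral variability.

    Perturbs every class's pigment peak wavelength by independent Gaussian
    draws (sd ``lambda_max_sd_nm``), rebuilds the perturbed receptor set and
    evaluates the contrasts the perturbed observer receives from the nominal
    solution.  Returns an (n_draws, 5) array of signed contrasts in class
    order; summarise the silenced-class columns against the instrument's
    intrusion tolerances (e.g. rod <= 0.3 %, cone <= 1.5 %).
    """
    rng = np.random.default_rng(rng)
    sol = solve_modulation(primaries, receptors, background_weights, targets)
    nominal_lmax = dict(zip(CLASSES, receptors.lambda_max))
    out = np.empty((n_draws, 5))
    for d in range(n_draws):
        shifted = {
            k: v + rng.normal(0.0, lambda_max_sd_nm) for k, v in nominal_lmax.items()
        }
        pert = build_receptor_set(receptors.wavelengths, lambda_max=shifted)
        out[d] = residual_intrusion(primaries, sol, pert)
    return out
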
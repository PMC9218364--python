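"""Silent-substitution solver: exactness, silencing, gamut and intrusion."""

import numpy as np
import pytest

from melsum import spectral as sp
from melsum import substitution as sub


def _toy_basis(grid):
    """Five narrow, nearly disjoint primaries for near-diagonal excitation."""
    peaks = (430.0, 480.0, 530.0, 580.0, 630.0)
    spds = tuple(sp.make_primary_spd(p, 4.0, grid) for p in peaks)
    return sp.PrimaryBasis(spds, peaks, (4.0,) * 5)


class TestExcitationMatrix:
    def test_entries_nonnegative_and_condition_finite(self, primaries, receptors):
        E = sub.excitation_matrix(primaries, receptors)
        assert np.all(E >= 0)
        assert np.isfinite(np.linalg.cond(E))

    def test_duplicate_primary_reported_as_singular(self, grid, receptors):
        spd = sp.make_primary_spd(540.0, 10.0, grid)
        basis = sp.PrimaryBasis((spd,) * 5, (540.0,) * 5, (10.0,) * 5)
        with pytest.raises(np.linalg.LinAlgError, match="540"):
            sub.excitation_matrix(basis, receptors)


class TestSolveModulation:
    def test_zero_targets_give_zero_modulation(self, working_point):
        primaries, receptors, w = working_point
        sol = sub.solve_modulation(primaries, receptors, w, np.zeros(5))
        np.testing.assert_allclose(sol.modulation, 0.0, atol=1e-15)
        assert sol.feasible

    def test_melanopsin_isolation_silences_other_classes(self, working_point):
        primaries, receptors, w = working_point
        sol = sub.solve_modulation(
            primaries, receptors, w, sub.contrast_vector(i=0.17)
        )
        assert sol.feasible
        assert np.abs(sol.residual).max() < 1e-9
        assert sol.achieved[sp.CLASSES.index("i")] == pytest.approx(0.17, abs=1e-10)

    def test_round_trip_contrast_of_endpoints(self, working_point, rng):
        primaries, receptors, w = working_point
        targets = sub.contrast_vector(r=0.1, i=-0.05)
        sol = sub.solve_modulation(primaries, receptors, w, targets)
        E = sub.excitation_matrix(primaries, receptors)
        hi, lo = sol.endpoints
        ach = (E @ hi - E @ lo) / (E @ hi + E @ lo)
        np.testing.assert_allclose(ach, targets, atol=1e-10)

    def test_matches_least_squares_oracle_on_random_systems(self, rng):
        # brute-force oracle: lstsq on random invertible systems
        for _ in range(200):
            E = rng.uniform(0.1, 1.0, (5, 5)) + np.eye(5)
            w = rng.uniform(0.2, 0.8, 5)
            c = rng.uniform(-0.2, 0.2, 5)
            b = E @ w
            dp_oracle, *_ = np.linalg.lstsq(E, c * b, rcond=None)
            dp = np.linalg.solve(E, c * b)
            np.testing.assert_allclose(dp, dp_oracle, rtol=1e-8, atol=1e-12)

    def test_superposition_of_targets(self, working_point):
        primaries, receptors, w = working_point
        a = sub.contrast_vector(i=0.1)
        b = sub.contrast_vector(r=0.05)
        sol_a = sub.solve_modulation(primaries, receptors, w, a)
        sol_b = sub.solve_modulation(primaries, receptors, w, b)
        sol_ab = sub.solve_modulation(primaries, receptors, w, a + b)
        np.testing.assert_allclose(
            sol_ab.modulation, sol_a.modulation + sol_b.modulation, atol=1e-12
        )

    def test_infeasible_flagged_not_clipped(self, working_point):
        primaries, receptors, w = working_point
        sol = sub.solve_modulation(
            primaries, receptors, w, sub.contrast_vector(r=0.9)
        )
        assert not sol.feasible
        assert sol.max_scale < 1.0
        hi, lo = sol.endpoints
        assert hi.max() > 1.0 or lo.min() < 0.0  # untouched, reported as-is


class TestResidualIntrusion:
    def test_zero_perturbation_equals_nominal_residuals(self, working_point):
        primaries, receptors, w = working_point
        sol = sub.solve_modulation(primaries, receptors, w, sub.contrast_vector(i=0.17))
        intr = sub.residual_intrusion(primaries, sol, receptors)
        assert np.abs(intr[:4]).max() < 1e-9

    def test_supplemental_rod_contrast_is_returned(self, working_point):
        primaries, receptors, w = working_point
        sol = sub.solve_modulation(
            primaries, receptors, w, sub.contrast_vector(i=0.17, r=0.03)
        )
        intr = sub.residual_intrusion(primaries, sol, receptors)
        assert intr[sp.CLASSES.index("r")] == pytest.approx(0.03, abs=1e-10)

    def test_monte_carlo_rod_intrusion_is_small(self, working_point):
        primaries, receptors, w = working_point
        draws = sub.intrusion_monte_carlo(
            primaries, receptors, w, sub.contrast_vector(i=0.17),
            n_draws=40, lambda_max_sd_nm=1.0, rng=3,
        )
        rod = np.abs(draws[:, sp.CLASSES.index("r")])
        # rod intrusion in a melanopsin-directed stimulus stays at the
        # sub-percent level for percent-scale pigment-peak variability
        assert np.median(rod) < 0.02
        assert rod.max() < 0.10


class TestGamut:
    def test_toy_system_limit_set_by_most_demanding_primary(self, grid):
        basis = _toy_basis(grid)
        receptors = sp.build_receptor_set(grid)
        w = np.full(5, 0.5)
        lim = sub.gamut_limit(basis, receptors, w, sub.contrast_vector(i=0.2))
        sol = sub.solve_modulation(basis, receptors, w, sub.contrast_vector(i=0.2))
        expected = np.min(0.5 / np.abs(sol.modulation[np.abs(sol.modulation) > 0]))
        assert lim == pytest.approx(min(expected, 1.0 / 0.2))

    def test_limit_shrinks_near_range_boundary(self, working_point):
        primaries, receptors, _ = working_point
        direction = sub.contrast_vector(i=0.1)
        lim_mid = sub.gamut_limit(primaries, receptors, np.full(5, 0.5), direction)
        lim_edge = sub.gamut_limit(primaries, receptors, np.full(5, 0.95), direction)
        assert lim_edge < lim_mid

    def test_inverse_homogeneity_in_demand(self, working_point):
        # the feasible multiplier is homogeneous of degree -1 in the demand
        primaries, receptors, w = working_point
        lim1 = sub.gamut_limit(primaries, receptors, w, sub.contrast_vector(i=0.05))
        lim2 = sub.gamut_limit(primaries, receptors, w, sub.contrast_vector(i=0.10))
        assert lim1 == pytest.approx(2.0 * lim2, rel=1e-9)

    def test_zero_direction_rejected(self, working_point):
        primaries, receptors, w = working_point
        with pytest.raises(ValueError):
            sub.gamut_limit(primaries, receptors, w, np.zeros(5))

    def test_study_background_supports_study_contrasts(self, working_point):
        # the working point must reach the stimulus contrasts used for CFF
        # measurements: melanopsin 17 %, rod 15 %
        primaries, receptors, w = working_point
        assert sub.gamut_limit(primaries, receptors, w,
                               sub.contrast_vector(i=1.0)) >= 0.17
        assert sub.gamut_limit(primaries, receptors, w,
                               sub.contrast_vector(r=1.0)) >= 0.15
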
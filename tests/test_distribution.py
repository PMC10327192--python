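import numpy as np
import pytest
from scipy.optimize import nnls
from scipy.special import betaincinv

from svauc.distribution import (
    DesignProblem,
    HydroParams,
    SGrid,
    build_design_matrix,
    build_s_grid,
    eliminate_systematic_noise,
    recover_noise,
    regularization_bound,
    solve_regularized,
)
from svauc.lamm import SVEDBERG, CellGeometry, RotorState, step_solution


class _GridConfig:
    def __init__(self, smin, smax, resolution, log=False, from_file=False):
        self.smin = smin
        self.smax = smax
        self.resolution = resolution
        self.use_log_space_sgrid = log
        self.grid_from_file = from_file


class TestSGrid:
    def test_linear_spacing(self):
        grid = build_s_grid(_GridConfig(1.0, 10.0, 10))
        np.testing.assert_allclose(np.diff(grid.s_values), 1.0)
        assert grid.s_values[0] == 1.0 and grid.s_values[-1] == 10.0

    def test_log_spacing(self):
        grid = build_s_grid(_GridConfig(1.0, 10.0, 10, log=True))
        ratios = grid.s_values[1:] / grid.s_values[:-1]
        np.testing.assert_allclose(ratios, 10.0 ** (1.0 / 9.0), rtol=1e-12)

    def test_grid_from_file(self, tmp_path):
        (tmp_path / "sdist.ra1").write_text("1\n2\n5\n20\n")
        grid = build_s_grid(_GridConfig(0, 0, 0, from_file=True), tmp_path, "RA1")
        np.testing.assert_array_equal(grid.s_values, [1.0, 2.0, 5.0, 20.0])
        assert grid.spacing == "file"

    def test_log_spacing_needs_positive_smin(self):
        with pytest.raises(ValueError, match="Smin > 0"):
            build_s_grid(_GridConfig(0.0, 10.0, 10, log=True))

    def test_missing_sdist_file(self, tmp_path):
        with pytest.raises(ValueError, match="sdist"):
            build_s_grid(_GridConfig(0, 0, 0, from_file=True), tmp_path, "ra1")

    def test_weights_sum_to_span(self):
        grid = SGrid(np.array([1.0, 2.0, 4.0, 8.0]))
        assert grid.weights.sum() == pytest.approx(7.0)


@pytest.fixture(scope="module")
def small_setup(noiseless_scan_set_module):
    return noiseless_scan_set_module


@pytest.fixture(scope="module")
def noiseless_scan_set_module():
    import numpy as np

    from svauc.lamm import RotorState
    from svauc.scan_io import Scan, assemble_scan_set
    from svauc.synthetic import Species, TruthManifest, ideal_signal

    manifest = TruthManifest(
        species=[Species(s=5.0, frictional_ratio=1.3, loading=1.0)],
        times=np.linspace(600.0, 6000.0, 8),
        sigma_random=0.0,
        seed=0,
    )
    signal = ideal_signal(manifest)
    omega_sq = RotorState(manifest.rotor_speed).omega_sq
    scans = [
        Scan(radii=manifest.radii, values=signal[:, k], scan_time=t,
             w2t=omega_sq * t, rotor_speed=manifest.rotor_speed, temperature=20.0)
        for k, t in enumerate(manifest.times)
    ]
    return manifest, assemble_scan_set(scans)


HYDRO = HydroParams(vbar=0.73, density=1.0, viscosity=0.01002,
                    frictional_ratio=1.3, temperature_k=293.15)
LIMITS = (6.17, 7.05)


def _problem(scan_set, grid, model="cofs", **flags):
    return build_design_matrix(
        grid, model, HYDRO, RotorState(scan_set.rotor_speed),
        CellGeometry(6.10, 7.15), scan_set, LIMITS, **flags
    )


class TestDesignMatrix:
    def test_lsgofs_column_is_step(self, small_setup):
        _, scan_set = small_setup
        grid = SGrid(np.array([3.0, 5.0]))
        prob = _problem(scan_set, grid, model="lsgofs")
        expected = step_solution(
            5.0 * SVEDBERG, RotorState(scan_set.rotor_speed),
            CellGeometry(6.10, 7.15), scan_set.times, prob.radii
        ).ravel(order="F")
        np.testing.assert_allclose(prob.a_matrix[:, 1], expected)

    def test_unknown_model_rejected(self, small_setup):
        _, scan_set = small_setup
        with pytest.raises(ValueError, match="model"):
            _problem(scan_set, SGrid(np.array([3.0, 5.0])), model="c(s)")

    def test_meniscus_must_precede_left_limit(self, small_setup):
        _, scan_set = small_setup
        with pytest.raises(ValueError, match="eniscus"):
            build_design_matrix(
                SGrid(np.array([3.0, 5.0])), "cofs", HYDRO,
                RotorState(scan_set.rotor_speed), CellGeometry(6.30, 7.15),
                scan_set, LIMITS,
            )

    def test_single_species_self_consistency(self, small_setup):
        """Noiseless data generated from one kernel column is recovered by
        plain NNLS with the exact loading."""
        _, scan_set = small_setup
        grid = SGrid(np.linspace(3.0, 7.0, 9))  # 5 S is grid point 4
        prob = _problem(scan_set, grid)
        b = prob.a_matrix[:, 4] * 0.8
        w, _ = nnls(prob.a_matrix, b)
        expected = np.zeros(9)
        expected[4] = 0.8
        np.testing.assert_allclose(w, expected, atol=1e-8)


class TestNoiseElimination:
    def _toy_problem(self, ti=False, ri=False, baseline=False, seed=0):
        rng = np.random.default_rng(seed)
        nr, ns, n_s = 30, 6, 5
        a = rng.random((nr * ns, n_s))
        b = rng.random(nr * ns)
        grid = SGrid(np.linspace(1.0, 5.0, n_s))
        return DesignProblem(
            a_matrix=a, b=b, s_grid=grid,
            radii=np.linspace(6.2, 7.0, nr), times=np.linspace(600, 3000, ns),
            fit_ti=ti, fit_ri=ri, fit_baseline=baseline,
        )

    def test_ti_projector_annihilates_radial_offsets(self):
        prob = self._toy_problem(ti=True)
        red = eliminate_systematic_noise(prob)
        ti = np.sin(np.linspace(0, 7, prob.n_radii))
        contaminated = prob.b + np.tile(ti, prob.n_scans)
        prob2 = self._toy_problem(ti=True)
        prob2.b = contaminated
        red2 = eliminate_systematic_noise(prob2)
        np.testing.assert_allclose(red2.pb, red.pb, atol=1e-12)

    def test_ri_projector_annihilates_scan_offsets(self):
        prob = self._toy_problem(ri=True)
        red = eliminate_systematic_noise(prob)
        offsets = np.linspace(-0.2, 0.3, prob.n_scans)
        prob2 = self._toy_problem(ri=True)
        prob2.b = prob.b + np.repeat(offsets, prob.n_radii)
        red2 = eliminate_systematic_noise(prob2)
        np.testing.assert_allclose(red2.pb, red.pb, atol=1e-12)

    def test_noise_recovery_matches_augmented_least_squares(self):
        """Projector route reproduces the solution of the explicit
        augmented system with TI/RI indicator columns in A."""
        rng = np.random.default_rng(3)
        prob = self._toy_problem(ti=True, ri=True, seed=3)
        nr, ns = prob.n_radii, prob.n_scans
        truth_w = np.array([0.0, 0.5, 0.0, 0.3, 0.0])
        ti = 0.05 * np.sin(np.linspace(0, 9, nr))
        ri = rng.normal(0, 0.02, ns)
        clean = prob.a_matrix @ truth_w
        prob.b = clean + np.tile(ti, ns) + np.repeat(ri, nr)

        red = eliminate_systematic_noise(prob)
        w = np.linalg.lstsq(red.pa, red.pb, rcond=None)[0]
        noise = recover_noise(red, w)
        model = (
            prob.a_matrix @ w
            + np.tile(noise.ti, ns)
            + np.repeat(noise.ri, nr)
            + noise.baseline
        )
        rmsd = np.sqrt(np.mean((prob.b - model) ** 2))
        assert rmsd <= 1e-10

        # oracle: explicit augmented least squares with noise columns
        ti_cols = np.vstack([np.tile(np.eye(nr)[:, i], ns) for i in range(nr)]).T
        ri_cols = np.vstack([np.repeat(np.eye(ns)[:, k], nr) for k in range(ns)]).T
        aug = np.hstack([prob.a_matrix, ti_cols, ri_cols])
        sol = np.linalg.lstsq(aug, prob.b, rcond=None)[0]
        resid_oracle = prob.b - aug @ sol
        resid_ours = prob.b - model
        np.testing.assert_allclose(resid_ours, resid_oracle, atol=1e-9)

    def test_noise_dimension_counting(self):
        assert eliminate_systematic_noise(self._toy_problem(ti=True)).noise_dims == 30
        assert eliminate_systematic_noise(self._toy_problem(ri=True)).noise_dims == 6
        assert (
            eliminate_systematic_noise(self._toy_problem(ti=True, ri=True)).noise_dims
            == 35
        )
        assert eliminate_systematic_noise(self._toy_problem(baseline=True)).noise_dims == 1

    def test_baseline_split_convention(self):
        """With baseline+TI the global constant is reported separately and
        the TI vector is re-centered to zero mean."""
        prob = self._toy_problem(ti=True, baseline=True)
        red = eliminate_systematic_noise(prob)
        w = np.linalg.lstsq(red.pa, red.pb, rcond=None)[0]
        noise = recover_noise(red, w)
        assert abs(noise.ti.mean()) < 1e-12


class TestRegularizationBound:
    def test_median_is_one(self):
        assert regularization_bound(2.5, 5000, 40, 0.5) == pytest.approx(2.5)

    def test_monotone_in_p(self):
        bounds = [regularization_bound(1.0, 2000, 50, p) for p in (0.55, 0.68, 0.9, 0.99)]
        assert all(b2 > b1 for b1, b2 in zip(bounds, bounds[1:]))
        assert bounds[0] > 1.0

    def test_factor_against_independent_quantile(self):
        """F(df, df) quantile via the regularized incomplete beta inverse,
        independently of the stats-distribution interface."""
        df = 5000
        p = 0.68
        x = betaincinv(df / 2.0, df / 2.0, 1.0 - p)
        factor_oracle = (1.0 - x) / x  # F = (1-x)/x for equal dof
        got = regularization_bound(1.0, df + 60, 60, p)
        np.testing.assert_allclose(got, factor_oracle, rtol=1e-10)

    @pytest.mark.parametrize("p", [0.3, 1.0, 1.5])
    def test_p_range_enforced(self, p):
        with pytest.raises(ValueError):
            regularization_bound(1.0, 100, 10, p)


class TestSolveRegularized:
    def _noisy_problem(self, scan_set, sigma=0.005, seed=0):
        rng = np.random.default_rng(seed)
        grid = SGrid(np.linspace(1.0, 12.0, 40))
        prob = _problem(scan_set, grid, fit_ri=True)
        prob.b = prob.b + rng.normal(0, sigma, prob.b.shape)
        return eliminate_systematic_noise(prob)

    def test_p_half_gives_plain_nnls(self, small_setup):
        _, scan_set = small_setup
        red = self._noisy_problem(scan_set)
        dist, _ = solve_regularized(red, "Tikhonov", 0.5)
        assert dist.alpha == 0.0
        w0, _ = nnls(red.pa, red.pb, maxiter=10000)
        np.testing.assert_allclose(dist.loadings, w0, atol=1e-7)

    @pytest.mark.parametrize("reg", ["Tikhonov", "maxent"])
    def test_ssr_meets_f_bound(self, small_setup, reg):
        """The resolved alpha matches the F-statistics SSR bound to 0.1%."""
        _, scan_set = small_setup
        red = self._noisy_problem(scan_set)
        w0, _ = nnls(red.pa, red.pb, maxiter=10000)
        ssr_min = float(np.sum((red.pa @ w0 - red.pb) ** 2))
        bound = regularization_bound(
            ssr_min, red.problem.n_points, red.noise_dims, 0.68
        )
        dist, _ = solve_regularized(red, reg, 0.68)
        ssr = dist.rmsd ** 2 * red.problem.n_points
        assert ssr <= bound * (1.0 + 1e-3)
        assert ssr >= ssr_min
        assert abs(ssr - bound) <= 1e-3 * bound

    def test_ssr_monotone_in_alpha(self, small_setup):
        _, scan_set = small_setup
        red = self._noisy_problem(scan_set)
        grid = red.problem.s_grid
        from svauc.distribution import _second_difference_operator

        l_op = _second_difference_operator(grid.s_values) @ np.diag(1.0 / grid.weights)
        ssrs = []
        for alpha in [0.0, 1e-4, 1e-2, 1.0, 100.0]:
            a_aug = np.vstack([red.pa, np.sqrt(alpha) * l_op])
            b_aug = np.concatenate([red.pb, np.zeros(l_op.shape[0])])
            w, _ = nnls(a_aug, b_aug, maxiter=10000)
            ssrs.append(float(np.sum((red.pa @ w - red.pb) ** 2)))
        assert all(s2 >= s1 - 1e-12 for s1, s2 in zip(ssrs, ssrs[1:]))

    def test_distribution_nonnegative_and_integrates_to_signal(self, small_setup):
        _, scan_set = small_setup
        red = self._noisy_problem(scan_set)
        dist, _ = solve_regularized(red, "Tikhonov", 0.68)
        assert np.all(dist.c_values >= 0.0)
        integral = np.sum(dist.loadings)
        # total boundary signal of the unit-loading single species
        assert integral == pytest.approx(1.0, rel=0.05)

    def test_suppress_baseline_correlation_zeroes_smin(self, small_setup):
        _, scan_set = small_setup
        rng = np.random.default_rng(5)
        grid = SGrid(np.linspace(0.2, 12.0, 40))
        prob = _problem(scan_set, grid, fit_baseline=True)
        prob.b = prob.b + 0.05 + rng.normal(0, 0.005, prob.b.shape)
        red = eliminate_systematic_noise(prob)
        dist, _ = solve_regularized(red, "Tikhonov", 0.68,
                                    suppress_baseline_correlation=True)
        assert dist.c_values[0] <= 1e-3 * dist.c_values.max()
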
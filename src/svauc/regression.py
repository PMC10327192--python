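"""Outer nonlinear regression over meniscus, bottom and frictional ratio.

The distribution amplitudes and systematic-noise components enter the
model linearly and are solved exactly (NNLS after noise projection) at
every trial of the nonlinear parameters; the optimizer therefore only
sees the 1-3 dimensional landscape of meniscus, bottom and f/f0.
Following standard practice the nonlinear iterations run unregularized
(alpha = 0) to keep the objective smooth; the single regularized solve
producing the reported distribution happens once at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize, nnls

from svauc.distribution import (
    DesignProblem,
    Distribution,
    HydroParams,
    NoiseVectors,
    SGrid,
    build_design_matrix,
    eliminate_systematic_noise,
    recover_noise,
    solve_regularized,
)
from svauc.lamm import CellGeometry, RotorState
from svauc.scan_io import ScanSet

_PENALTY_RMSD = 1.0e6


@dataclass
class FitSpec:
    """Everything the nonlinear regression needs besides the data."""

    model: str  # 'cofs' | 'lsgofs'
    s_grid: SGrid
    hydro: HydroParams
    meniscus: float
    bottom: float
    left_fit_limit: float
    right_fit_limit: float
    fit_meniscus: bool = False
    fit_bottom: bool = False
    fit_frictional_ratio: bool = False
    meniscus_bounds: tuple[float, float] = (0.0, np.inf)
    bottom_bounds: tuple[float, float] = (0.0, np.inf)
    frictional_ratio_bounds: tuple[float, float] = (1.0, 4.0)
    fit_ti: bool = False
    fit_ri: bool = False
    fit_baseline: bool = False
    reg_type: str = "maxent"
    reg_p_value: float = 0.68
    suppress_baseline_correlation: bool = False
    algorithm: str = "Simplex"  # 'Simplex' | 'Levenberg-Marquardt'
    seed: int = 0
    lamm_grid: int = 400


@dataclass
class FitResult:
    """Converged nonlinear parameters plus the final regularized solution."""

    meniscus: float
    bottom: float
    frictional_ratio: float
    distribution: Distribution
    ti_noise: np.ndarray
    ri_noise: np.ndarray
    baseline: float
    residuals: np.ndarray  # [n_radii x n_scans] over the fit window
    fitted_matrix: np.ndarray  # model + noise, same shape
    radii: np.ndarray
    times: np.ndarray
    rmsd: float
    ssr: float
    n_points: int
    per_scan_rmsd: np.ndarray
    converged: bool
    n_evaluations: int
    fitting_steps: list[str] = field(default_factory=list)

    @property
    def fitting_steps_text(self) -> str:
        return self.fitting_steps[0] if self.fitting_steps else ""


def per_scan_rmsd(residuals: np.ndarray) -> np.ndarray:
    """Local rmsd over radii, one value per scan (column)."""
    residuals = np.asarray(residuals, dtype=float)
    if residuals.ndim != 2:
        raise ValueError("residuals must be an [n_radii x n_scans] matrix")
    return np.sqrt(np.mean(residuals ** 2, axis=0))


class _Objective:
    """Unregularized best-linear-fit rmsd as a function of the active
    nonlinear parameters; memoized because simplex reflections can
    revisit vertices."""

    def __init__(self, spec: FitSpec, scan_set: ScanSet):
        self.spec = spec
        self.scan_set = scan_set
        self.rotor = RotorState(scan_set.rotor_speed)
        self.names = [
            name
            for name, flag in (
                ("meniscus", spec.fit_meniscus),
                ("bottom", spec.fit_bottom),
                ("frictional_ratio", spec.fit_frictional_ratio),
            )
            if flag
        ]
        self.n_calls = 0
        self._memo: dict[bytes, float] = {}

    def theta0(self) -> np.ndarray:
        start = {
            "meniscus": self.spec.meniscus,
            "bottom": self.spec.bottom,
            "frictional_ratio": self.spec.hydro.frictional_ratio,
        }
        return np.array([start[n] for n in self.names])

    def bounds(self) -> list[tuple[float, float]]:
        table = {
            "meniscus": self.spec.meniscus_bounds,
            "bottom": self.spec.bottom_bounds,
            "frictional_ratio": self.spec.frictional_ratio_bounds,
        }
        return [table[n] for n in self.names]

    def unpack(self, theta: np.ndarray) -> tuple[float, float, float]:
        values = {
            "meniscus": self.spec.meniscus,
            "bottom": self.spec.bottom,
            "frictional_ratio": self.spec.hydro.frictional_ratio,
        }
        for name, v in zip(self.names, theta):
            values[name] = float(v)
        return values["meniscus"], values["bottom"], values["frictional_ratio"]

    def _violation(self, theta: np.ndarray) -> float:
        men, bot, fr = self.unpack(theta)
        v = 0.0
        for (lo, hi), val in zip(self.bounds(), theta):
            v += max(0.0, lo - val) + max(0.0, val - hi)
        if men >= self.spec.left_fit_limit:
            v += men - self.spec.left_fit_limit + 1e-6
        if men >= bot:
            v += men - bot + 1e-6
        if fr < 1.0:
            v += 1.0 - fr
        return v

    def linear_solve(self, theta: np.ndarray):
        """Plain NNLS fit at theta; returns (rmsd, problem, reduced, loadings)."""
        self.n_calls += 1
        men, bot, fr = self.unpack(theta)
        spec = self.spec
        hydro = HydroParams(
            vbar=spec.hydro.vbar,
            density=spec.hydro.density,
            viscosity=spec.hydro.viscosity,
            frictional_ratio=fr,
            temperature_k=spec.hydro.temperature_k,
        )
        problem = build_design_matrix(
            spec.s_grid,
            spec.model,
            hydro,
            self.rotor,
            CellGeometry(men, bot),
            self.scan_set,
            (spec.left_fit_limit, spec.right_fit_limit),
            fit_ti=spec.fit_ti,
            fit_ri=spec.fit_ri,
            fit_baseline=spec.fit_baseline,
            n_grid=spec.lamm_grid,
        )
        reduced = eliminate_systematic_noise(problem)
        q, r_mat = np.linalg.qr(reduced.pa, mode="reduced")
        z = q.T @ reduced.pb
        const = max(float(reduced.pb @ reduced.pb - z @ z), 0.0)
        w, _ = nnls(r_mat, z, maxiter=50 * len(spec.s_grid.s_values))
        resid = r_mat @ w - z
        ssr = float(resid @ resid) + const
        rmsd = float(np.sqrt(ssr / problem.n_points))
        return rmsd, problem, reduced, w

    def __call__(self, theta: np.ndarray) -> float:
        theta = np.asarray(theta, dtype=float)
        violation = self._violation(theta)
        if violation > 0:
            return _PENALTY_RMSD * (1.0 + violation)
        key = theta.tobytes()
        hit = self._memo.get(key)
        if hit is not None:
            return hit
        rmsd = self.linear_solve(theta)[0]
        self._memo[key] = rmsd
        return rmsd


def objective(theta: np.ndarray, spec: FitSpec, scan_set: ScanSet) -> float:
    """rmsd of the unregularized best linear fit at nonlinear parameters
    ``theta`` (active parameters only, in meniscus/bottom/f-f0 order)."""
    return _Objective(spec, scan_set)(np.asarray(theta, dtype=float))


def _initial_simplex(theta0: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Starting simplex with +/-2% random perturbation per vertex."""
    n = len(theta0)
    simplex = np.tile(theta0, (n + 1, 1))
    for i in range(1, n + 1):
        step = 0.02 * (abs(theta0[i - 1]) if theta0[i - 1] != 0 else 0.02)
        simplex[i, i - 1] += step
    simplex *= 1.0 + 0.02 * (2.0 * rng.random(simplex.shape) - 1.0)
    return simplex


def fit_model(spec: FitSpec, scan_set: ScanSet) -> FitResult:
    """Optimize the flagged nonlinear parameters, then perform the final
    regularized solve at the optimum.

    With no *Fitted flags enabled this reduces to a single evaluation at
    the starting values (the AutoRun-without-AutoFit behavior).
    """
    obj = _Objective(spec, scan_set)
    theta0 = obj.theta0()
    steps: list[str] = []
    converged = True

    if len(theta0) == 0:
        theta_best = theta0
        steps.append("no nonlinear parameters fitted; single evaluation at start values")
    else:
        for (lo, hi), val, name in zip(obj.bounds(), theta0, obj.names):
            if not (lo <= val <= hi):
                raise ValueError(
                    f"starting {name} = {val} violates its bounds [{lo}, {hi}]"
                )
        if spec.algorithm == "Simplex":
            rng = np.random.default_rng(spec.seed)
            res = minimize(
                obj,
                theta0,
                method="Nelder-Mead",
                options={
                    "initial_simplex": _initial_simplex(theta0, rng),
                    "xatol": 1e-6,
                    "fatol": 1e-10,
                    "maxiter": 600,
                },
            )
            theta_best = np.asarray(res.x, dtype=float)
            converged = bool(res.success)
            steps.append(
                f"Simplex (Nelder-Mead, seed {spec.seed}): {res.nit} iterations, "
                f"{obj.n_calls} model evaluations, rmsd {res.fun:.6g}"
            )
        elif spec.algorithm == "Levenberg-Marquardt":
            lb = np.array([b[0] for b in obj.bounds()])
            ub = np.array([b[1] for b in obj.bounds()])

            def residual_vector(theta):
                rmsd, problem, reduced, w = obj.linear_solve(theta)
                return reduced.pb - reduced.pa @ w

            res = least_squares(
                residual_vector,
                theta0,
                bounds=(lb, ub),
                method="trf",
                diff_step=1e-4,
                xtol=1e-10,
                ftol=2e-6,  # ~1e-6 relative rmsd change
                max_nfev=200 * (len(theta0) + 1),
            )
            theta_best = np.asarray(res.x, dtype=float)
            converged = res.status > 0
            steps.append(
                f"Levenberg-Marquardt (trust-region-reflective bounds): "
                f"{res.nfev} evaluations, rmsd {np.sqrt(2 * res.cost / len(res.fun)):.6g}"
            )
        else:
            raise ValueError(f"unknown fitting algorithm {spec.algorithm!r}")
        # optimizers can only improve on the start; keep the better point
        if obj(theta_best) > obj(theta0):
            theta_best = theta0
            converged = False
            steps.append("optimizer failed to improve; reporting starting values")

    # final regularized solve at the optimum
    rmsd0, problem, reduced, _ = obj.linear_solve(theta_best)
    dist, noise = solve_regularized(
        reduced,
        spec.reg_type,
        spec.reg_p_value,
        suppress_baseline_correlation=spec.suppress_baseline_correlation,
        n_fitted_nonlinear=len(theta0),
    )
    steps.append(
        f"final {spec.reg_type} solve at p={spec.reg_p_value}: alpha={dist.alpha:.4g}, "
        f"rmsd {dist.rmsd:.6g} (unregularized {rmsd0:.6g})"
    )

    men, bot, fr = obj.unpack(theta_best)
    nr, ns = problem.n_radii, problem.n_scans
    model_matrix = (problem.a_matrix @ dist.loadings).reshape(nr, ns, order="F")
    fitted = model_matrix + noise.ti[:, None] + noise.ri[None, :] + noise.baseline
    data = problem.b.reshape(nr, ns, order="F")
    residuals = data - fitted
    ssr = float(np.sum(residuals ** 2))
    rmsd = float(np.sqrt(ssr / residuals.size))
    return FitResult(
        meniscus=men,
        bottom=bot,
        frictional_ratio=fr,
        distribution=dist,
        ti_noise=noise.ti,
        ri_noise=noise.ri,
        baseline=noise.baseline,
        residuals=residuals,
        fitted_matrix=fitted,
        radii=problem.radii,
        times=problem.times,
        rmsd=rmsd,
        ssr=ssr,
        n_points=residuals.size,
        per_scan_rmsd=per_scan_rmsd(residuals),
        converged=converged,
        n_evaluations=obj.n_calls,
        fitting_steps=steps,
    )
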
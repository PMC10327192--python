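"""Regularized linear inversion for c(s) and ls-g*(s) distributions.

Both analyses model the measured scans as a superposition of
sedimentation kernels over a discrete grid of s-values,

    a(r, t) = integral c(s) chi(s, D(s); r, t) ds + TI(r) + RI(t) + beta,

where chi is a Lamm-equation solution (c(s)) or a non-diffusing step
(ls-g*(s)), TI is a time-invariant radius-dependent baseline, RI a
radial-invariant per-scan offset, and beta a global constant.  The
systematic-noise components enter linearly and are eliminated
algebraically by orthogonal projection before the non-negative
least-squares solve; regularization (maximum entropy or Tikhonov) is
scaled so the sum of squared residuals meets an F-statistics bound set
by a confidence level p.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal

import numpy as np
from scipy.optimize import nnls
from scipy.stats import f as f_dist

from svauc.lamm import (
    SVEDBERG,
    CellGeometry,
    KernelCache,
    RotorState,
    diffusion_from_s,
    solve_lamm,
    step_solution,
)
from svauc.scan_io import ScanSet


@dataclass
class SGrid:
    """Discrete grid of sedimentation coefficients in Svedberg."""

    s_values: np.ndarray
    spacing: Literal["linear", "log", "file"] = "linear"

    def __post_init__(self) -> None:
        self.s_values = np.asarray(self.s_values, dtype=float)
        if len(self.s_values) < 2:
            raise ValueError("s-grid needs at least 2 points (Resolution >= 2)")
        if not np.all(np.diff(self.s_values) > 0):
            raise ValueError("s-grid must be strictly increasing")

    @property
    def weights(self) -> np.ndarray:
        """Trapezoidal quadrature weights delta_j so that
        integral c(s) ds = sum_j delta_j c_j."""
        s = self.s_values
        h = np.diff(s)
        w = np.empty_like(s)
        w[0] = h[0] / 2.0
        w[-1] = h[-1] / 2.0
        w[1:-1] = (h[:-1] + h[1:]) / 2.0
        return w


@dataclass
class HydroParams:
    """Solution/solute parameters for the hydrodynamic scaling law."""

    vbar: float  # mL/g
    density: float  # g/mL
    viscosity: float  # Poise
    frictional_ratio: float  # f/f0
    temperature_k: float  # K


@dataclass
class DesignProblem:
    """Kernel matrix over the s-grid plus data and noise-subspace flags.

    The data vector ``b`` is the fit-window signal flattened scan-major
    (scan 1 radii ascending, then scan 2, ...).
    """

    a_matrix: np.ndarray  # [n_data x n_s]
    b: np.ndarray
    s_grid: SGrid
    radii: np.ndarray  # retained radii (fit window)
    times: np.ndarray
    fit_ti: bool = False
    fit_ri: bool = False
    fit_baseline: bool = False

    @property
    def n_radii(self) -> int:
        return len(self.radii)

    @property
    def n_scans(self) -> int:
        return len(self.times)

    @property
    def n_points(self) -> int:
        return len(self.b)


@dataclass
class ReducedProblem:
    """Design problem with the systematic-noise subspaces projected out."""

    problem: DesignProblem
    pa: np.ndarray
    pb: np.ndarray
    noise_dims: int


@dataclass
class NoiseVectors:
    ti: np.ndarray  # per retained radius
    ri: np.ndarray  # per scan
    baseline: float


@dataclass
class Distribution:
    """Differential sedimentation-coefficient distribution c(s).

    ``c_values`` is signal per Svedberg (>= 0); ``loadings`` are the
    per-grid-point signal amplitudes w_j = delta_j * c_j, whose sum is
    the total fitted boundary signal.
    """

    s_values: np.ndarray
    c_values: np.ndarray
    rmsd: float
    loadings: np.ndarray = None
    alpha: float = 0.0

    def total_signal(self) -> float:
        return float(np.sum(self.loadings))


def build_s_grid(config, data_directory=None, channel: str | None = None) -> SGrid:
    """Construct the s-grid from analysis parameters.

    ``config`` needs attributes ``smin``, ``smax``, ``resolution``,
    ``use_log_space_sgrid`` and ``grid_from_file``.  With
    ``grid_from_file`` the grid is read from ``sdist.<ext>`` in the data
    directory; otherwise it is linear or geometric between Smin and Smax
    with Resolution points.
    """
    if getattr(config, "grid_from_file", False):
        if data_directory is None or not channel:
            raise ValueError("GridfromFile requires a data directory and channel")
        path = Path(data_directory) / f"sdist.{channel.lower().lstrip('.')}"
        try:
            values = np.loadtxt(path, ndmin=1)
        except OSError as exc:
            raise ValueError(f"cannot read s-grid file {path}: {exc}") from exc
        if values.size < 2:
            raise ValueError(f"s-grid file {path} needs at least 2 values")
        return SGrid(np.sort(values), spacing="file")
    smin, smax, n = config.smin, config.smax, config.resolution
    if not smin < smax:
        raise ValueError(f"require Smin < Smax, got {smin} >= {smax}")
    if n < 2:
        raise ValueError(f"Resolution must be >= 2, got {n}")
    if getattr(config, "use_log_space_sgrid", False):
        if smin <= 0:
            raise ValueError("log-spaced s-grid requires Smin > 0")
        return SGrid(np.geomspace(smin, smax, n), spacing="log")
    return SGrid(np.linspace(smin, smax, n), spacing="linear")


def build_design_matrix(
    grid: SGrid,
    model: str,
    hydro: HydroParams,
    rotor: RotorState,
    geom: CellGeometry,
    scan_set: ScanSet,
    fit_limits: tuple[float, float],
    fit_ti: bool = False,
    fit_ri: bool = False,
    fit_baseline: bool = False,
    n_grid: int = 400,
    cache: KernelCache | None = None,
) -> DesignProblem:
    """Vectorize the sedimentation kernels into the design matrix.

    Column j holds chi(s_j, D(s_j)) for 'cofs' (D from the frictional-ratio
    scaling law) or the non-diffusing step chi(s_j, 0) for 'lsgofs',
    evaluated on the retained radii x scan times of the fit window.
    """
    if model not in ("cofs", "lsgofs"):
        raise ValueError(f"unknown model {model!r}; expected 'cofs' or 'lsgofs'")
    left, right = fit_limits
    if not (scan_set.radii[0] <= left < right <= scan_set.radii[-1] + 1e-12):
        raise ValueError(
            f"fit limits [{left}, {right}] outside data range "
            f"[{scan_set.radii[0]}, {scan_set.radii[-1]}]"
        )
    if geom.meniscus >= left:
        raise ValueError(
            f"meniscus ({geom.meniscus}) must lie left of LeftFitLimit ({left})"
        )
    mask = (scan_set.radii >= left) & (scan_set.radii <= right)
    radii = scan_set.radii[mask]
    times = scan_set.times
    b = scan_set.signal[mask, :].ravel(order="F")

    n_s = len(grid.s_values)
    a_matrix = np.empty((len(b), n_s))
    for j, s_sv in enumerate(grid.s_values):
        s_sec = s_sv * SVEDBERG
        if model == "lsgofs":
            prof = step_solution(s_sec, rotor, geom, times, radii)
        else:
            d_coef = diffusion_from_s(
                s_sec,
                hydro.frictional_ratio,
                hydro.vbar,
                hydro.density,
                hydro.viscosity,
                hydro.temperature_k,
            )
            if cache is not None:
                prof = cache.get(s_sec, d_coef, rotor, geom, times, radii, n_grid=n_grid)
            else:
                prof = solve_lamm(s_sec, d_coef, rotor, geom, times, radii, n_grid=n_grid)
        a_matrix[:, j] = prof.ravel(order="F")
    return DesignProblem(
        a_matrix=a_matrix,
        b=b,
        s_grid=grid,
        radii=radii,
        times=times,
        fit_ti=fit_ti,
        fit_ri=fit_ri,
        fit_baseline=fit_baseline,
    )


def _project_matrix(x: np.ndarray, ti: bool, ri: bool, baseline: bool) -> np.ndarray:
    """Orthogonal projection of [n_radii x n_scans] data onto the
    complement of the enabled noise subspaces (two-way centering)."""
    if ti and ri:
        row = x.mean(axis=1, keepdims=True)
        col = x.mean(axis=0, keepdims=True)
        return x - row - col + x.mean()
    if ti:
        return x - x.mean(axis=1, keepdims=True)
    if ri:
        return x - x.mean(axis=0, keepdims=True)
    if baseline:
        return x - x.mean()
    return x


def eliminate_systematic_noise(problem: DesignProblem) -> ReducedProblem:
    """Project the TI/RI/baseline subspaces out of the linear problem.

    The global constant is contained in both the TI and the RI subspace,
    so enabling baseline together with either adds no dimensions; with
    both TI and RI the combined subspace has n_radii + n_scans - 1
    dimensions (two-way ANOVA centering on the complete radius x scan
    grid).
    """
    ti, ri, base = problem.fit_ti, problem.fit_ri, problem.fit_baseline
    if ri and problem.n_scans < 2:
        raise ValueError("RI noise needs at least 2 scans")
    if ti and problem.n_radii < 2:
        raise ValueError("TI noise needs at least 2 radii")
    nr, ns = problem.n_radii, problem.n_scans

    def proj(vec: np.ndarray) -> np.ndarray:
        return _project_matrix(
            vec.reshape(nr, ns, order="F"), ti, ri, base
        ).ravel(order="F")

    if not (ti or ri or base):
        return ReducedProblem(problem, problem.a_matrix, problem.b, 0)
    pa = np.column_stack([proj(problem.a_matrix[:, j]) for j in range(problem.a_matrix.shape[1])])
    pb = proj(problem.b)
    if ti and ri:
        dims = nr + ns - 1
    elif ti:
        dims = nr
    elif ri:
        dims = ns
    else:
        dims = 1
    return ReducedProblem(problem, pa, pb, dims)


def recover_noise(reduced: ReducedProblem, loadings: np.ndarray) -> NoiseVectors:
    """Least-squares TI/RI/baseline vectors from the residual b - A c.

    When the baseline flag accompanies TI (or RI), the rank deficiency is
    resolved by reporting the baseline as the mean of the noise vector and
    re-centering that vector to zero mean.
    """
    p = reduced.problem
    d = (p.b - p.a_matrix @ loadings).reshape(p.n_radii, p.n_scans, order="F")
    ti = np.zeros(p.n_radii)
    ri = np.zeros(p.n_scans)
    baseline = 0.0
    if p.fit_ti and p.fit_ri:
        ti = d.mean(axis=1)
        ri = d.mean(axis=0) - d.mean()
    elif p.fit_ti:
        ti = d.mean(axis=1)
    elif p.fit_ri:
        ri = d.mean(axis=0)
    elif p.fit_baseline:
        baseline = float(d.mean())
        return NoiseVectors(ti, ri, baseline)
    if p.fit_baseline:
        if p.fit_ti:
            baseline = float(ti.mean())
            ti = ti - baseline
        elif p.fit_ri:
            baseline = float(ri.mean())
            ri = ri - baseline
    return NoiseVectors(ti, ri, baseline)


def regularization_bound(
    ssr_min: float, n_points: int, n_free_params: int, p_value: float
) -> float:
    """Largest SSR statistically indistinguishable from the best fit.

    ssr_max = ssr_min * F_quantile(p; df, df) with df = n_points -
    n_free_params.  At p = 0.5 the F(df, df) median is exactly 1, so no
    regularization is admitted; the bound grows monotonically (and
    without limit) as p -> 1.
    """
    if not (0.5 <= p_value < 1.0):
        raise ValueError(f"regularization p-value must be in [0.5, 1), got {p_value}")
    if n_points <= n_free_params:
        raise ValueError("need more data points than free parameters")
    df = n_points - n_free_params
    if p_value == 0.5:
        return float(ssr_min)  # median of F(df, df) is exactly 1
    return float(ssr_min * f_dist.ppf(p_value, df, df))


def _second_difference_operator(s: np.ndarray) -> np.ndarray:
    """Second-difference (curvature) rows on a possibly non-uniform grid."""
    n = len(s)
    if n < 3:
        return np.zeros((0, n))
    h = np.diff(s)
    rows = np.zeros((n - 2, n))
    scale = np.mean(h) ** 2  # normalize so entries are O(1) on uniform grids
    for k in range(1, n - 1):
        hl, hr = h[k - 1], h[k]
        rows[k - 1, k - 1] = 2.0 * scale / (hl * (hl + hr))
        rows[k - 1, k] = -2.0 * scale / (hl * hr)
        rows[k - 1, k + 1] = 2.0 * scale / (hr * (hl + hr))
    return rows


def solve_regularized(
    reduced: ReducedProblem,
    reg_type: str,
    p_value: float,
    suppress_baseline_correlation: bool = False,
    n_fitted_nonlinear: int = 0,
    max_bisect: int = 60,
    ssr_rtol: float = 1e-3,
) -> tuple[Distribution, NoiseVectors]:
    """Solve the non-negative inverse problem with scaled regularization.

    The regularization strength alpha is found by bisection on log10
    alpha so that SSR(alpha) matches the F-statistics bound from
    :func:`regularization_bound` within ``ssr_rtol`` relative; p = 0.5
    (bound equal to the minimum SSR) yields the plain NNLS solution.
    With ``suppress_baseline_correlation`` the penalty weight on the
    smallest s-value is multiplied by 1e4 (a strong prior pulling the
    first grid point toward zero, breaking its correlation with
    baselines).
    """
    if reg_type not in ("maxent", "Tikhonov"):
        raise ValueError(f"unknown regularization {reg_type!r}")
    prob = reduced.problem
    s_sv = prob.s_grid.s_values
    delta = prob.s_grid.weights
    n_s = len(s_sv)

    # QR-reduce the (projected) least-squares problem once; every
    # regularized subproblem then works on the small n_s x n_s core.
    q, r_mat = np.linalg.qr(reduced.pa, mode="reduced")
    z = q.T @ reduced.pb
    const = float(reduced.pb @ reduced.pb - z @ z)
    const = max(const, 0.0)
    n_points = prob.n_points

    def data_ssr(w: np.ndarray) -> float:
        resid = r_mat @ w - z
        return float(resid @ resid) + const

    try:
        w0, _ = nnls(r_mat, z, maxiter=50 * n_s)
    except RuntimeError as exc:
        raise RuntimeError(f"NNLS did not converge on the unregularized problem: {exc}")
    ssr_min = data_ssr(w0)
    n_free = reduced.noise_dims + n_fitted_nonlinear
    bound = regularization_bound(ssr_min, n_points, n_free, p_value)

    def make_distribution(w: np.ndarray, alpha: float) -> Distribution:
        ssr = data_ssr(w)
        return Distribution(
            s_values=s_sv,
            c_values=w / delta,
            rmsd=float(np.sqrt(ssr / n_points)),
            loadings=w,
            alpha=alpha,
        )

    if bound <= ssr_min * (1.0 + 1e-12) or ssr_min == 0.0:
        dist = make_distribution(w0, 0.0)
        return dist, recover_noise(reduced, w0)

    l_op = _second_difference_operator(s_sv) @ np.diag(1.0 / delta)
    suppress_row = np.zeros((1, n_s))
    if suppress_baseline_correlation:
        suppress_row[0, 0] = 100.0 / delta[0]  # weight^2 = 1e4 on c(s_min)

    # maximum-entropy prior level: flat distribution carrying the total
    # fitted signal spread over the grid span
    total = max(float(np.sum(w0)), 1e-12)
    c0 = total / (n_s * (s_sv[-1] - s_sv[0]))

    def solve_at(alpha: float) -> tuple[np.ndarray, float]:
        sq = np.sqrt(alpha)
        if reg_type == "Tikhonov":
            a_aug = np.vstack([r_mat, sq * l_op, sq * suppress_row])
            b_aug = np.concatenate([z, np.zeros(a_aug.shape[0] - n_s)])
            w, _ = nnls(a_aug, b_aug, maxiter=50 * n_s)
            return w, data_ssr(w)
        # maxent: sequential quadratic approximation of sum c ln(c/c0),
        # each step an augmented NNLS with diagonal reweighting
        c_prev = np.full(n_s, c0)
        w = w0
        floor = 1e-8 * c0
        for _ in range(15):
            cp = np.maximum(c_prev, floor)
            u = np.sqrt(alpha / (2.0 * cp)) / delta  # row weight acting on w
            if suppress_baseline_correlation:
                u[0] *= 100.0
            target = -cp * np.log(cp / c0)  # quadratic-model minimizer
            a_aug = np.vstack([r_mat, np.diag(u)])
            b_aug = np.concatenate([z, u * delta * target])
            w, _ = nnls(a_aug, b_aug, maxiter=50 * n_s)
            c_new = w / delta
            if np.linalg.norm(c_new - c_prev) <= 1e-6 * (np.linalg.norm(c_new) + floor):
                c_prev = c_new
                break
            c_prev = c_new
        return w, data_ssr(w)

    log_lo, log_hi = -8.0, 8.0
    w_hi, ssr_hi = solve_at(10.0 ** log_hi)
    if ssr_hi <= bound:
        # even maximal smoothing stays within the bound; adopt it
        dist = make_distribution(w_hi, 10.0 ** log_hi)
        return dist, recover_noise(reduced, w_hi)
    best_w, best_alpha = w0, 0.0
    for _ in range(max_bisect):
        log_mid = 0.5 * (log_lo + log_hi)
        alpha = 10.0 ** log_mid
        w, ssr = solve_at(alpha)
        if ssr <= bound:
            best_w, best_alpha = w, alpha
            log_lo = log_mid
        else:
            log_hi = log_mid
        if abs(ssr - bound) <= ssr_rtol * bound:
            best_w, best_alpha = w, alpha
            break
    dist = make_distribution(best_w, best_alpha)
    return dist, recover_noise(reduced, best_w)


def write_sdist(grid: SGrid, data_directory, channel: str) -> Path:
    """Write the s-grid as the single-column ``sdist.<ext>`` template file."""
    path = Path(data_directory) / f"sdist.{channel.lower().lstrip('.')}"
    np.savetxt(path, grid.s_values, fmt="%.8g")
    return path
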
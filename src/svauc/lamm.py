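"""Lamm-equation kernels for sedimentation-velocity modelling.

The Lamm equation describes the evolution of the radial concentration
profile chi(r, t) of a species with sedimentation coefficient ``s`` and
diffusion coefficient ``D`` in a sector-shaped centrifuge cell spinning
at angular velocity omega:

    d(chi)/dt = (1/r) d/dr [ r D d(chi)/dr - s omega^2 r^2 chi ]

with zero-flux boundary conditions at the meniscus ``m`` and bottom
``b`` of the solution column and uniform initial loading chi(r, 0) = 1.

Two kernels are provided: :func:`solve_lamm` (full sedimentation +
diffusion, the c(s) kernel) and :func:`step_solution` (the non-diffusing
step kernel of ls-g*(s)).  :func:`diffusion_from_s` supplies the
hydrodynamic scaling law that ties D to s through a constant frictional
ratio f/f0, the standard c(s) parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csc_matrix, identity
from scipy.sparse.linalg import splu

#: Boltzmann constant in CGS units (erg/K).
BOLTZMANN_CGS = 1.38065e-16

#: One Svedberg in seconds.
SVEDBERG = 1e-13


@dataclass(frozen=True)
class CellGeometry:
    """Solution-column geometry: meniscus and bottom radii in cm from the
    center of rotation."""

    meniscus: float
    bottom: float

    def __post_init__(self) -> None:
        if not (0.0 < self.meniscus < self.bottom):
            raise ValueError(
                f"require 0 < meniscus < bottom, got m={self.meniscus}, b={self.bottom}"
            )


@dataclass(frozen=True)
class RotorState:
    """Rotor speed in rpm; angular velocity derived as rpm * 2*pi/60."""

    rotor_speed: float

    def __post_init__(self) -> None:
        if not self.rotor_speed > 0:
            raise ValueError(f"rotor_speed must be > 0, got {self.rotor_speed}")

    @property
    def omega(self) -> float:
        """Angular velocity in rad/s."""
        return self.rotor_speed * 2.0 * np.pi / 60.0

    @property
    def omega_sq(self) -> float:
        return self.omega ** 2


def diffusion_from_s(
    s: float,
    fr: float,
    vbar: float,
    rho: float,
    eta: float,
    temperature_k: float,
) -> float:
    """Diffusion coefficient from the frictional-ratio scaling law.

    D = (sqrt(2)/(18 pi)) * kT * s^(-1/2) * (eta * fr)^(-3/2)
        * ((1 - vbar*rho)/vbar)^(1/2)

    Parameters
    ----------
    s : sedimentation coefficient in seconds (Svedberg * 1e-13).
    fr : frictional ratio f/f0 (>= 1).
    vbar : partial specific volume in mL/g.
    rho : solvent density in g/mL.
    eta : solvent viscosity in Poise (g cm^-1 s^-1).
    temperature_k : absolute temperature in K.

    Returns
    -------
    D in cm^2/s.
    """
    if s <= 0:
        raise ValueError(f"s must be > 0, got {s}")
    if fr < 1.0:
        raise ValueError(f"frictional ratio must be >= 1, got {fr}")
    if eta <= 0 or temperature_k <= 0:
        raise ValueError("viscosity and temperature must be positive")
    buoyancy = 1.0 - vbar * rho
    if buoyancy <= 0 or vbar <= 0:
        raise ValueError(
            f"neutral or floating species (1 - vbar*rho = {buoyancy:g}) is not "
            "supported by the c(s) scaling law"
        )
    kt = BOLTZMANN_CGS * temperature_k
    return (
        np.sqrt(2.0) / (18.0 * np.pi)
        * kt
        * s ** -0.5
        * (eta * fr) ** -1.5
        * np.sqrt(buoyancy / vbar)
    )


def step_solution(
    s: float,
    rotor: RotorState,
    geom: CellGeometry,
    times: np.ndarray,
    radii: np.ndarray,
) -> np.ndarray:
    """Non-diffusing boundary solution (the ls-g*(s) kernel).

    chi(r, t) = exp(-2 s omega^2 t) for r behind the boundary position
    m * exp(s omega^2 t), else 0.  The plateau decays by radial dilution;
    once the boundary passes the bottom the column is depleted.

    Returns a [n_radii x n_times] matrix.
    """
    if s <= 0:
        raise ValueError(f"s must be > 0, got {s}")
    times = np.atleast_1d(np.asarray(times, dtype=float))
    radii = np.atleast_1d(np.asarray(radii, dtype=float))
    tau = s * rotor.omega_sq * times  # dimensionless sedimentation clock
    boundary = geom.meniscus * np.exp(tau)
    plateau = np.exp(-2.0 * tau)
    profile = np.where(radii[:, None] > boundary[None, :], plateau[None, :], 0.0)
    profile[:, boundary >= geom.bottom] = 0.0
    return profile


def radial_grid(geom: CellGeometry, n: int = 500, clustering: float = 0.5) -> np.ndarray:
    """Radial solver grid on [m, b], smoothly clustered toward both ends.

    ``clustering`` in [0, 1): 0 gives a uniform grid; 0.5 roughly doubles
    the node density near meniscus and bottom where gradients are steepest.
    """
    xi = np.linspace(0.0, 1.0, n)
    x = xi - clustering / (2.0 * np.pi) * np.sin(2.0 * np.pi * xi)
    return geom.meniscus + (geom.bottom - geom.meniscus) * x


@dataclass
class _CNOperator:
    """Crank-Nicolson stepping operator for one (s, D, geometry, dt)."""

    lhs_lu: object
    rhs: csc_matrix

    def step(self, chi: np.ndarray) -> np.ndarray:
        return self.lhs_lu.solve(self.rhs @ chi)


def _bernoulli(x: np.ndarray) -> np.ndarray:
    """B(x) = x / (exp(x) - 1), the Scharfetter-Gummel weighting function,
    evaluated stably near x = 0 and for large |x|."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-8
    out[small] = 1.0 - 0.5 * x[small]
    xs = x[~small]
    with np.errstate(over="ignore"):
        out[~small] = np.where(xs > 500, 0.0, xs / np.expm1(np.clip(xs, None, 500)))
    return out


def _build_operator(
    r: np.ndarray, s: float, d_coef: float, omega_sq: float, dt: float
) -> _CNOperator:
    """Finite-volume spatial operator M with chi' = M chi, wrapped in a CN
    time-stepper (I - dt/2 M)^-1 (I + dt/2 M).  Zero flux at both walls.

    Face fluxes use Scharfetter-Gummel exponential fitting, which reduces
    to central differencing at low cell Peclet number and to upwinding at
    high Peclet number, keeping the scheme oscillation-free for weakly
    diffusing species."""
    n = len(r)
    faces = 0.5 * (r[:-1] + r[1:])
    # control volumes: integral of r dr over each cell ~ r_i * width_i
    left_edge = np.concatenate(([r[0]], faces))
    right_edge = np.concatenate((faces, [r[-1]]))
    vol = r * (right_edge - left_edge)
    vol[0] = max(vol[0], 1e-300)
    vol[-1] = max(vol[-1], 1e-300)

    h = np.diff(r)
    v_face = s * omega_sq * faces  # local sedimentation velocity at face
    pe = v_face * h / d_coef  # cell Peclet number
    # interior face flux F_i = a_i*chi_{i+1} - c_i*chi_i (positive F = flux
    # of material toward smaller r per the conservative form)
    base = faces * d_coef / h
    c_coef = base * _bernoulli(-pe)
    a_coef = base * _bernoulli(pe)

    lower = np.zeros(n)
    diag = np.zeros(n)
    upper = np.zeros(n)
    # dV_i chi_i/dt = F_i - F_{i-1}; boundary fluxes are zero
    diag[:-1] += -c_coef / vol[:-1]
    upper[:-1] += a_coef / vol[:-1]
    lower[1:] += c_coef / vol[1:]
    diag[1:] += -a_coef / vol[1:]

    idx = np.arange(n)
    rows = np.concatenate((idx, idx[:-1], idx[1:]))
    cols = np.concatenate((idx, idx[1:], idx[:-1]))
    vals = np.concatenate((diag, upper[:-1], lower[1:]))
    m_op = csc_matrix((vals, (rows, cols)), shape=(n, n))

    eye = identity(n, format="csc")
    lhs = (eye - 0.5 * dt * m_op).tocsc()
    rhs = (eye + 0.5 * dt * m_op).tocsc()
    return _CNOperator(lhs_lu=splu(lhs), rhs=rhs)


def solve_lamm(
    s: float,
    d_coef: float,
    rotor: RotorState,
    geom: CellGeometry,
    times: np.ndarray,
    radii: np.ndarray,
    n_grid: int = 400,
    courant: float = 1.0,
) -> np.ndarray:
    """Solve the Lamm equation for unit loading; return [n_radii x n_times].

    Crank-Nicolson finite-volume scheme on a fixed radial grid with mild
    clustering at meniscus and bottom; the time step is chosen so the
    sedimenting boundary advances less than ``courant`` grid cells per
    step.  D = 0 delegates to the analytic :func:`step_solution`.

    Parameters use CGS: s in seconds, D in cm^2/s, radii in cm, times in s.
    """
    if not np.isfinite(s) or not np.isfinite(d_coef):
        raise ValueError("s and D must be finite")
    if s <= 0:
        raise ValueError(f"s must be > 0, got {s}")
    if d_coef < 0:
        raise ValueError(f"D must be >= 0, got {d_coef}")
    times = np.atleast_1d(np.asarray(times, dtype=float))
    radii = np.atleast_1d(np.asarray(radii, dtype=float))
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    if d_coef == 0.0:
        return step_solution(s, rotor, geom, times, radii)

    r = radial_grid(geom, n=n_grid)
    t_end = float(times.max())
    # when the diffusive boundary width is below half the finest grid cell
    # no discretization can resolve it; the analytic step kernel is then
    # the more accurate model
    dr_min = float(np.diff(r).min())
    if t_end > 0 and np.sqrt(2.0 * d_coef * t_end) < 0.5 * dr_min:
        return step_solution(s, rotor, geom, times, radii)
    profile = np.empty((len(radii), len(times)))
    chi = np.ones(len(r))
    if t_end == 0.0:
        profile[:] = 1.0
        return profile

    # boundary velocity at the bottom bounds the front speed everywhere
    v_max = s * rotor.omega_sq * geom.bottom
    dt = courant * dr_min / v_max
    n_steps = max(2, int(np.ceil(t_end / dt)))
    dt = t_end / n_steps
    op = _build_operator(r, s, d_coef, rotor.omega_sq, dt)

    order = np.argsort(times)
    t_sorted = times[order]
    out_idx = 0
    # emit any t == 0 requests
    while out_idx < len(t_sorted) and t_sorted[out_idx] == 0.0:
        profile[:, order[out_idx]] = np.interp(radii, r, chi)
        out_idx += 1

    t_prev, chi_prev = 0.0, chi
    for k in range(1, n_steps + 1):
        t_now = k * dt
        chi_now = op.step(chi_prev)
        while out_idx < len(t_sorted) and t_sorted[out_idx] <= t_now + 1e-9 * t_end:
            # linear interpolation in time between CN steps (second order)
            w = (t_sorted[out_idx] - t_prev) / dt
            snap = (1.0 - w) * chi_prev + w * chi_now
            profile[:, order[out_idx]] = np.interp(radii, r, snap)
            out_idx += 1
        t_prev, chi_prev = t_now, chi_now
        if out_idx == len(t_sorted):
            break

    np.maximum(profile, 0.0, out=profile)
    return profile


class KernelCache:
    """Memo for Lamm-equation kernel evaluations within one fit iteration.

    Keyed on the full physical parameter set; callers must create a fresh
    cache (or rely on key mismatch) when nonlinear parameters change.
    """

    def __init__(self, maxsize: int = 4096) -> None:
        self._store: dict = {}
        self._maxsize = maxsize

    def get(
        self,
        s: float,
        d_coef: float,
        rotor: RotorState,
        geom: CellGeometry,
        times: np.ndarray,
        radii: np.ndarray,
        n_grid: int = 400,
    ) -> np.ndarray:
        key = (
            round(s, 20),
            round(d_coef, 20),
            rotor.rotor_speed,
            geom.meniscus,
            geom.bottom,
            times.tobytes(),
            radii.tobytes(),
            n_grid,
        )
        hit = self._store.get(key)
        if hit is None:
            if len(self._store) >= self._maxsize:
                self._store.clear()
            hit = solve_lamm(s, d_coef, rotor, geom, times, radii, n_grid=n_grid)
            self._store[key] = hit
        return hit
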
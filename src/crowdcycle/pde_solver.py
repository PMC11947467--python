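"""Method-of-lines solver for the two-compartment reaction-diffusion model.

Solves, with no-flux boundaries,

    d(rho1)/dt = D lap(rho1) - k1 rho1 f(rho) + 2 k2 rho2 g(rho)
    d(rho2)/dt = D lap(rho2) + k1 rho1 f(rho) -   k2 rho2 g(rho)

on a 1-D Cartesian interval or a radially symmetric disc.  The spatial
discretisation is a cell-centred finite-volume scheme (second-order central
differences in flux form); the radial Laplacian (1/r) d/dr (r d rho/dr) is
discretised with face radii so that the flux through the r = 0 face of the
innermost cell vanishes by symmetry.  No-flux boundaries and exact mass
conservation of the diffusion operator hold by construction.

Two time integrators are provided: an adaptive explicit Runge-Kutta
(scipy's RK45, the accuracy default) and a fixed-step classical RK4 under a
diffusive CFL bound, JIT-compiled with numba when available.  The fixed-step
path is what the Bayesian calibration uses inside its likelihood, where many
thousands of forward solves are needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model_core import CrowdingSpec, ModelParameters

__all__ = [
    "Grid",
    "InitialCondition",
    "SolverSettings",
    "SimulationResult",
    "IntegrationError",
    "simulate",
    "total_mass",
    "edge_position",
    "expansion_speed",
]

#: densities are cells/mm^2 while space is in um; integrals over um pick up
#: these factors to land back in cells (radial) or cells per mm width (1-D).
_UM_TO_MM = 1e-3

_KIND_CODE = {"linear": 0, "heaviside": 1, "constant": 2}


class IntegrationError(RuntimeError):
    """Raised when the forward solve loses validity (NaN/Inf or large
    negativity); carries the first bad output time in ``time_h``."""

    def __init__(self, message: str, time_h: float):
        super().__init__(message)
        self.time_h = time_h


@dataclass(frozen=True)
class Grid:
    """Uniform cell-centred grid on [0, L] (Cartesian) or [0, R] (radial).

    Nodes sit at cell centres ``(i + 1/2) dx``; the innermost radial volume
    element touches r = 0.
    """

    geometry: Literal["cartesian1d", "radial"]
    L: float
    N: int

    def __post_init__(self) -> None:
        if self.geometry not in ("cartesian1d", "radial"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.N < 3:
            raise ValueError(f"need N >= 3 grid cells, got {self.N}")
        if self.L <= 0:
            raise ValueError(f"domain size L must be positive, got {self.L}")

    @property
    def dx(self) -> float:
        return self.L / self.N

    @property
    def nodes(self) -> np.ndarray:
        return (np.arange(self.N) + 0.5) * self.dx

    def laplacian_weights(self) -> tuple[np.ndarray, np.ndarray]:
        """Left/right face weights: lap_i = wl_i (u_{i-1}-u_i) + wr_i (u_{i+1}-u_i).

        Boundary faces carry zero weight (no flux).  For both geometries the
        interior weights sum to 2/dx^2, so the diffusive CFL bound is the
        Cartesian one.
        """
        dx = self.dx
        i = np.arange(self.N, dtype=float)
        if self.geometry == "cartesian1d":
            wl = np.full(self.N, 1.0 / dx**2)
            wr = np.full(self.N, 1.0 / dx**2)
        else:
            centre = i + 0.5
            wl = i / (centre * dx**2)            # face radius i*dx; 0 at r=0
            wr = (i + 1.0) / (centre * dx**2)
        wl[0] = 0.0  # no-flux (automatically 0 radially: face at r=0)
        wr[-1] = 0.0
        return wl, wr

    def cell_measures(self) -> np.ndarray:
        """Integration weight of each cell: dx (um) in 1-D, 2 pi r dr (um^2)
        radially — before the um -> mm unit conversion."""
        if self.geometry == "cartesian1d":
            return np.full(self.N, self.dx)
        return 2.0 * math.pi * self.nodes * self.dx


@dataclass(frozen=True)
class InitialCondition:
    """Density profiles of both compartments on the grid nodes, cells/mm^2."""

    rho1: np.ndarray
    rho2: np.ndarray

    def __post_init__(self) -> None:
        r1 = np.asarray(self.rho1, dtype=float)
        r2 = np.asarray(self.rho2, dtype=float)
        object.__setattr__(self, "rho1", r1)
        object.__setattr__(self, "rho2", r2)
        if r1.shape != r2.shape or r1.ndim != 1:
            raise ValueError("rho1 and rho2 must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(r1)) and np.all(np.isfinite(r2))):
            raise ValueError("initial densities must be finite")
        if np.any(r1 < 0) or np.any(r2 < 0):
            raise ValueError("initial densities must be nonnegative")


@dataclass(frozen=True)
class SolverSettings:
    """Time-stepping control and output schedule.

    ``method="adaptive"`` uses scipy RK45 with ``rtol``/``atol``;
    ``method="fixed"`` takes classical RK4 steps bounded by
    ``cfl_safety * dx^2 / (2 D)`` (and by the reaction timescale).
    ``output_times`` are hours, strictly increasing, first >= 0.
    Negative undershoots smaller than ``negativity_rtol`` times the field
    scale are clamped to zero; anything larger raises IntegrationError.
    """

    output_times: Sequence[float] = field(default_factory=lambda: (0.0, 46.0))
    method: Literal["adaptive", "fixed"] = "adaptive"
    rtol: float = 1e-6
    atol: float = 1e-9
    cfl_safety: float = 0.9
    negativity_rtol: float = 1e-6

    def __post_init__(self) -> None:
        t = np.asarray(self.output_times, dtype=float)
        object.__setattr__(self, "output_times", t)
        if t.ndim != 1 or t.size < 1:
            raise ValueError("output_times must be a nonempty 1-D sequence")
        if t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ValueError("output_times must be strictly increasing, first >= 0")
        if self.method not in ("adaptive", "fixed"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass(frozen=True)
class SimulationResult:
    """Solution fields on the space-time output grid.

    ``rho1`` and ``rho2`` are (n_times, N) arrays in cells/mm^2.
    """

    grid: Grid
    times: np.ndarray
    rho1: np.ndarray
    rho2: np.ndarray

    @property
    def rho_total(self) -> np.ndarray:
        return self.rho1 + self.rho2

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: one row per (time, position)."""
        nt, nx = self.rho1.shape
        return pd.DataFrame(
            {
                "time_h": np.repeat(self.times, nx),
                "position_um": np.tile(self.grid.nodes, nt),
                "rho1": self.rho1.ravel(),
                "rho2": self.rho2.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# right-hand sides

def _rhs_numpy(params: ModelParameters, spec: CrowdingSpec, wl, wr):
    D, k1, k2 = params.D, params.k1, params.k2
    n = wl.size

    def rhs(t, y):
        r1 = y[:n]
        r2 = y[n:]
        rho = r1 + r2
        # crowding factors evaluated on the raw state; transient undershoots
        # are clipped so the factors stay defined
        f = spec.f(np.maximum(rho, 0.0), params)
        g = spec.g(np.maximum(rho, 0.0), params)
        a = k1 * f * r1
        b = k2 * g * r2
        lap1 = np.zeros(n)
        lap2 = np.zeros(n)
        lap1[1:] += wl[1:] * (r1[:-1] - r1[1:])
        lap1[:-1] += wr[:-1] * (r1[1:] - r1[:-1])
        lap2[1:] += wl[1:] * (r2[:-1] - r2[1:])
        lap2[:-1] += wr[:-1] * (r2[1:] - r2[:-1])
        return np.concatenate((D * lap1 - a + 2.0 * b, D * lap2 + a - b))

    return rhs


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    @njit(cache=True)
    def _crowd_nb(kind: int, rho: float, K: float) -> float:
        if kind == 0:
            v = 1.0 - rho / K
            return v if v > 0.0 else 0.0
        if kind == 1:
            return 1.0 if rho < K else 0.0
        return 1.0

    @njit(cache=True)
    def _rhs_nb(y, out, wl, wr, D, k1, k2, K1, K2, fk, gk):
        n = wl.size
        for i in range(n):
            r1 = y[i]
            r2 = y[n + i]
            rho = r1 + r2
            if rho < 0.0:
                rho = 0.0
            a = k1 * _crowd_nb(fk, rho, K1) * r1
            b = k2 * _crowd_nb(gk, rho, K2) * r2
            l1 = 0.0
            l2 = 0.0
            if i > 0:
                l1 += wl[i] * (y[i - 1] - r1)
                l2 += wl[i] * (y[n + i - 1] - r2)
            if i < n - 1:
                l1 += wr[i] * (y[i + 1] - r1)
                l2 += wr[i] * (y[n + i + 1] - r2)
            out[i] = D * l1 - a + 2.0 * b
            out[n + i] = D * l2 + a - b

    @njit(cache=True)
    def _rk4_nb(y, wl, wr, D, k1, k2, K1, K2, fk, gk, dt, nsteps):
        m = y.size
        s1 = np.empty(m)
        s2 = np.empty(m)
        s3 = np.empty(m)
        s4 = np.empty(m)
        tmp = np.empty(m)
        for _ in range(nsteps):
            _rhs_nb(y, s1, wl, wr, D, k1, k2, K1, K2, fk, gk)
            for j in range(m):
                tmp[j] = y[j] + 0.5 * dt * s1[j]
            _rhs_nb(tmp, s2, wl, wr, D, k1, k2, K1, K2, fk, gk)
            for j in range(m):
                tmp[j] = y[j] + 0.5 * dt * s2[j]
            _rhs_nb(tmp, s3, wl, wr, D, k1, k2, K1, K2, fk, gk)
            for j in range(m):
                tmp[j] = y[j] + dt * s3[j]
            _rhs_nb(tmp, s4, wl, wr, D, k1, k2, K1, K2, fk, gk)
            for j in range(m):
                y[j] = y[j] + dt / 6.0 * (s1[j] + 2.0 * s2[j] + 2.0 * s3[j] + s4[j])
        return y

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def _rk4_python(y, rhs, dt, nsteps, t0):
    t = t0
    for _ in range(nsteps):
        s1 = rhs(t, y)
        s2 = rhs(t + dt / 2, y + dt / 2 * s1)
        s3 = rhs(t + dt / 2, y + dt / 2 * s2)
        s4 = rhs(t + dt, y + dt * s3)
        y = y + dt / 6.0 * (s1 + 2 * s2 + 2 * s3 + s4)
        t += dt
    return y


# ---------------------------------------------------------------------------
# public driver

def simulate(
    params: ModelParameters,
    spec: CrowdingSpec,
    ic: InitialCondition,
    grid: Grid,
    settings: SolverSettings,
) -> SimulationResult:
    """Forward-solve the model; deterministic given its inputs.

    Returns densities at ``settings.output_times``.  The initial state is
    reported at the first output time (which acts as t = 0 of the solve).
    """
    if ic.rho1.size != grid.N:
        raise ValueError(
            f"initial condition has {ic.rho1.size} nodes but grid has {grid.N}"
        )
    wl, wr = grid.laplacian_weights()
    times = np.asarray(settings.output_times, dtype=float)
    y0 = np.concatenate((ic.rho1, ic.rho2))
    scale = max(float(np.max(np.abs(y0))), 1.0)
    neg_tol = settings.negativity_rtol * scale

    if settings.method == "adaptive":
        rhs = _rhs_numpy(params, spec, wl, wr)
        sol = solve_ivp(
            rhs,
            (times[0], times[-1]),
            y0,
            method="RK45",
            t_eval=times,
            rtol=settings.rtol,
            atol=settings.atol,
        )
        if not sol.success or sol.y.shape[1] != times.size:
            t_bad = float(sol.t[-1]) if sol.t.size else float(times[0])
            raise IntegrationError(
                f"adaptive integration failed at t={t_bad:.3f} h: {sol.message}",
                t_bad,
            )
        states = sol.y.T.copy()
    else:
        dt_diff = settings.cfl_safety * grid.dx**2 / (2.0 * params.D) if params.D > 0 else math.inf
        dt_react = 0.25 / (params.k1 + params.k2)
        dt_max = min(dt_diff, dt_react)
        states = np.empty((times.size, y0.size))
        states[0] = y0
        y = y0.copy()
        use_nb = _HAVE_NUMBA
        rhs = None if use_nb else _rhs_numpy(params, spec, wl, wr)
        for j in range(1, times.size):
            span = times[j] - times[j - 1]
            nsteps = max(1, int(math.ceil(span / dt_max)))
            dt = span / nsteps
            if use_nb:
                y = _rk4_nb(
                    y,
                    wl,
                    wr,
                    params.D,
                    params.k1,
                    params.k2,
                    params.K1,
                    params.K2,
                    _KIND_CODE[spec.kind_f],
                    _KIND_CODE[spec.kind_g],
                    dt,
                    nsteps,
                )
            else:
                y = _rk4_python(y, rhs, dt, nsteps, times[j - 1])
            states[j] = y

    # validity + negativity guard
    for j, t in enumerate(times):
        row = states[j]
        if not np.all(np.isfinite(row)):
            raise IntegrationError(
                f"non-finite state at t={t:.3f} h", float(t)
            )
        low = row.min()
        if low < -neg_tol:
            raise IntegrationError(
                f"negative density {low:.3e} (tolerance {neg_tol:.3e}) at t={t:.3f} h",
                float(t),
            )
    states = np.maximum(states, 0.0)

    n = grid.N
    return SimulationResult(
        grid=grid, times=times, rho1=states[:, :n], rho2=states[:, n:]
    )


def total_mass(result: SimulationResult, time_index: int) -> float:
    """Total cell count at one output time.

    Cartesian: integral of rho dx per unit transverse width, returned in
    cells per mm of width (um -> mm conversion applied).  Radial:
    2 pi * integral of rho r dr, returned in cells.
    """
    nt = result.times.size
    if not -nt <= time_index < nt:
        raise IndexError(f"time index {time_index} out of range for {nt} outputs")
    w = result.grid.cell_measures()
    rho = result.rho_total[time_index]
    if result.grid.geometry == "cartesian1d":
        return float(np.sum(rho * w) * _UM_TO_MM)
    return float(np.sum(rho * w) * _UM_TO_MM**2)


def edge_position(
    positions: np.ndarray, profile: np.ndarray, threshold: float
) -> Optional[float]:
    """Outermost position where the profile crosses ``threshold``, um.

    Linear interpolation between the bracketing nodes; ``None`` (the
    "no-edge" marker) if the profile never reaches the threshold.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    positions = np.asarray(positions, dtype=float)
    profile = np.asarray(profile, dtype=float)
    above = np.nonzero(profile >= threshold)[0]
    if above.size == 0:
        return None
    i = above[-1]
    if i == positions.size - 1:
        return float(positions[-1])
    # profile[i] >= threshold > profile[i+1]
    p0, p1 = profile[i], profile[i + 1]
    x0, x1 = positions[i], positions[i + 1]
    if p0 == p1:
        return float(x0)
    return float(x0 + (p0 - threshold) / (p0 - p1) * (x1 - x0))


def expansion_speed(
    result: SimulationResult,
    threshold: float,
    window: tuple[float, float],
) -> float:
    """Front speed, um/h: least-squares slope of edge position vs time.

    Uses output times inside ``window`` (inclusive) at which an edge exists;
    at least three such times are required.
    """
    t0, t1 = window
    ts, xs = [], []
    for j, t in enumerate(result.times):
        if t0 <= t <= t1:
            x = edge_position(result.grid.nodes, result.rho_total[j], threshold)
            if x is not None:
                ts.append(t)
                xs.append(x)
    if len(ts) < 3:
        raise ValueError(
            f"need >= 3 output times with a defined edge in window {window}, got {len(ts)}"
        )
    slope = np.polyfit(ts, xs, 1)[0]
    return float(slope)
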
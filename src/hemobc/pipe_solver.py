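"""Finite-difference unsteady axisymmetric pipe flow.

Independent numerical oracle for the analytic Womersley profile
generator: the axial momentum equation for fully developed axisymmetric
flow in a rigid circular pipe,

    du/dt = G(t)/rho + nu (1/r) d/dr (r du/dr),

with no slip at r = R and regularity (du/dr = 0) at the axis, driven by
a periodic axial pressure-gradient forcing G(t) = -dp/dx.  The solver
uses Crank-Nicolson in time and second-order central differences in
radius (ghost node at the axis), so it converges at second order in
both dr and dt to the closed-form Womersley solution — an accuracy the
first-order schemes typical of production CFD codes do not need, but an
oracle does.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import solve_banded
from scipy.special import jv

__all__ = ["PipeProblem", "PipeSolution", "solve", "womersley_exact"]

_I32 = np.exp(0.75j * np.pi)  # i^(3/2)


@dataclass(frozen=True)
class PipeProblem:
    """Pulsatile pipe-flow problem definition.

    ``gradient_harmonics`` are the complex amplitudes G_n of the
    pressure-gradient forcing for harmonics n = 1..N of the fundamental
    angular frequency; ``mean_gradient`` is the steady component G_0.
    The physical forcing is ``G(t) = G_0 + sum_n Re{G_n e^{i n w t}}``
    in Pa/m, with positive G driving positive u.
    """

    radius: float
    kinematic_viscosity: float
    density: float
    fundamental_angular_frequency: float
    mean_gradient: float = 0.0
    gradient_harmonics: Sequence[complex] = field(default_factory=tuple)
    n_radial: int = 128
    dt: float = None

    def __post_init__(self):
        if min(self.radius, self.kinematic_viscosity, self.density) <= 0:
            raise ValueError("radius, viscosity and density must be positive")
        if self.fundamental_angular_frequency <= 0:
            raise ValueError("fundamental angular frequency must be positive")
        if self.n_radial < 8:
            raise ValueError("need at least 8 radial nodes")
        object.__setattr__(
            self, "gradient_harmonics", tuple(complex(g) for g in self.gradient_harmonics)
        )
        if self.dt is None:
            object.__setattr__(self, "dt", self.period / 512.0)
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def period(self) -> float:
        return 2.0 * np.pi / self.fundamental_angular_frequency

    def womersley_number(self, n: int = 1) -> float:
        return self.radius * np.sqrt(
            n * self.fundamental_angular_frequency / self.kinematic_viscosity
        )

    def forcing(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        g = np.full_like(t, self.mean_gradient, dtype=float)
        w = self.fundamental_angular_frequency
        for n, Gn in enumerate(self.gradient_harmonics, start=1):
            g = g + np.real(Gn * np.exp(1j * n * w * t))
        return g


@dataclass(frozen=True)
class PipeSolution:
    """Velocity u(r, t) over the final simulated cycle."""

    r: np.ndarray  # (N_r + 1,) radial nodes, 0..R
    times: np.ndarray  # (n_t,) within the final cycle, starting at phase 0
    u: np.ndarray  # (n_t, N_r + 1)
    periodicity_residual: float

    def flow_rate(self) -> np.ndarray:
        """Cross-sectional flow rate 2 pi int u r dr at each time."""
        return 2.0 * np.pi * np.trapezoid(self.u * self.r, self.r, axis=1)


def womersley_exact(problem: PipeProblem, r, t) -> np.ndarray:
    """Closed-form periodic solution for the given forcing harmonics.

    Steady part: Poiseuille, ``G_0 (R^2 - r^2) / (4 rho nu)``.  Each
    harmonic: ``Re{ (G_n / (i rho n w)) [1 - J0(i^{3/2} a_n r/R) /
    J0(i^{3/2} a_n)] e^{i n w t} }``.
    """
    r = np.asarray(r, dtype=float)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    R = problem.radius
    rho, nu = problem.density, problem.kinematic_viscosity
    w = problem.fundamental_angular_frequency
    u = np.multiply.outer(
        np.ones(t.size), problem.mean_gradient * (R**2 - r**2) / (4.0 * rho * nu)
    )
    for n, Gn in enumerate(problem.gradient_harmonics, start=1):
        alpha = problem.womersley_number(n)
        z = _I32 * alpha
        prof = (Gn / (1j * rho * n * w)) * (1.0 - jv(0, z * r / R) / jv(0, z))
        u = u + np.real(np.multiply.outer(np.exp(1j * n * w * t), prof))
    return u if u.shape[0] > 1 else u[0]


def analytic_flow_harmonics(problem: PipeProblem) -> tuple[float, np.ndarray]:
    """Mean flow and complex flow-rate amplitudes Q_n of the exact solution.

    Useful for constructing a flow waveform that corresponds exactly to
    the pressure-gradient forcing of ``problem``.
    """
    R = problem.radius
    rho, nu = problem.density, problem.kinematic_viscosity
    w = problem.fundamental_angular_frequency
    q_mean = problem.mean_gradient * np.pi * R**4 / (8.0 * rho * nu)
    Qn = []
    for n, Gn in enumerate(problem.gradient_harmonics, start=1):
        alpha = problem.womersley_number(n)
        z = _I32 * alpha
        bracket = 1.0 - 2.0 * jv(1, z) / (z * jv(0, z))
        Qn.append((Gn / (1j * rho * n * w)) * np.pi * R**2 * bracket)
    return q_mean, np.asarray(Qn, dtype=complex)


def solve(
    problem: PipeProblem,
    n_cycles: int = 4,
    initial_condition: np.ndarray | str = "zero",
) -> PipeSolution:
    """March the pipe-flow equation and return the final cycle.

    ``initial_condition`` is ``"zero"``, ``"analytic"`` (start on the
    closed-form periodic solution so the viscous transient is absent
    from the first cycle), or an explicit array of nodal velocities.
    The periodicity residual ``max |u_final - u_previous|`` over the
    last two cycles indicates how completely the transient has decayed.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be at least 1")
    Nr = problem.n_radial
    R = problem.radius
    nu = problem.kinematic_viscosity
    rho = problem.density
    dr = R / Nr
    r = np.arange(Nr + 1) * dr
    dt = problem.dt
    steps_per_cycle = int(round(problem.period / dt))
    if abs(steps_per_cycle * dt - problem.period) > 1e-9 * problem.period:
        raise ValueError("dt must divide the period evenly")

    if isinstance(initial_condition, str):
        if initial_condition == "zero":
            u = np.zeros(Nr + 1)
        elif initial_condition == "analytic":
            u = womersley_exact(problem, r, 0.0)
        else:
            raise ValueError("initial_condition must be 'zero', 'analytic' or array")
    else:
        u = np.array(initial_condition, dtype=float)
        if u.shape != (Nr + 1,):
            raise ValueError(f"initial condition must have shape ({Nr + 1},)")
    u[-1] = 0.0  # no slip

    # spatial operator L u = (1/r) d/dr (r du/dr), interior nodes 1..Nr-1
    j = np.arange(1, Nr)
    lower = (1.0 - 0.5 / j) / dr**2
    diag_in = -2.0 / dr**2 * np.ones(Nr - 1)
    upper = (1.0 + 0.5 / j) / dr**2
    # axis node (j=0): ghost symmetry gives L u|_0 = 4 (u_1 - u_0) / dr^2

    lam = 0.5 * nu * dt
    n_un = Nr  # unknowns: nodes 0..Nr-1 (wall fixed at 0)
    ab = np.zeros((3, n_un))  # banded (I - lam L)
    ab[1, 0] = 1.0 + lam * 4.0 / dr**2
    ab[0, 1] = -lam * 4.0 / dr**2
    ab[1, 1:] = 1.0 - lam * diag_in
    ab[0, 2:] = -lam * upper[:-1]
    ab[2, :-1] = np.concatenate([[-lam * lower[0]], -lam * lower[1:]])

    def apply_L(v):
        out = np.empty(Nr + 1)
        out[0] = 4.0 * (v[1] - v[0]) / dr**2
        out[j] = lower * v[j - 1] + diag_in * v[j] + upper * v[j + 1]
        out[-1] = 0.0
        return out

    n_total = steps_per_cycle * n_cycles
    hist = np.zeros((n_total + 1, Nr + 1))
    hist[0] = u
    times = np.arange(n_total + 1) * dt
    for step in range(n_total):
        g0 = problem.forcing(times[step]) / rho
        g1 = problem.forcing(times[step + 1]) / rho
        rhs_full = u + dt * (0.5 * (g0 + g1) + 0.5 * nu * apply_L(u))
        sol = solve_banded((1, 1), ab, rhs_full[:-1])
        u = np.append(sol, 0.0)
        hist[step + 1] = u

    final = hist[-(steps_per_cycle + 1) :]
    final_t = times[-(steps_per_cycle + 1) :]
    if n_cycles >= 2:
        prev = hist[-(2 * steps_per_cycle + 1) : -steps_per_cycle]
        residual = float(np.max(np.abs(final - prev)))
    else:
        residual = float("inf")
    return PipeSolution(r=r, times=final_t, u=final, periodicity_residual=residual)
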
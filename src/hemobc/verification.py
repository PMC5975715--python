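"""Cross-verification of the Womersley generator against the pipe solver.

The analytic Womersley profile generator and the Crank-Nicolson
finite-difference pipe solver reach the same physics by entirely
different routes: Bessel-function evaluation of the closed-form
harmonic solution versus time-marching the axisymmetric momentum
equation from a pressure-gradient forcing.  Agreement between the two
therefore validates both the Bessel formulation (branch conventions,
normalization) and the finite-difference discretization.

The comparison is made per harmonic: a single pressure-gradient
harmonic of Womersley number alpha drives the pipe solver; its analytic
flow-rate amplitude is handed to the profile generator as a one-term
Fourier waveform; and the two velocity fields are compared as functions
of the normalized radial coordinate rho on an inlet patch, so that both
describe the same prescribed flow rate in the same coordinates.
"""

from __future__ import annotations

import numpy as np

from . import pipe_solver as ps
from .inlet_profiles import womersley_profile
from .patch import InletPatch
from .waveform import FourierWaveform

__all__ = ["compare_womersley_to_pipe_solver"]

BLOOD_KINEMATIC_VISCOSITY = 0.004 / 1060.0  # m^2/s
BLOOD_DENSITY = 1060.0  # kg/m^3


def compare_womersley_to_pipe_solver(
    patch: InletPatch,
    alpha: float,
    n_radial: int = 128,
    steps_per_cycle: int = 512,
    n_cycles: int = 2,
    n_compare_times: int = 16,
    gradient_amplitude: float = 100.0,
    kinematic_viscosity: float = BLOOD_KINEMATIC_VISCOSITY,
    density: float = BLOOD_DENSITY,
) -> dict:
    """L-infinity mismatch between generator and finite-difference oracle.

    A single forcing harmonic with Womersley number ``alpha`` (on the
    patch's effective radius) is marched by the finite-difference
    solver; the generator evaluates the closed-form profile for the
    corresponding flow-rate harmonic.  Returns a dict with the relative
    L-infinity error over ``n_compare_times`` instants of the final
    cycle and the velocity scale used for normalization.
    """
    R = patch.effective_radius
    nu = kinematic_viscosity
    omega = alpha**2 * nu / R**2
    period = 2.0 * np.pi / omega

    problem = ps.PipeProblem(
        radius=R,
        kinematic_viscosity=nu,
        density=density,
        fundamental_angular_frequency=omega,
        gradient_harmonics=[complex(gradient_amplitude)],
        n_radial=n_radial,
        dt=period / steps_per_cycle,
    )
    solution = ps.solve(problem, n_cycles=n_cycles, initial_condition="analytic")

    # flow-rate harmonic equivalent to the pressure-gradient forcing
    q_mean, Qn = ps.analytic_flow_harmonics(problem)
    fw = FourierWaveform(
        mean_flow=q_mean,
        cosine_coeffs=np.array([Qn[0].real]),
        sine_coeffs=np.array([-Qn[0].imag]),
        fundamental_angular_frequency=omega,
    )

    stride = max(1, steps_per_cycle // n_compare_times)
    times = solution.times[::stride]
    u_gen = np.atleast_2d(womersley_profile(patch, fw, nu, times))

    rho = patch.boundary_rho()
    err_max = 0.0
    scale = 0.0
    for k, t in enumerate(times):
        k_fd = int(round((t - solution.times[0]) / problem.dt))
        u_fd = np.interp(rho * R, solution.r, solution.u[k_fd])
        err_max = max(err_max, float(np.max(np.abs(u_gen[k] - u_fd))))
        scale = max(scale, float(np.max(np.abs(u_fd))))
    return {
        "linf_error": err_max,
        "velocity_scale": scale,
        "linf_relative_error": err_max / scale,
        "alpha": alpha,
        "n_radial": n_radial,
        "steps_per_cycle": steps_per_cycle,
    }
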
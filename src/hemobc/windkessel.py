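"""Two- and three-element Windkessel outlet pressure models.

The three-element (RCR) Windkessel is the electric-circuit analogue of
the distal vasculature: a proximal resistance R_p in series with a
parallel pair of a compliance C and a distal resistance R_d.  The
outlet pressure p obeys the linear ODE

    dp/dt + p / (C R_d) = (Q / C) (1 + R_p / R_d) + R_p dQ/dt,

driven by the vessel flow rate Q(t).  The two-element (RC) model is the
special case R_p = 0.  Time integration is fully implicit (backward
Euler) with dQ/dt discretized by the backward difference, which is
unconditionally stable for any step size — important because
physiological time constants R_d C (~0.5-1.5 s) are comparable to the
cardiac period.

Parameter tables in the hemodynamics literature are quoted in CGS units
(dyn s/cm^5 for resistances, cm^5/dyn for compliance); SI equivalents
are Pa s/m^3 and m^3/Pa with 1 dyn s/cm^5 = 1e5 Pa s/m^3.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

from .waveform import FourierWaveform

__all__ = [
    "WindkesselParams",
    "WindkesselState",
    "WindkesselResult",
    "convert_units",
    "step_implicit",
    "simulate",
    "frequency_response",
    "read_params_json",
    "RESISTANCE_CGS_TO_SI",
    "CAPACITANCE_CGS_TO_SI",
]

#: 1 dyn s/cm^5 in Pa s/m^3.
RESISTANCE_CGS_TO_SI = 1.0e5
#: 1 cm^5/dyn in m^3/Pa.
CAPACITANCE_CGS_TO_SI = 1.0e-5


@dataclass(frozen=True)
class WindkesselParams:
    """Windkessel element values.

    ``proximal_resistance`` (R_p) is zero for the two-element model;
    ``capacitance`` (C) and ``distal_resistance`` (R_d) are present in
    both.  ``units`` tags the value system ('SI' or 'CGS').
    """

    proximal_resistance: float
    capacitance: float
    distal_resistance: float
    units: str = "SI"

    def __post_init__(self):
        if self.units not in ("SI", "CGS"):
            raise ValueError("units must be 'SI' or 'CGS'")
        if self.capacitance <= 0:
            raise ValueError("capacitance must be positive")
        if self.distal_resistance <= 0:
            raise ValueError("distal resistance must be positive")
        if self.proximal_resistance < 0:
            raise ValueError("proximal resistance must be non-negative")

    @property
    def total_resistance(self) -> float:
        return self.proximal_resistance + self.distal_resistance

    @property
    def time_constant(self) -> float:
        """RC decay time constant R_d C, seconds (in SI units)."""
        return self.distal_resistance * self.capacitance


@dataclass(frozen=True)
class WindkesselState:
    """Evolving outlet pressure state."""

    pressure: float
    time: float = 0.0

    def __post_init__(self):
        if not (np.isfinite(self.pressure) and np.isfinite(self.time)):
            raise ValueError("state must be finite")


@dataclass(frozen=True)
class WindkesselResult:
    """Pressure trace from :func:`simulate` plus the periodicity residual."""

    times: np.ndarray
    pressures: np.ndarray
    periodicity_residual: float


def convert_units(params: WindkesselParams, target: str) -> WindkesselParams:
    """Convert parameter values between SI and CGS; round trip is identity."""
    if target not in ("SI", "CGS"):
        raise ValueError("target units must be 'SI' or 'CGS'")
    if target == params.units:
        return params
    if target == "SI":  # CGS -> SI
        r, c = RESISTANCE_CGS_TO_SI, CAPACITANCE_CGS_TO_SI
    else:  # SI -> CGS
        r, c = 1.0 / RESISTANCE_CGS_TO_SI, 1.0 / CAPACITANCE_CGS_TO_SI
    return replace(
        params,
        proximal_resistance=params.proximal_resistance * r,
        capacitance=params.capacitance * c,
        distal_resistance=params.distal_resistance * r,
        units=target,
    )


def step_implicit(
    params: WindkesselParams,
    state: WindkesselState,
    Q_now: float,
    Q_next: float,
    dt: float,
) -> WindkesselState:
    """One backward-Euler step of the Windkessel ODE.

    Solves

        p_next (1/dt + 1/(C R_d)) = p_now/dt
                                    + (Q_next/C)(1 + R_p/R_d)
                                    + R_p (Q_next - Q_now)/dt

    for ``p_next``; unconditionally stable for any ``dt > 0``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    Rp, C, Rd = (
        params.proximal_resistance,
        params.capacitance,
        params.distal_resistance,
    )
    rhs = (
        state.pressure / dt
        + (Q_next / C) * (1.0 + Rp / Rd)
        + Rp * (Q_next - Q_now) / dt
    )
    p_next = rhs / (1.0 / dt + 1.0 / (C * Rd))
    return WindkesselState(pressure=p_next, time=state.time + dt)


def simulate(
    params: WindkesselParams,
    fw: FourierWaveform,
    dt: float = 0.01,
    n_cycles: int = 5,
    p_init: float | None = None,
) -> WindkesselResult:
    """Integrate the Windkessel ODE over ``n_cycles`` cardiac cycles.

    ``p_init`` defaults to the steady-state pressure at the mean flow,
    ``Q_mean (R_p + R_d)``, the fastest start toward the periodic
    regime.  The periodicity residual is ``max |p(t) - p(t - T)|`` over
    the final cycle, a convergence diagnostic for the cycle count.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_cycles < 1:
        raise ValueError("n_cycles must be at least 1")
    T = fw.period
    steps_per_cycle = int(round(T / dt))
    if steps_per_cycle < 2:
        raise ValueError("dt too large: fewer than 2 steps per cycle")
    n_steps = steps_per_cycle * n_cycles
    times = np.arange(n_steps + 1) * dt
    Q = np.asarray(fw.evaluate(times), dtype=float)
    if p_init is None:
        p_init = fw.mean_flow * params.total_resistance
    p = np.empty(n_steps + 1)
    p[0] = p_init
    state = WindkesselState(pressure=p_init, time=0.0)
    for k in range(n_steps):
        state = step_implicit(params, state, Q[k], Q[k + 1], dt)
        p[k + 1] = state.pressure
    last = p[-steps_per_cycle:]
    prev = p[-2 * steps_per_cycle : -steps_per_cycle]
    residual = float(np.max(np.abs(last - prev))) if n_cycles >= 2 else float("inf")
    return WindkesselResult(times=times, pressures=p, periodicity_residual=residual)


def frequency_response(params: WindkesselParams, omega: float) -> complex:
    """Complex impedance p_hat / Q_hat at angular frequency ``omega``.

    Closed form for the periodic steady state of the Windkessel ODE:
    ``Z(w) = R_p + R_d / (1 + i w C R_d)``.  At w = 0 this is the total
    resistance R_p + R_d.
    """
    return params.proximal_resistance + params.distal_resistance / (
        1.0 + 1j * omega * params.capacitance * params.distal_resistance
    )


def read_params_json(path) -> WindkesselParams:
    """Read a parameter JSON with fields ``Rp``, ``C``, ``Rd``, ``units``."""
    with open(path) as fh:
        data = json.load(fh)
    try:
        return WindkesselParams(
            proximal_resistance=float(data.get("Rp", 0.0)),
            capacitance=float(data["C"]),
            distal_resistance=float(data["Rd"]),
            units=data.get("units", "CGS"),
        )
    except KeyError as exc:
        raise ValueError(f"{path}: missing Windkessel field {exc}") from exc
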
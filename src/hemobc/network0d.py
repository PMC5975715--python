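"""Single-junction 0D outlet networks: prescribed splits or Windkessels.

A desk-scale analogue of the outlet boundary-condition comparison in a
3-D vessel model: one inlet waveform feeds a junction from which N
terminal branches leave.  Two terminal treatments are supported:

* ``outflow`` — each outlet carries a prescribed percentage of the
  instantaneous inlet flow (the splits must sum to 100%),
* ``windkessel`` — each outlet ends in an RC or RCR Windkessel; a
  common junction pressure and the per-outlet flows are found by
  solving, at every implicit time step, the exact linear system

      Q_in = sum_i Q_i
      P_j  = p_c,i + R_p,i Q_i                       (terminal i)
      C_i (p_c,i' - p_c,i) / dt = Q_i - p_c,i'/R_d,i (compliance i)

  monolithically (unknowns P_j, {p_c,i'}, {Q_i}).  R_p = 0 terminals
  degenerate to P_j = p_c,i and the junction equation aggregates their
  compliances; the monolithic system covers both cases and mixtures.

Mass is conserved exactly at every step by construction of the junction
equation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .waveform import FourierWaveform
from .windkessel import WindkesselParams, convert_units

__all__ = [
    "OutletSpec",
    "NetworkResult",
    "fill_remainder",
    "solve_outflow",
    "solve_windkessel_network",
]

_FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class OutletSpec:
    """One terminal branch of the network.

    ``mode`` is ``"outflow"`` (prescribed percentage ``flow_fraction``)
    or ``"windkessel"`` (lumped ``params``).  A ``flow_fraction`` of
    None marks the outlet whose split is completed by mass conservation
    (see :func:`fill_remainder`).
    """

    name: str
    mode: str
    flow_fraction: Optional[float] = None  # percent of inlet flow
    params: Optional[WindkesselParams] = None

    def __post_init__(self):
        if self.mode not in ("outflow", "windkessel"):
            raise ValueError("mode must be 'outflow' or 'windkessel'")
        if self.mode == "outflow":
            if self.flow_fraction is not None and not (
                0.0 <= self.flow_fraction <= 100.0
            ):
                raise ValueError("flow_fraction must be in [0, 100] percent")
        elif self.params is None:
            raise ValueError("windkessel outlets need params")


@dataclass(frozen=True)
class NetworkResult:
    """Per-outlet flows, junction pressure, and the conservation residual."""

    times: np.ndarray
    outlet_names: tuple
    flows: np.ndarray  # (n_times, n_outlets), m^3/s
    junction_pressure: Optional[np.ndarray]  # (n_times,), Pa; None for outflow
    conservation_residual: float

    def flow(self, name: str) -> np.ndarray:
        return self.flows[:, self.outlet_names.index(name)]


def fill_remainder(specs: Sequence[OutletSpec]) -> list[OutletSpec]:
    """Complete at most one unset outflow fraction by mass conservation."""
    unset = [s for s in specs if s.mode == "outflow" and s.flow_fraction is None]
    if len(unset) > 1:
        raise ValueError("at most one outlet may leave its fraction unset")
    if not unset:
        return list(specs)
    known = sum(s.flow_fraction for s in specs if s.flow_fraction is not None)
    remainder = 100.0 - known
    if remainder < -_FRACTION_TOL:
        raise ValueError(f"prescribed fractions already exceed 100% ({known}%)")
    out = []
    for s in specs:
        if s is unset[0]:
            out.append(
                OutletSpec(name=s.name, mode="outflow", flow_fraction=remainder)
            )
        else:
            out.append(s)
    return out


def solve_outflow(
    specs: Sequence[OutletSpec], fw: FourierWaveform, times
) -> NetworkResult:
    """Distribute the inlet waveform by prescribed percentage splits."""
    specs = fill_remainder(specs)
    if any(s.mode != "outflow" for s in specs):
        raise ValueError("solve_outflow requires all outlets in outflow mode")
    fractions = np.array([s.flow_fraction for s in specs], dtype=float)
    if abs(fractions.sum() - 100.0) > _FRACTION_TOL:
        raise ValueError(
            f"outflow fractions must sum to 100%, got {fractions.sum()!r}"
        )
    times = np.atleast_1d(np.asarray(times, dtype=float))
    Q_in = np.atleast_1d(np.asarray(fw.evaluate(times), dtype=float))
    flows = np.multiply.outer(Q_in, fractions / 100.0)
    residual = float(np.max(np.abs(flows.sum(axis=1) - Q_in), initial=0.0))
    return NetworkResult(
        times=times,
        outlet_names=tuple(s.name for s in specs),
        flows=flows,
        junction_pressure=None,
        conservation_residual=residual,
    )


def solve_windkessel_network(
    specs: Sequence[OutletSpec],
    fw: FourierWaveform,
    dt: float = 0.01,
    n_cycles: int = 5,
) -> NetworkResult:
    """Couple N Windkessel terminals at a common junction pressure.

    Backward-Euler in time; per step, one exact linear solve for the
    junction pressure, the compliance pressures, and the outlet flows.
    Compliance states start at the steady-state division of the mean
    inlet flow (inverse-total-resistance divider).
    """
    if any(s.mode != "windkessel" for s in specs):
        raise ValueError("solve_windkessel_network requires windkessel outlets")
    if dt <= 0 or n_cycles < 1:
        raise ValueError("need dt > 0 and n_cycles >= 1")
    params = [convert_units(s.params, "SI") for s in specs]
    n = len(params)
    Rp = np.array([p.proximal_resistance for p in params])
    Rd = np.array([p.distal_resistance for p in params])
    C = np.array([p.capacitance for p in params])

    T = fw.period
    steps_per_cycle = int(round(T / dt))
    n_steps = steps_per_cycle * n_cycles
    times = np.arange(n_steps + 1) * dt
    Q_in = np.atleast_1d(np.asarray(fw.evaluate(times), dtype=float))

    # steady-state initialization at the mean flow
    g_total = (1.0 / (Rp + Rd)).sum()
    q0 = fw.mean_flow * (1.0 / (Rp + Rd)) / g_total
    p_c = q0 * Rd  # compliance node pressure at steady state

    # unknown vector x = [P_j, p_c_1..n, Q_1..n]
    flows = np.zeros((n_steps + 1, n))
    pj = np.zeros(n_steps + 1)

    A = np.zeros((2 * n + 1, 2 * n + 1))
    rhs = np.zeros(2 * n + 1)
    # junction: sum_i Q_i = Q_in
    A[0, n + 1 :] = 1.0
    for i in range(n):
        # terminal: P_j - p_c_i - Rp_i Q_i = 0
        A[1 + i, 0] = 1.0
        A[1 + i, 1 + i] = -1.0
        A[1 + i, n + 1 + i] = -Rp[i]
        # compliance: (C_i/dt + 1/Rd_i) p_c_i' - Q_i = C_i/dt * p_c_i_old
        A[1 + n + i, 1 + i] = C[i] / dt + 1.0 / Rd[i]
        A[1 + n + i, n + 1 + i] = -1.0

    # sample 0 is a consistency step from the steady initialization, so
    # every reported sample satisfies the junction balance exactly
    for k in range(n_steps + 1):
        rhs[0] = Q_in[k]
        rhs[1 + n :] = C / dt * p_c
        x = np.linalg.solve(A, rhs)
        pj[k] = x[0]
        p_c = x[1 : n + 1]
        flows[k] = x[n + 1 :]

    residual = float(np.max(np.abs(flows.sum(axis=1) - Q_in)))
    return NetworkResult(
        times=times,
        outlet_names=tuple(s.name for s in specs),
        flows=flows,
        junction_pressure=pj,
        conservation_residual=residual,
    )
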
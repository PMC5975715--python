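"""Deterministic synthetic inputs: patches, waveforms, toy wall fields.

Everything a test or a demonstration run needs is generated here, with
no external data: structured disk/ellipse triangulations, the synthetic
aortic waveform, and toy wall-shear-stress field pairs whose comparison
statistics are recorded alongside by an independent brute-force
summation.  All generators are fully deterministic under a fixed seed.

The module also carries two parameter tables for an adult thoracic
aorta model with four supra-aortic branches, in the units conventional
in the lumped-parameter literature: percentage outflow splits and
RCR Windkessel element values (CGS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import WallField
from .patch import InletPatch, _recenter_and_build
from .waveform import FlowWaveform, synthetic_aortic_waveform
from .windkessel import WindkesselParams

__all__ = [
    "FixtureConfig",
    "make_patch",
    "make_wall_field",
    "make_waveform",
    "AORTA_OUTFLOW_SPLITS",
    "AORTA_WINDKESSEL_CGS",
]

#: Percentage outflow splits for an adult thoracic aorta model:
#: four supra-aortic branches, remainder through the descending aorta.
AORTA_OUTFLOW_SPLITS = {
    "right_common_carotid": 9.8,
    "right_subclavian": 9.5,
    "left_common_carotid": 5.2,
    "left_subclavian": 6.4,
    "descending_aorta": 69.1,
}

#: RCR Windkessel element values (CGS: dyn s/cm^5, cm^5/dyn) for the
#: same aorta model; R_p applies to the three-element variant only.
AORTA_WINDKESSEL_CGS = {
    "right_common_carotid": WindkesselParams(1180.0, 7.70e-5, 18400.0, units="CGS"),
    "right_subclavian": WindkesselParams(1040.0, 8.74e-5, 16300.0, units="CGS"),
    "left_common_carotid": WindkesselParams(1180.0, 7.70e-5, 18400.0, units="CGS"),
    "left_subclavian": WindkesselParams(970.0, 9.34e-5, 15200.0, units="CGS"),
    "descending_aorta": WindkesselParams(188.0, 4.82e-4, 2950.0, units="CGS"),
}


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs for the synthetic generators.

    ``kind`` selects the patch outline; ``radius`` is the disk radius or
    the ellipse's first semi-axis (``semi_axis_b`` the second);
    ``n_rings`` the radial mesh density; ``seed`` fixes all random
    sampling in the toy wall fields.
    """

    kind: str = "circle"
    radius: float = 0.01  # m; aortic-root scale
    semi_axis_b: float = None
    n_rings: int = 24
    seed: int = 0
    n_facets: int = 64
    n_times: int = 33

    def __post_init__(self):
        if self.kind not in ("circle", "ellipse"):
            raise ValueError("kind must be 'circle' or 'ellipse'")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.n_rings < 4:
            raise ValueError("need at least 4 mesh rings")
        if self.kind == "ellipse" and self.semi_axis_b is None:
            object.__setattr__(self, "semi_axis_b", 0.5 * self.radius)


def make_patch(config: FixtureConfig = FixtureConfig()) -> InletPatch:
    """Structured triangulated disk or ellipse, centroid at the origin.

    Polar construction: ring j of ``n_rings`` holds 6j nodes, giving
    near-equilateral triangles everywhere; the discrete area converges
    to the analytic area as O(n_rings^-2) and is within 0.1% at the
    default density.
    """
    n = config.n_rings
    nodes = [(0.0, 0.0)]
    ring_start = [0, 1]
    for ring in range(1, n + 1):
        m = 6 * ring
        theta = 2.0 * np.pi * np.arange(m) / m
        r = ring / n
        nodes.extend(zip(r * np.cos(theta), r * np.sin(theta)))
        ring_start.append(ring_start[-1] + m)

    faces = []
    # innermost fan
    for k in range(6):
        faces.append([0, 1 + k, 1 + (k + 1) % 6])
    # ring-to-ring strips
    for ring in range(1, n):
        s_in, s_out = ring_start[ring], ring_start[ring + 1]
        m_in, m_out = 6 * ring, 6 * (ring + 1)
        i = j = 0  # node offsets on inner/outer ring
        for _ in range(m_in + m_out):
            a_in = s_in + i % m_in
            a_out = s_out + j % m_out
            # advance whichever ring lags in angle
            if (i + 1) * m_out <= (j + 1) * m_in:
                faces.append([a_in, a_out, s_in + (i + 1) % m_in])
                i += 1
            else:
                faces.append([a_in, a_out, s_out + (j + 1) % m_out])
                j += 1
            if i == m_in and j == m_out:
                break

    xy = np.asarray(nodes, dtype=float) * config.radius
    if config.kind == "ellipse":
        xy[:, 1] *= config.semi_axis_b / config.radius
    return _recenter_and_build(np.asarray(xy), np.asarray(faces, dtype=int))


def make_waveform(
    period: float = 1.0,
    peak_flow_lpm: float = 25.0,
    **kwargs,
) -> FlowWaveform:
    """Synthetic aortic-like waveform (thin wrapper, L/min peak input)."""
    return synthetic_aortic_waveform(
        period=period, peak_flow=peak_flow_lpm / 60000.0, **kwargs
    )


def make_wall_field(
    config: FixtureConfig = FixtureConfig(),
    scale: float = None,
) -> tuple[WallField, WallField, dict]:
    """Toy (reference, case) wall-field pair with recorded statistics.

    Per-facet stress follows ``tau(t) = a_i + b_i sin(w t + phi_i)``
    with ``b_i < a_i`` so magnitudes stay positive; one cardiac cycle is
    sampled on ``n_times`` points.  When ``scale`` is given the case is
    the reference multiplied by that factor (closed-form differences);
    otherwise the case is an independent random field.

    The recorded ``expected`` dict holds the instantaneous integrated
    difference at the first sample and the cycle-averaged difference,
    computed by explicit Python-loop summation and trapezoid rule —
    deliberately independent of the vectorized implementations under
    test.
    """
    rng = np.random.default_rng(config.seed)
    n_f, n_t = config.n_facets, config.n_times
    T = 1.0
    times = np.linspace(0.0, T, n_t)
    areas = rng.uniform(0.5, 1.5, n_f) * 1e-5  # m^2
    stations = rng.uniform(0.0, 3.0, n_f)  # multiples of D

    def random_field():
        a = rng.uniform(1.0, 3.0, n_f)
        b = rng.uniform(0.0, 0.9, n_f) * a
        phi = rng.uniform(0.0, 2.0 * np.pi, n_f)
        return a[None, :] + b[None, :] * np.sin(
            2.0 * np.pi * times[:, None] / T + phi[None, :]
        )

    tau_ref = random_field()
    tau_case = tau_ref * scale if scale is not None else random_field()

    reference = WallField(areas, tau_ref, times, facet_stations=stations)
    case = WallField(areas, tau_case, times, facet_stations=stations)

    # brute-force oracle: explicit loops, no shared code with metrics
    def spatial_sum(tau_row):
        total = 0.0
        for i in range(n_f):
            total += tau_row[i] * areas[i]
        return total

    num0 = spatial_sum(tau_case[0]) - spatial_sum(tau_ref[0])
    den0 = spatial_sum(tau_ref[0])
    wss_inst = abs(100.0 * num0 / den0)

    num_int = den_int = 0.0
    for k in range(n_t - 1):
        h = times[k + 1] - times[k]
        num_k = spatial_sum(tau_case[k]) - spatial_sum(tau_ref[k])
        num_k1 = spatial_sum(tau_case[k + 1]) - spatial_sum(tau_ref[k + 1])
        num_int += 0.5 * h * (num_k + num_k1)
        den_int += 0.5 * h * (spatial_sum(tau_ref[k]) + spatial_sum(tau_ref[k + 1]))
    tawss = abs(100.0 * num_int / den_int)

    expected = {"integrated_wss_diff_t0": wss_inst, "tawss_diff": tawss}
    return reference, case, expected
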
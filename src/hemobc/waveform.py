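"""Periodic volumetric flow waveforms and their truncated Fourier series.

Cardiac flow waveforms are T-periodic; pulsatile boundary-condition
generators (Womersley profiles, Windkessel models) consume the waveform
through its Fourier representation

    Q(t) = a0 + sum_n [ a_n cos(n w t) + b_n sin(n w t) ],   w = 2 pi / T.

Flow rates are carried internally in m^3/s.  Clinical waveforms are
usually reported in L/min; readers convert (1 L/min = 1/60000 m^3/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FlowWaveform",
    "FourierWaveform",
    "fit_fourier",
    "synthetic_aortic_waveform",
    "read_waveform_csv",
    "write_waveform_csv",
    "LPM_TO_M3S",
]

#: 1 L/min expressed in m^3/s.
LPM_TO_M3S = 1.0 / 60000.0

MIN_SAMPLES_PER_PERIOD = 16


@dataclass(frozen=True)
class FlowWaveform:
    """One period of a volumetric flow-rate waveform.

    Parameters
    ----------
    times
        Sample times in seconds, strictly increasing, all within
        ``[0, period)``.  Uniform spacing is not required.
    flows
        Volumetric flow rate at each sample time, m^3/s.
    period
        Waveform period T in seconds.
    """

    times: np.ndarray
    flows: np.ndarray
    period: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        flows = np.asarray(self.flows, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "flows", flows)
        if times.ndim != 1 or flows.shape != times.shape:
            raise ValueError("times and flows must be 1-D arrays of equal length")
        if times.size < MIN_SAMPLES_PER_PERIOD:
            raise ValueError(
                f"need at least {MIN_SAMPLES_PER_PERIOD} samples per period, "
                f"got {times.size}"
            )
        if not np.all(np.diff(times) > 0):
            raise ValueError("sample times must be strictly increasing")
        if not (self.period > 0):
            raise ValueError("period must be positive")
        if times[0] < 0 or times[-1] >= self.period:
            raise ValueError("sample times must lie within [0, period)")
        if not np.all(np.isfinite(flows)):
            raise ValueError("flow samples must be finite")

    @property
    def mean_flow(self) -> float:
        """Periodic trapezoidal time average of the samples, m^3/s."""
        t = np.append(self.times, self.times[0] + self.period)
        q = np.append(self.flows, self.flows[0])
        return float(np.trapezoid(q, t) / self.period)

    @property
    def peak_flow(self) -> float:
        return float(np.max(self.flows))


@dataclass(frozen=True)
class FourierWaveform:
    """Truncated real Fourier series of a periodic flow waveform.

    ``evaluate(t)`` returns
    ``mean_flow + sum_n (a_n cos(n w t) + b_n sin(n w t))`` with
    ``w = fundamental_angular_frequency``; the series is T-periodic and
    real for all t.
    """

    mean_flow: float
    cosine_coeffs: np.ndarray
    sine_coeffs: np.ndarray
    fundamental_angular_frequency: float
    order: int = field(init=False)

    def __post_init__(self) -> None:
        a = np.atleast_1d(np.asarray(self.cosine_coeffs, dtype=float))
        b = np.atleast_1d(np.asarray(self.sine_coeffs, dtype=float))
        if a.shape != b.shape:
            raise ValueError("cosine and sine coefficient arrays must match")
        object.__setattr__(self, "cosine_coeffs", a)
        object.__setattr__(self, "sine_coeffs", b)
        object.__setattr__(self, "order", int(a.size))
        if self.fundamental_angular_frequency <= 0:
            raise ValueError("fundamental angular frequency must be positive")

    @property
    def period(self) -> float:
        return 2.0 * np.pi / self.fundamental_angular_frequency

    def harmonic_amplitudes(self) -> np.ndarray:
        """Complex amplitudes Q_n = a_n - i b_n for harmonics n = 1..N.

        With this convention ``Re{Q_n exp(i n w t)}`` reproduces
        ``a_n cos(n w t) + b_n sin(n w t)``.
        """
        return self.cosine_coeffs - 1j * self.sine_coeffs

    def evaluate(self, t):
        """Flow rate at time(s) ``t`` (seconds), m^3/s."""
        t = np.asarray(t, dtype=float)
        w = self.fundamental_angular_frequency
        n = np.arange(1, self.order + 1)
        phase = np.multiply.outer(t, n) * w  # (..., N)
        out = self.mean_flow + (
            np.cos(phase) @ self.cosine_coeffs + np.sin(phase) @ self.sine_coeffs
        )
        return out if out.ndim else float(out)

    __call__ = evaluate


def fit_fourier(waveform: FlowWaveform, order: int) -> FourierWaveform:
    """Fit a truncated Fourier series to one period of samples.

    The constant term is the periodic trapezoidal time average of the
    samples; harmonic coefficients are the least-squares solution at the
    (possibly non-uniform) sample times.  On a uniform grid this
    coincides with the joint least-squares fit (the constant column is
    orthogonal to every harmonic there), which in turn equals the DFT
    coefficients.

    Raises
    ------
    ValueError
        If ``order`` is negative or exceeds the Nyquist limit of the
        sampling (``2*order + 1 > n_samples``).
    """
    order = int(order)
    if order < 0:
        raise ValueError("order must be non-negative")
    n_samples = waveform.times.size
    if 2 * order + 1 > n_samples:
        raise ValueError(
            f"order {order} exceeds the Nyquist limit of {n_samples} samples "
            f"per period (need n >= 2*order + 1)"
        )
    w = 2.0 * np.pi / waveform.period
    a0 = waveform.mean_flow
    if order == 0:
        return FourierWaveform(a0, np.zeros(0), np.zeros(0), w)
    n = np.arange(1, order + 1)
    phase = np.outer(waveform.times, n) * w
    design = np.hstack([np.cos(phase), np.sin(phase)])
    coef, *_ = np.linalg.lstsq(design, waveform.flows - a0, rcond=None)
    return FourierWaveform(a0, coef[:order], coef[order:], w)


def synthetic_aortic_waveform(
    period: float = 1.0,
    peak_flow: float = 25.0 * LPM_TO_M3S,
    systole_fraction: float = 0.35,
    dip_fraction: float = 0.10,
    n_samples: int = 256,
) -> FlowWaveform:
    """Synthetic aortic-like flow waveform (clearly synthetic, parametric).

    One cardiac cycle with a single smooth systolic ejection peak of
    height ``peak_flow``, a brief post-systolic backflow dip of depth
    ``dip_fraction * peak_flow`` (valve-closure undershoot), and
    near-zero diastolic flow.  Continuous and periodic by construction.

    Defaults emulate a resting adult ascending aorta: 1 s cycle,
    25 L/min peak, systole occupying 35% of the cycle.

    Returns
    -------
    FlowWaveform
        Samples on a uniform grid, with the exact peak instant inserted
        so that ``max(flows) == peak_flow`` holds exactly.
    """
    if not (0.0 < systole_fraction < 1.0):
        raise ValueError("systole_fraction must be in (0, 1)")
    if dip_fraction < 0:
        raise ValueError("dip_fraction must be non-negative")
    t_sys = systole_fraction * period
    t_dip = min(0.5 * t_sys, period - t_sys)  # undershoot width

    def q(t):
        t = np.asarray(t, dtype=float) % period
        out = np.zeros_like(t)
        in_sys = t < t_sys
        out[in_sys] = peak_flow * np.sin(np.pi * t[in_sys] / t_sys) ** 2
        in_dip = (t >= t_sys) & (t < t_sys + t_dip)
        out[in_dip] = (
            -dip_fraction * peak_flow * np.sin(np.pi * (t[in_dip] - t_sys) / t_dip) ** 2
        )
        return out

    times = np.linspace(0.0, period, n_samples, endpoint=False)
    t_peak = 0.5 * t_sys
    if not np.any(np.isclose(times, t_peak, rtol=0, atol=1e-12 * period)):
        times = np.sort(np.append(times, t_peak))
    return FlowWaveform(times, q(times), period)


def read_waveform_csv(path, flow_unit: str = "lpm", period: float | None = None) -> FlowWaveform:
    """Read a two-column ``time_s,flow`` CSV into a :class:`FlowWaveform`.

    ``flow_unit`` is ``"lpm"`` (L/min, converted) or ``"m3s"``.  If
    ``period`` is omitted it is inferred as the wrap-around of the
    sample grid, ``t[-1] + (t[-1] - t[-2])``.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns time_s,flow")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    q = df.iloc[:, 1].to_numpy(dtype=float)
    if flow_unit == "lpm":
        q = q * LPM_TO_M3S
    elif flow_unit != "m3s":
        raise ValueError(f"unknown flow unit {flow_unit!r} (use 'lpm' or 'm3s')")
    if period is None:
        if t.size < 2:
            raise ValueError("cannot infer period from fewer than 2 samples")
        period = float(t[-1] + (t[-1] - t[-2]))
    return FlowWaveform(t, q, period)


def write_waveform_csv(waveform: FlowWaveform, path, flow_unit: str = "m3s") -> None:
    q = waveform.flows
    if flow_unit == "lpm":
        q = q / LPM_TO_M3S
    elif flow_unit != "m3s":
        raise ValueError(f"unknown flow unit {flow_unit!r}")
    pd.DataFrame({"time_s": waveform.times, "flow": q}).to_csv(path, index=False)
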
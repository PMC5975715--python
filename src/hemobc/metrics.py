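"""Flow-field comparison statistics for boundary-condition studies.

Three statistics quantify how much a candidate boundary condition
perturbs the solution relative to a reference case:

* **NRMSD** — root-mean-square deviation of axial velocity magnitude
  over the samples of a cross-sectional slice, normalized by the mean
  reference velocity.  The mean is the plain (unweighted) sample mean.
* **Integrated WSS difference** — the area-weighted surface integral of
  the wall-shear-stress difference at one instant, as a percentage of
  the reference integral:
  ``|100 * sum (tau_case - tau_ref) dA / sum tau_ref dA|``.
* **TAWSS difference** — the same spatial sums additionally integrated
  over one cardiac cycle by the composite trapezoidal rule before the
  ratio is taken.

Spatial integration is the standard facet-value x facet-area summation
for sampled surface data.  Slices and wall fields can be restricted to
a near-inlet region by their streamwise station (in multiples of the
inlet diameter D).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FieldSlice",
    "WallField",
    "nrmsd",
    "integrated_wss_diff",
    "tawss_diff",
    "restrict_to_station",
    "read_slice_csv",
    "write_slice_csv",
    "read_wall_csv",
    "write_wall_csv",
]


@dataclass(frozen=True)
class FieldSlice:
    """Axial-velocity samples on one cross-sectional slice.

    ``station`` is the streamwise coordinate of the slice in multiples
    of the inlet diameter D; ``weights`` are sample areas (m^2), kept
    for surface integrals even though the NRMSD statistic itself uses
    the unweighted sample mean.
    """

    values: np.ndarray  # m/s, axial velocity magnitudes
    weights: np.ndarray  # m^2
    station: float = 0.0
    time_label: Optional[str] = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if v.ndim != 1 or w.shape != v.shape:
            raise ValueError("values and weights must be matching 1-D arrays")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "weights", w)

    @property
    def n_samples(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class WallField:
    """Wall-shear-stress magnitudes sampled per facet over a time grid.

    ``tau`` has shape (n_times, n_facets) in Pa; ``facet_stations``
    (optional) carries per-facet streamwise coordinates in D for
    near-inlet restriction.
    """

    facet_areas: np.ndarray  # m^2
    tau: np.ndarray  # (n_times, n_facets), Pa
    times: np.ndarray  # s
    facet_stations: Optional[np.ndarray] = None

    def __post_init__(self):
        a = np.asarray(self.facet_areas, dtype=float)
        tau = np.atleast_2d(np.asarray(self.tau, dtype=float))
        t = np.atleast_1d(np.asarray(self.times, dtype=float))
        if np.any(a <= 0):
            raise ValueError("facet areas must be positive")
        if tau.shape != (t.size, a.size):
            raise ValueError(
                f"tau must be (n_times={t.size}, n_facets={a.size}), got {tau.shape}"
            )
        if np.any(tau < 0):
            raise ValueError("wall shear stress magnitudes must be non-negative")
        object.__setattr__(self, "facet_areas", a)
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "times", t)
        if self.facet_stations is not None:
            s = np.asarray(self.facet_stations, dtype=float)
            if s.shape != a.shape:
                raise ValueError("facet_stations must match facet_areas")
            object.__setattr__(self, "facet_stations", s)

    @property
    def n_facets(self) -> int:
        return self.facet_areas.size


def _check_matching_slices(reference: FieldSlice, case: FieldSlice):
    if reference.n_samples != case.n_samples:
        raise ValueError(
            f"slices have different sample counts "
            f"({reference.n_samples} vs {case.n_samples})"
        )


def nrmsd(reference: FieldSlice, case: FieldSlice) -> float:
    """Normalized root-mean-square deviation between two slices.

    ``sqrt(mean_i (U_ref,i - U_case,i)^2) / mean_i U_ref,i`` with plain
    sample means over the n slice samples.
    """
    _check_matching_slices(reference, case)
    ref_mean = float(np.mean(reference.values))
    if ref_mean == 0.0:
        raise ZeroDivisionError("reference slice has zero mean velocity")
    rms = np.sqrt(np.mean((reference.values - case.values) ** 2))
    return float(rms / ref_mean)


def _check_matching_walls(case: WallField, reference: WallField, in_time=False):
    if case.n_facets != reference.n_facets:
        raise ValueError(
            f"wall fields have different facet counts "
            f"({case.n_facets} vs {reference.n_facets})"
        )
    if not np.allclose(case.facet_areas, reference.facet_areas, rtol=1e-12):
        raise ValueError("wall fields must share the same facet areas")
    if in_time and (
        case.times.shape != reference.times.shape
        or not np.allclose(case.times, reference.times, rtol=1e-12)
    ):
        raise ValueError("wall fields must share the same time grid")


def integrated_wss_diff(
    case: WallField, reference: WallField, time_index: int = 0
) -> float:
    """Integrated WSS difference at one instant, percent.

    ``|100 * sum_facets (tau_case - tau_ref) dA / sum_facets tau_ref dA|``
    with facet-area-weighted sums.
    """
    _check_matching_walls(case, reference)
    a = reference.facet_areas
    denom = float(reference.tau[time_index] @ a)
    if denom == 0.0:
        raise ZeroDivisionError("reference wall field integrates to zero")
    num = float((case.tau[time_index] - reference.tau[time_index]) @ a)
    return abs(100.0 * num / denom)


def tawss_diff(case: WallField, reference: WallField) -> float:
    """Time-averaged WSS difference over one cardiac cycle, percent.

    The spatial area-weighted sums are integrated over the cycle by the
    composite trapezoidal rule before taking the absolute percent
    ratio.
    """
    _check_matching_walls(case, reference, in_time=True)
    a = reference.facet_areas
    num_t = (case.tau - reference.tau) @ a  # (n_times,)
    den_t = reference.tau @ a
    num = np.trapezoid(num_t, reference.times)
    den = np.trapezoid(den_t, reference.times)
    if den == 0.0:
        raise ZeroDivisionError("reference wall field integrates to zero")
    return abs(100.0 * float(num) / float(den))


def restrict_to_station(field, max_station_in_D: float):
    """Keep only samples/slices with streamwise station <= the cutoff.

    Accepts a :class:`WallField` with per-facet stations, a single
    :class:`FieldSlice`, or a sequence of slices.  Returns the same
    kind of object.
    """
    if isinstance(field, WallField):
        if field.facet_stations is None:
            raise ValueError("wall field has no facet stations to restrict by")
        keep = field.facet_stations <= max_station_in_D
        return WallField(
            facet_areas=field.facet_areas[keep],
            tau=field.tau[:, keep],
            times=field.times,
            facet_stations=field.facet_stations[keep],
        )
    if isinstance(field, FieldSlice):
        return field if field.station <= max_station_in_D else None
    if isinstance(field, Sequence):
        return [s for s in field if s.station <= max_station_in_D]
    raise TypeError(f"cannot restrict object of type {type(field).__name__}")


# -- CSV formats -----------------------------------------------------------


def read_slice_csv(path) -> list[FieldSlice]:
    """Read slices from ``station_D,sample_id,area_m2,value`` CSV."""
    df = pd.read_csv(path)
    slices = []
    for station, grp in df.groupby("station_D", sort=True):
        grp = grp.sort_values("sample_id")
        slices.append(
            FieldSlice(
                values=grp["value"].to_numpy(dtype=float),
                weights=grp["area_m2"].to_numpy(dtype=float),
                station=float(station),
            )
        )
    return slices


def write_slice_csv(slices: Sequence[FieldSlice], path) -> None:
    frames = []
    for s in slices:
        frames.append(
            pd.DataFrame(
                {
                    "station_D": s.station,
                    "sample_id": np.arange(s.n_samples),
                    "area_m2": s.weights,
                    "value": s.values,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def read_wall_csv(path) -> WallField:
    """Read a wall field from ``time_s,facet_id,area_m2,tau_pa[,station_D]``."""
    df = pd.read_csv(path)
    times = np.unique(df["time_s"].to_numpy(dtype=float))
    facets = np.unique(df["facet_id"].to_numpy(dtype=int))
    n_t, n_f = times.size, facets.size
    tau = np.zeros((n_t, n_f))
    ti = {t: i for i, t in enumerate(times)}
    fi = {f: i for i, f in enumerate(facets)}
    rows_t = df["time_s"].map(ti).to_numpy()
    rows_f = df["facet_id"].map(fi).to_numpy()
    tau[rows_t, rows_f] = df["tau_pa"].to_numpy(dtype=float)
    areas = np.zeros(n_f)
    areas[rows_f] = df["area_m2"].to_numpy(dtype=float)
    stations = None
    if "station_D" in df.columns:
        stations = np.zeros(n_f)
        stations[rows_f] = df["station_D"].to_numpy(dtype=float)
    return WallField(facet_areas=areas, tau=tau, times=times, facet_stations=stations)


def write_wall_csv(field: WallField, path) -> None:
    n_t, n_f = field.tau.shape
    data = {
        "time_s": np.repeat(field.times, n_f),
        "facet_id": np.tile(np.arange(n_f), n_t),
        "area_m2": np.tile(field.facet_areas, n_t),
        "tau_pa": field.tau.ravel(),
    }
    if field.facet_stations is not None:
        data["station_D"] = np.tile(field.facet_stations, n_t)
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")
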
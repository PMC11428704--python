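"""Endothelial risk indices from wall shear stress time series.

Given the WSS vector at each wall point over one cardiac cycle T, the
four standard indices are

* TAWSS = (1/T) \\int_0^T |WSS(t)| dt           (time-averaged magnitude, Pa)
* OSI   = 0.5 (1 - |\\int WSS dt| / \\int |WSS| dt)  in [0, 0.5]
* RRT   = 1 / ((1 - 2 OSI) TAWSS)               (relative residence time, 1/Pa)
* ECAP  = OSI / TAWSS                           (activation potential, 1/Pa)

The OSI numerator integrates the WSS *vector* (directional cancellation),
the denominator its magnitude; the two 1/T factors cancel, which is the
standard normalization guaranteeing OSI in [0, 0.5].  RRT diverges as
OSI -> 0.5 or TAWSS -> 0; such points are capped at a configurable
ceiling and flagged rather than propagated as infinities.

Quadrature is the trapezoid rule on the uniform periodic grid (equal to
the sample mean on an open grid), so piecewise-constant reversing series
integrate exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import presets

__all__ = [
    "WSSSeries",
    "IndexMaps",
    "tawss",
    "osi",
    "rrt",
    "ecap",
    "compute_index_maps",
    "wss_snapshots",
    "wss_series_to_csv",
    "wss_series_from_csv",
    "index_maps_to_csv",
]

#: Default RRT cap for degenerate (fully oscillatory or zero-shear) points.
RRT_CEILING = 1e3


@dataclass(frozen=True)
class WSSSeries:
    """Wall-point x time WSS vectors over exactly one period.

    ``vectors`` has shape (n_points, n_times, n_components) in Pa, sampled
    on the uniform open grid t_k = k*period/n_times.  ``arc_length`` gives
    the position of each wall point along its wall polyline, metres.
    """

    arc_length: np.ndarray
    vectors: np.ndarray
    period: float
    positions: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        arc = np.atleast_1d(np.asarray(self.arc_length, dtype=float))
        vec = np.asarray(self.vectors, dtype=float)
        if vec.ndim != 3:
            raise ValueError("vectors must be (n_points, n_times, n_components)")
        if vec.shape[0] != arc.size:
            raise ValueError("arc_length / vectors point counts differ")
        if vec.shape[1] < 2:
            raise ValueError("need at least two time samples")
        if not np.all(np.isfinite(vec)):
            raise ValueError("WSS vectors must be finite")
        if self.period <= 0:
            raise ValueError("period must be positive")
        object.__setattr__(self, "arc_length", arc)
        object.__setattr__(self, "vectors", vec)

    @property
    def n_points(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_times(self) -> int:
        return self.vectors.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_times) * (self.period / self.n_times)

    def magnitudes(self) -> np.ndarray:
        """|WSS| per point per time, shape (n_points, n_times)."""
        return np.linalg.norm(self.vectors, axis=-1)


def _period_mean(values: np.ndarray, axis: int = -1) -> np.ndarray:
    """(1/T)\\int over the period = sample mean on the uniform open grid."""
    return np.mean(values, axis=axis)


def tawss(series: WSSSeries) -> np.ndarray:
    """Time-averaged WSS magnitude per wall point, Pa."""
    return _period_mean(series.magnitudes(), axis=1)


def osi(series: WSSSeries) -> np.ndarray:
    """Oscillatory shear index per wall point, clamped to [0, 0.5].

    Points with zero TAWSS (no shear at any time) are defined as OSI = 0.
    """
    mean_vec = _period_mean(series.vectors, axis=1)
    num = np.linalg.norm(mean_vec, axis=-1)
    den = _period_mean(series.magnitudes(), axis=1)
    out = np.zeros(series.n_points)
    ok = den > 0
    out[ok] = 0.5 * (1.0 - num[ok] / den[ok])
    return np.clip(out, 0.0, 0.5)


def rrt(tawss_map: np.ndarray, osi_map: np.ndarray,
        ceiling: float = RRT_CEILING) -> tuple[np.ndarray, np.ndarray]:
    """Relative residence time 1/((1 - 2 OSI) TAWSS), 1/Pa.

    Returns (rrt, degenerate): where the denominator underflows the
    ceiling (OSI -> 0.5 or TAWSS -> 0) the value is capped at ``ceiling``
    and flagged True in the boolean mask.
    """
    t = np.asarray(tawss_map, dtype=float)
    o = np.asarray(osi_map, dtype=float)
    denom = (1.0 - 2.0 * o) * t
    degenerate = denom <= 1.0 / ceiling
    out = np.full(t.shape, ceiling)
    out[~degenerate] = 1.0 / denom[~degenerate]
    return out, degenerate


def ecap(tawss_map: np.ndarray, osi_map: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Endothelial cell activation potential OSI/TAWSS, 1/Pa.

    Zero-TAWSS points are flagged and reported as 0.
    """
    t = np.asarray(tawss_map, dtype=float)
    o = np.asarray(osi_map, dtype=float)
    degenerate = t <= 0
    out = np.zeros(t.shape)
    out[~degenerate] = o[~degenerate] / t[~degenerate]
    return out, degenerate


@dataclass(frozen=True)
class IndexMaps:
    """Per-wall-point TAWSS/OSI/RRT/ECAP maps with degeneracy flags."""

    arc_length: np.ndarray
    tawss: np.ndarray
    osi: np.ndarray
    rrt: np.ndarray
    ecap: np.ndarray
    rrt_degenerate: np.ndarray
    ecap_degenerate: np.ndarray


def compute_index_maps(series: WSSSeries,
                       rrt_ceiling: float = RRT_CEILING) -> IndexMaps:
    """All four endothelial indices of a WSS series in one pass."""
    t = tawss(series)
    o = osi(series)
    r, r_flag = rrt(t, o, ceiling=rrt_ceiling)
    e, e_flag = ecap(t, o)
    return IndexMaps(arc_length=series.arc_length, tawss=t, osi=o,
                     rrt=r, ecap=e, rrt_degenerate=r_flag,
                     ecap_degenerate=e_flag)


def wss_snapshots(series: WSSSeries,
                  times: Sequence[float] = presets.WSS_SNAPSHOT_TIMES
                  ) -> dict[float, np.ndarray]:
    """|WSS| maps at the requested instants (linear interpolation in time).

    Defaults to the standard report times 0.01, 0.14, 0.35 and 0.59 s of
    the 1 s cycle.  Times must lie within [0, period].
    """
    mags = series.magnitudes()
    grid = np.append(series.times, series.period)
    closed = np.concatenate([mags, mags[:, :1]], axis=1)
    out = {}
    for t in times:
        if not 0.0 <= t <= series.period:
            raise ValueError(f"snapshot time {t} outside [0, {series.period}]")
        k = np.searchsorted(grid, t, side="right") - 1
        k = min(k, len(grid) - 2)
        w = (t - grid[k]) / (grid[k + 1] - grid[k])
        out[float(t)] = (1.0 - w) * closed[:, k] + w * closed[:, k + 1]
    return out


def wss_series_to_csv(series: WSSSeries, path) -> None:
    """Long-format CSV: point_id, arc_length_m, time_s, wss_x, wss_y."""
    npts, nt, nc = series.vectors.shape
    if nc != 2:
        raise ValueError("CSV export supports 2-component WSS vectors")
    pid = np.repeat(np.arange(npts), nt)
    arc = np.repeat(series.arc_length, nt)
    t = np.tile(series.times, npts)
    flat = series.vectors.reshape(npts * nt, 2)
    df = pd.DataFrame({"point_id": pid, "arc_length_m": arc, "time_s": t,
                       "wss_x": flat[:, 0], "wss_y": flat[:, 1]})
    with Path(path).open("w") as fh:
        fh.write(f"# period_s: {float(series.period)!r}\n")
        df.to_csv(fh, index=False)


def wss_series_from_csv(path) -> WSSSeries:
    """Read the long-format CSV written by :func:`wss_series_to_csv`."""
    path = Path(path)
    period = None
    with path.open() as fh:
        first = fh.readline().strip()
        if first.startswith("#") and "period_s:" in first:
            period = float(first.split("period_s:", 1)[1])
    df = pd.read_csv(path, comment="#")
    pids = np.unique(df["point_id"].to_numpy())
    nt = np.count_nonzero(df["point_id"].to_numpy() == pids[0])
    df = df.sort_values(["point_id", "time_s"], kind="stable")
    vec = df[["wss_x", "wss_y"]].to_numpy().reshape(len(pids), nt, 2)
    arc = df["arc_length_m"].to_numpy().reshape(len(pids), nt)[:, 0]
    if period is None:
        tcol = df["time_s"].to_numpy().reshape(len(pids), nt)[0]
        period = float(tcol[-1] + (tcol[-1] - tcol[-2]))
    return WSSSeries(arc_length=arc, vectors=vec, period=period)


def index_maps_to_csv(maps: IndexMaps, path) -> None:
    """Per-point CSV with TAWSS, OSI, RRT, ECAP and degeneracy flags."""
    df = pd.DataFrame({
        "arc_length_m": maps.arc_length,
        "TAWSS": maps.tawss,
        "OSI": maps.osi,
        "RRT": maps.rrt,
        "ECAP": maps.ecap,
        "rrt_degenerate": maps.rrt_degenerate.astype(int),
        "ecap_degenerate": maps.ecap_degenerate.astype(int),
    })
    df.to_csv(path, index=False)
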
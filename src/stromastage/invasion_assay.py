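"""Quantification of cancer invasion into stromal monolayers (ANSIA).

The accelerated nanopatterned stromal invasion assay images a patterned
cancer-fibroblast interface over time; the traced region of interest
(ROI) of the cancer compartment grows as cancer cells invade the stroma.
This module computes the normalized invasion extent

    dArea_t  = Area_t - Area_t0
    <dArea_t> = dArea_t / L_interface,

converts an ROI to a one-dimensional front-advance profile along the
interface, smooths it with a 20-px moving average, calls invasive forks
with the side-window peak rule (a pixel is a peak candidate when the
smoothed profile exceeds the mean over 40 px on each side; consecutive
candidates collapse to the interval midpoint), and compares fork depths
between two conditions with a two-sided Mann-Whitney test.

Coordinates follow the image convention: x runs along the initial
cancer-stroma interface, y increases downward, and invasion advances in
the +y direction beyond the interface line.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.stats
from shapely.geometry import LineString, Polygon


@dataclasses.dataclass
class InvasionSeries:
    """ROI polygons of the cancer compartment over time.

    ``times`` are hours, strictly increasing; ``polygons`` hold one
    (n_vertices, 2) array of pixel coordinates per time point;
    ``interface_length`` is the length in pixels of the initial
    cancer-stroma interface used for normalization.
    """

    times: np.ndarray
    polygons: list[np.ndarray]
    interface_length: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.polygons):
            raise ValueError("one polygon required per time point")
        if len(self.times) and not np.all(np.diff(self.times) > 0):
            raise ValueError("time points must be strictly increasing")
        if not self.interface_length > 0:
            raise ValueError("interface length must be positive")
        self.polygons = [np.asarray(p, dtype=float) for p in self.polygons]
        for t, p in zip(self.times, self.polygons):
            if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 3:
                raise ValueError(f"polygon at t={t} is not an (n>=3, 2) array")


@dataclasses.dataclass
class PeakSet:
    """Called invasive forks: positions along the interface and depths."""

    positions: np.ndarray  # px, strictly increasing
    depths: np.ndarray  # px, >= 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.depths = np.asarray(self.depths, dtype=float)
        if len(self.positions) != len(self.depths):
            raise ValueError("positions and depths differ in length")
        if len(self.positions) > 1 and not np.all(
            np.diff(self.positions) > 0
        ):
            raise ValueError("peak positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.positions)


def polygon_area(vertices: np.ndarray) -> float:
    """Unsigned polygon area (shoelace) in px^2."""
    return Polygon(np.asarray(vertices, dtype=float)).area


def normalized_invasion(series: InvasionSeries) -> pd.DataFrame:
    """Per-time-point invasion extent.

    Returns a table with columns ``time_h``, ``area``, ``delta_area``
    (Area_t - Area_t0) and ``norm_delta_area`` (delta_area divided by the
    initial interface length, i.e. the mean front advance in px).
    """
    areas = np.array([polygon_area(p) for p in series.polygons])
    delta = areas - areas[0]
    return pd.DataFrame(
        {
            "time_h": series.times,
            "area": areas,
            "delta_area": delta,
            "norm_delta_area": delta / series.interface_length,
        }
    )


def roi_to_profile(
    polygon: np.ndarray,
    interface_length: float,
    interface_y: float = 0.0,
    x_origin: float = 0.0,
) -> np.ndarray:
    """Convert an ROI polygon to a 1-D front-advance profile.

    ``advance[x]`` is the maximal extent of the polygon beyond the
    initial interface line (y = ``interface_y``, invasion in +y) at
    integer interface position x; positions the polygon does not cover
    are 0. The profile has ``round(interface_length)`` entries.
    """
    poly = Polygon(np.asarray(polygon, dtype=float))
    if not poly.is_valid:
        raise ValueError("invalid (self-intersecting) ROI polygon")
    miny, maxy = poly.bounds[1] - 1.0, poly.bounds[3] + 1.0
    n = int(round(interface_length))
    advance = np.zeros(n)
    for i in range(n):
        x = x_origin + i
        cut = poly.intersection(LineString([(x, miny), (x, maxy)]))
        if cut.is_empty:
            continue
        ys = [
            c[1]
            for geom in getattr(cut, "geoms", [cut])
            for c in getattr(geom, "coords", [])
        ]
        if ys:
            advance[i] = max(0.0, max(ys) - interface_y)
    return advance


def smooth_profile(profile: np.ndarray, window: int = 20) -> np.ndarray:
    """Centered moving average with truncated windows at the edges.

    The window covers ``window`` pixels (``window//2`` to the left,
    the rest to the right); near the edges the mean is taken over the
    pixels actually available, so the output length equals the input.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(profile, dtype=float)
    n = len(x)
    left = window // 2
    right = window - 1 - left
    csum = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(n)
    lo = np.maximum(idx - left, 0)
    hi = np.minimum(idx + right, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def detect_peaks(smoothed: np.ndarray, side: int = 40,
                 min_prominence: float = 2.0) -> PeakSet:
    """Call invasive forks on a smoothed front profile.

    A pixel qualifies when the smoothed profile exceeds the mean over up
    to ``side`` pixels on its left and, separately, on its right by more
    than ``min_prominence`` (windows truncated at the profile ends; a
    pixel with an empty side cannot qualify). Maximal runs of
    consecutive qualifying pixels collapse to a single fork at the run
    midpoint (floored to an integer pixel); the fork depth is the
    smoothed value there.

    ``min_prominence`` (px) suppresses excursions at the manual-tracing
    jitter scale, far below a cell diameter; ``min_prominence=0``
    recovers the bare larger-than-either-side rule.
    """
    s = np.asarray(smoothed, dtype=float)
    n = len(s)
    if n <= 2 * side:
        raise ValueError(f"profile length {n} must exceed 2*side = {2 * side}")
    csum = np.concatenate([[0.0], np.cumsum(s)])
    idx = np.arange(n)
    llo = np.maximum(idx - side, 0)
    lcnt = idx - llo
    rhi = np.minimum(idx + side, n - 1)
    rcnt = rhi - idx
    with np.errstate(invalid="ignore"):
        lmean = np.where(lcnt > 0, (csum[idx] - csum[llo]) / np.maximum(lcnt, 1),
                         np.inf)
        rmean = np.where(rcnt > 0, (csum[rhi + 1] - csum[idx + 1])
                         / np.maximum(rcnt, 1), np.inf)
    qual = (s > lmean + min_prominence) & (s > rmean + min_prominence)
    positions = []
    depths = []
    i = 0
    while i < n:
        if qual[i]:
            j = i
            while j + 1 < n and qual[j + 1]:
                j += 1
            mid = (i + j) // 2
            positions.append(mid)
            depths.append(s[mid])
            i = j + 1
        else:
            i += 1
    return PeakSet(np.asarray(positions, float), np.asarray(depths, float))


@dataclasses.dataclass
class DepthComparison:
    """Two-group Mann-Whitney comparison of fork depths."""

    u_statistic: float
    p_value: float
    method: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float


def compare_depths(depths_a, depths_b) -> DepthComparison:
    """Two-sided Mann-Whitney U test between two sets of fork depths.

    Exact null distribution for small tie-free samples (both n <= 20);
    normal approximation with tie correction otherwise. Degenerate input
    with zero pooled variance (all depths identical) yields p = 1.
    """
    a = np.asarray(depths_a, dtype=float)
    b = np.asarray(depths_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both depth samples must be nonempty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return DepthComparison(
            u_statistic=len(a) * len(b) / 2.0,
            p_value=1.0,
            method="degenerate",
            n_a=len(a), n_b=len(b),
            median_a=float(np.median(a)), median_b=float(np.median(b)),
        )
    has_ties = len(np.unique(pooled)) < len(pooled)
    if max(len(a), len(b)) <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided",
                                   method=method)
    return DepthComparison(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method=method,
        n_a=len(a), n_b=len(b),
        median_a=float(np.median(a)), median_b=float(np.median(b)),
    )


def quantify_series(
    series: InvasionSeries,
    interface_y: float = 0.0,
    smooth_window: int = 20,
    peak_side: int = 40,
    min_prominence: float = 2.0,
) -> tuple[pd.DataFrame, np.ndarray, PeakSet]:
    """End-to-end quantification of one invasion series.

    Returns the per-time normalized invasion table, the smoothed final
    front profile, and the called forks on that profile.
    """
    table = normalized_invasion(series)
    profile = roi_to_profile(
        series.polygons[-1], series.interface_length, interface_y=interface_y
    )
    smoothed = smooth_profile(profile, window=smooth_window)
    peaks = detect_peaks(smoothed, side=peak_side,
                         min_prominence=min_prominence)
    return table, smoothed, peaks
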
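"""Per-pixel temporal segmentation of annual NBR series.

The change detector runs in three steps: single-year spike removal,
bottom-up merging of adjacent segments under a squared-error criterion,
and extraction of the single largest abrupt NBR loss (year, duration,
magnitude) per pixel.  Stand-replacing disturbance appears as an abrupt
negative step followed by gradual recovery; the detector reports the first
year of the post-drop segment as the change year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SegmentationParams
from .composite import Composite


@dataclass
class ChangeEvent:
    """One pixel's detected change."""

    pixel: tuple[int, int] | None
    change_year: int
    duration_yr: int
    delta_nbr: float
    pre_value: float
    post_value: float
    # Segment window (year indices) used for pre/post means; kept so the
    # same windows can be applied to other spectral indices.
    pre_start: int
    change_index: int
    post_end: int


def despike(values: np.ndarray, spike_tol: float) -> np.ndarray:
    """Replace single-year spikes by the mean of their neighbours.

    A value is a spike when it deviates from its two neighbours' mean by
    more than ``spike_tol`` while the neighbours agree to within
    ``spike_tol`` (a step has disagreeing neighbours and is preserved).
    Idempotent.
    """
    y = np.asarray(values, dtype=float).copy()
    if len(y) < 3:
        return y
    # Iterate the pass to a fixed point: replacing one spike can expose a
    # neighbouring one, and idempotence requires convergence.
    for _ in range(len(y)):
        nbr_mean = 0.5 * (y[:-2] + y[2:])
        is_spike = (np.abs(y[1:-1] - nbr_mean) > spike_tol) & \
                   (np.abs(y[2:] - y[:-2]) < spike_tol)
        if not is_spike.any():
            break
        y[1:-1] = np.where(is_spike, nbr_mean, y[1:-1])
    return y


def _sse(s1, s2, i, j):
    """SSE of the constant fit over half-open segment [i, j)."""
    n = j - i
    tot = s1[j] - s1[i]
    return (s2[j] - s2[i]) - tot * tot / n


def segment_series(values: np.ndarray, params: SegmentationParams) -> list[int]:
    """Bottom-up breakpoint detection on a dense annual series.

    Starts from singleton segments and repeatedly merges the adjacent pair
    whose merge increases the total squared error least (ties: earliest
    pair).  Merging continues while the segment count exceeds
    ``max_segments`` or the cheapest merge costs no more than
    ``mse_improvement_tol`` times the series' total sum of squares.
    Returns interior breakpoints as indices into ``values``, ascending;
    series shorter than 4 return no breakpoints.
    """
    y = np.asarray(values, dtype=float)
    n = len(y)
    if n < 4:
        return []
    s1 = np.concatenate([[0.0], np.cumsum(y)])
    s2 = np.concatenate([[0.0], np.cumsum(y * y)])
    # absolute epsilon guards against roundoff on (near-)constant series
    threshold = params.mse_improvement_tol * _sse(s1, s2, 0, n) + 1e-12

    bounds = list(range(n + 1))  # segment boundaries, singletons to start

    def merge_cost(k):
        # cost of removing interior boundary bounds[k]
        a, b, c = bounds[k - 1], bounds[k], bounds[k + 1]
        return _sse(s1, s2, a, c) - _sse(s1, s2, a, b) - _sse(s1, s2, b, c)

    while len(bounds) > 2:
        costs = [merge_cost(k) for k in range(1, len(bounds) - 1)]
        k_min = int(np.argmin(costs))  # argmin takes the earliest tie
        n_seg = len(bounds) - 1
        if n_seg <= params.max_segments and costs[k_min] > threshold:
            break
        del bounds[k_min + 1]
    return bounds[1:-1]


def detect_change(values: np.ndarray, params: SegmentationParams,
                  years: np.ndarray | None = None,
                  pixel: tuple[int, int] | None = None) -> ChangeEvent | None:
    """Detect the single largest abrupt NBR loss in one pixel's series.

    Returns ``None`` when no breakpoint steps down by at least
    ``min_delta_nbr``.  Invariant to adding a constant to the series.
    """
    y = despike(np.asarray(values, dtype=float), params.spike_tol)
    n = len(y)
    if years is None:
        years = np.arange(n)
    bps = segment_series(y, params)
    if not bps:
        return None
    bounds = [0] + bps + [n]
    best = None
    for k in range(1, len(bounds) - 1):
        a, b, c = bounds[k - 1], bounds[k], bounds[k + 1]
        pre = float(np.mean(y[a:b]))
        post = float(np.mean(y[b:c]))
        delta = pre - post
        if delta >= params.min_delta_nbr and (best is None or delta > best[0]):
            best = (delta, a, b, c, pre, post)
    if best is None:
        return None
    delta, a, b, c, pre, post = best
    # Duration: years from onset to the post-disturbance minimum of the
    # fitted (piecewise-constant) trajectory.  Using segment means rather
    # than raw values keeps the duration stable under observation noise,
    # so pixels of one disturbance patch agree on it.
    post_bounds = [x for x in bounds if x >= b]
    seg_means = [float(np.mean(y[post_bounds[k]:post_bounds[k + 1]]))
                 for k in range(len(post_bounds) - 1)]
    min_seg_start = post_bounds[int(np.argmin(seg_means))]
    return ChangeEvent(
        pixel=pixel,
        change_year=int(years[b]),
        duration_yr=int(min_seg_start - b + 1),
        delta_nbr=float(delta),
        pre_value=pre,
        post_value=post,
        pre_start=a,
        change_index=b,
        post_end=c,
    )


@dataclass
class DetectionMap:
    """Per-pixel detection rasters; ``change_year == 0`` means no change."""

    change_year: np.ndarray  # int32 (row, col), 0 = none
    duration_yr: np.ndarray
    delta_nbr: np.ndarray
    pre_nbr: np.ndarray
    post_nbr: np.ndarray
    pre_start: np.ndarray  # segment windows (year indices)
    change_index: np.ndarray
    post_end: np.ndarray
    years: np.ndarray


def detect_stack(composite: Composite, params: SegmentationParams,
                 usable: np.ndarray | None = None) -> DetectionMap:
    """Run change detection on every usable burnable pixel of a composite.

    Pixels whose NBR range is below ``min_delta_nbr`` cannot contain a
    detectable event (the drop is bounded by the range) and are skipped.
    """
    nbr = composite.values["nbr"]
    n_years, n_rows, n_cols = nbr.shape
    if usable is None:
        usable = composite.burnable
    dm = DetectionMap(
        change_year=np.zeros((n_rows, n_cols), dtype=np.int32),
        duration_yr=np.zeros((n_rows, n_cols), dtype=np.int32),
        delta_nbr=np.zeros((n_rows, n_cols), dtype=np.float32),
        pre_nbr=np.zeros((n_rows, n_cols), dtype=np.float32),
        post_nbr=np.zeros((n_rows, n_cols), dtype=np.float32),
        pre_start=np.zeros((n_rows, n_cols), dtype=np.int32),
        change_index=np.zeros((n_rows, n_cols), dtype=np.int32),
        post_end=np.zeros((n_rows, n_cols), dtype=np.int32),
        years=composite.years,
    )
    # Range screen: the detectable drop is bounded by the series range, so
    # pixels with range below the threshold cannot hold an event.  Usable
    # pixels are gap-filled (no NaNs); others are masked to 0 first.
    safe = np.where(usable[None, :, :], nbr, 0.0)
    rng_screen = (safe.max(axis=0) - safe.min(axis=0)
                  >= params.min_delta_nbr)
    candidates = np.argwhere(usable & rng_screen)
    for r, c in candidates:
        ev = detect_change(nbr[:, r, c], params, years=composite.years,
                           pixel=(r, c))
        if ev is None:
            continue
        dm.change_year[r, c] = ev.change_year
        dm.duration_yr[r, c] = ev.duration_yr
        dm.delta_nbr[r, c] = ev.delta_nbr
        dm.pre_nbr[r, c] = ev.pre_value
        dm.post_nbr[r, c] = ev.post_value
        dm.pre_start[r, c] = ev.pre_start
        dm.change_index[r, c] = ev.change_index
        dm.post_end[r, c] = ev.post_end
    return dm
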
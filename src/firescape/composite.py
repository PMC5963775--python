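"""Best-available-pixel compositing and gap filling.

Each pixel-year may hold several candidate observations (different
acquisition dates, sensors, cloud proximity).  A scoring function ranks
candidates and the best one becomes that year's composite value; years
with no valid candidate are gap-filled by linear interpolation so every
usable pixel ends up with a dense annual series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import INDICES
from .synth import CandidateStack

#: Default weights of the (DOY proximity, cloud distance, sensor) score terms.
DEFAULT_WEIGHTS = (0.5, 0.3, 0.2)

#: Fixed preference bonus per sensor tag (higher is preferred).
SENSOR_PREFERENCE = np.array([0.6, 0.8, 1.0])  # TM, ETM+, OLI


@dataclass
class PixelSeries:
    """One pixel's dense annual trajectory after compositing."""

    pixel: tuple[int, int]
    years: np.ndarray
    values: dict[str, np.ndarray]
    infilled: np.ndarray  # bool per year; False = observed


@dataclass
class Composite:
    """Annual composite stacks: values (year, row, col) per index."""

    values: dict[str, np.ndarray]
    observed: np.ndarray  # bool (year, row, col)
    years: np.ndarray
    burnable: np.ndarray
    pixel_size_m: float


def score_candidate(doy, cloud_distance, sensor, valid, target_doy,
                    weights=DEFAULT_WEIGHTS):
    """Score candidate observations; invalid candidates score ``-inf``.

    The score is a weighted sum of day-of-year proximity to ``target_doy``
    (1 at the target, falling linearly to 0 at 365 days away), cloud
    distance (already normalised to [0, 1]), and a fixed per-sensor
    preference bonus.
    """
    w_doy, w_cloud, w_sensor = weights
    doy_term = 1.0 - np.abs(np.asarray(doy, dtype=float) - target_doy) / 365.0
    score = (w_doy * doy_term
             + w_cloud * np.asarray(cloud_distance, dtype=float)
             + w_sensor * SENSOR_PREFERENCE[np.asarray(sensor)])
    return np.where(np.asarray(valid, dtype=bool), score, -np.inf)


def build_bap(stack: CandidateStack, target_doy: int = 213,
              weights=DEFAULT_WEIGHTS) -> Composite:
    """Reduce candidates to one best-available value per pixel-year.

    Ties in score are broken by earliest day-of-year, then sensor tag
    order.  Pixel-years with no valid candidate are NaN with
    ``observed=False``.
    """
    score = score_candidate(stack.doy, stack.cloud_distance, stack.sensor,
                            stack.valid, target_doy, weights)
    # lexsort: last key is primary -> sort by (-score, doy, sensor).
    order = np.lexsort((stack.sensor, stack.doy, -score), axis=1)
    best = order.take(0, axis=1)  # (year, row, col) candidate index
    any_valid = stack.valid.any(axis=1)
    values = {}
    idx = np.ogrid[:best.shape[0], :best.shape[1], :best.shape[2]]
    for ix in INDICES:
        v = stack.values[ix][idx[0], best, idx[1], idx[2]]
        v = np.where(any_valid, v, np.nan).astype(np.float32)
        values[ix] = v
    return Composite(values=values, observed=any_valid, years=stack.years,
                     burnable=stack.burnable, pixel_size_m=stack.pixel_size_m)


def fill_gaps_series(values: np.ndarray, observed: np.ndarray):
    """Fill one series' gaps: linear interior interpolation, nearest at ends.

    Returns ``(filled, infilled_flags)``.  Requires >= 2 observed years.
    """
    values = np.asarray(values, dtype=float)
    observed = np.asarray(observed, dtype=bool)
    if observed.sum() < 2:
        raise ValueError("fewer than 2 observed years")
    x = np.arange(len(values))
    filled = np.interp(x, x[observed], values[observed])
    filled[observed] = values[observed]
    return filled, ~observed


def fill_gaps(composite: Composite):
    """Gap-fill all burnable pixels of a composite, per index.

    Pixels with fewer than 2 observed years are flagged unusable and left
    NaN.  Returns ``(filled: Composite, unusable: bool (row, col))``; the
    returned composite's ``observed`` mask is unchanged (it doubles as the
    source flag: observed vs infilled).
    """
    obs = composite.observed
    n_obs = obs.sum(axis=0)
    usable = composite.burnable & (n_obs >= 2)
    unusable = composite.burnable & ~ (n_obs >= 2)
    filled = {ix: composite.values[ix].copy() for ix in INDICES}
    gap_pixels = np.argwhere(usable & (~obs).any(axis=0))
    x = np.arange(len(composite.years))
    for r, c in gap_pixels:
        m = obs[:, r, c]
        for ix in INDICES:
            col = filled[ix][:, r, c]
            interp = np.interp(x, x[m], col[m].astype(float))
            interp[m] = col[m]
            filled[ix][:, r, c] = interp
    out = Composite(values=filled, observed=obs, years=composite.years,
                    burnable=composite.burnable,
                    pixel_size_m=composite.pixel_size_m)
    return out, unusable


def pixel_series(composite: Composite, r: int, c: int) -> PixelSeries:
    """Extract one pixel's series from a gap-filled composite."""
    return PixelSeries(
        pixel=(r, c),
        years=composite.years,
        values={ix: composite.values[ix][:, r, c].astype(float)
                for ix in INDICES},
        infilled=~composite.observed[:, r, c],
    )
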
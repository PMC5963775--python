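"""Synthetic multi-year disturbance landscapes with known truth.

The generator stands in for a satellite image archive: it renders, for every
burnable pixel and year, a set of candidate spectral observations (NBR and
tasseled-cap brightness/greenness/wetness) around a known disturbance
history, with observation noise, cloud gaps, and gradual post-disturbance
recovery.  The truth ledger records every injected event so downstream
stages can be scored against it.

Disturbance processes
---------------------
fire
    Annual per-zone target burned-pixel count drawn Binomial(n_eligible, p);
    patches grown from random ignitions by stochastic 8-neighbour spread
    until the target is met (the last patch is truncated), which makes the
    marginal pixel process exactly i.i.d. Bernoulli(p) when re-burn
    exclusion is disabled.  NBR drops by a draw from N(dnbr_fire_mean,
    dnbr_fire_sd) and recovers exponentially:
    ``NBR(t) = baseline - drop * 2**(-(t - t_event)/halflife)``.
harvest
    Compact rectangles with a near-total NBR drop, a brightness *increase*
    (exposed soil), and recovery twice as fast as fire.
road
    1-2 pixel wide linear features with a permanent drop.
condition
    Diffuse low-magnitude drops (|dNBR| < 0.15) with slow recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CLASS_ORDER, INDICES, LandscapeConfig, subseed

# Baseline index levels of undisturbed forest.
BASELINES = {"nbr": 0.55, "tcb": 0.30, "tcg": 0.25, "tcw": 0.05}

_SPREAD_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
                   (0, 1), (1, -1), (1, 0), (1, 1)]

# Acquisition window: August 1st (DOY 213) +/- 40 days.
DOY_WINDOW = (173, 253)


@dataclass
class DisturbanceEvent:
    event_id: int
    cls: str
    year: int
    pixels: np.ndarray  # (n, 2) row/col
    dnbr_mean: float

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)


@dataclass
class TruthLedger:
    """Ground truth of the simulation: every event and its pixel set."""

    events: list[DisturbanceEvent]
    shape: tuple[int, int]
    years: np.ndarray
    burnable: np.ndarray = field(default=None)  # type: ignore
    last_disturbance_year: np.ndarray = field(default=None)  # type: ignore

    def class_mask_stack(self, cls: str) -> np.ndarray:
        """Boolean (year, row, col) stack of pixels disturbed by ``cls``."""
        out = np.zeros((len(self.years), *self.shape), dtype=bool)
        y0 = int(self.years[0])
        for ev in self.events:
            if ev.cls == cls:
                out[ev.year - y0, ev.pixels[:, 0], ev.pixels[:, 1]] = True
        return out

    def fire_mask_stack(self) -> np.ndarray:
        return self.class_mask_stack("fire")

    def any_disturbance_stack(self) -> np.ndarray:
        out = np.zeros((len(self.years), *self.shape), dtype=bool)
        y0 = int(self.years[0])
        for ev in self.events:
            out[ev.year - y0, ev.pixels[:, 0], ev.pixels[:, 1]] = True
        return out

    def event_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "event_id": [ev.event_id for ev in self.events],
                "class": [ev.cls for ev in self.events],
                "year": [ev.year for ev in self.events],
                "n_pixels": [ev.n_pixels for ev in self.events],
                "dnbr_mean": [ev.dnbr_mean for ev in self.events],
            }
        )


@dataclass
class CandidateStack:
    """Per pixel-year candidate observations, shape (year, cand, row, col)."""

    values: dict[str, np.ndarray]
    doy: np.ndarray
    cloud_distance: np.ndarray
    sensor: np.ndarray
    valid: np.ndarray
    years: np.ndarray
    burnable: np.ndarray
    pixel_size_m: float


def _grow_patch(rng, ignition, eligible, spread_prob, cap):
    """Grow one fire patch from an ignition by stochastic 8-neighbour spread.

    ``eligible`` is consumed in place.  Returns an (n, 2) pixel array with
    n <= cap.
    """
    n_rows, n_cols = eligible.shape
    patch = [ignition]
    eligible[ignition] = False
    frontier = [ignition]
    while frontier and len(patch) < cap:
        new_frontier = []
        for (r, c) in frontier:
            for dr, dc in _SPREAD_OFFSETS:
                rr, cc = r + dr, c + dc
                if 0 <= rr < n_rows and 0 <= cc < n_cols and eligible[rr, cc]:
                    if rng.random() < spread_prob:
                        eligible[rr, cc] = False
                        patch.append((rr, cc))
                        new_frontier.append((rr, cc))
                        if len(patch) >= cap:
                            break
            if len(patch) >= cap:
                break
        frontier = new_frontier
    return np.array(patch, dtype=np.int64)


def _rect_pixels(rng, eligible):
    """A random compact rectangle (3-8 x 3-8) of eligible pixels."""
    n_rows, n_cols = eligible.shape
    for _ in range(50):
        h = int(rng.integers(3, 9))
        w = int(rng.integers(3, 9))
        if n_rows < h or n_cols < w:
            continue
        r0 = int(rng.integers(0, n_rows - h + 1))
        c0 = int(rng.integers(0, n_cols - w + 1))
        block = eligible[r0:r0 + h, c0:c0 + w]
        if block.mean() > 0.8:
            rr, cc = np.nonzero(block)
            return np.column_stack([rr + r0, cc + c0])
    return None


def _line_pixels(rng, eligible):
    """A random 1-2 pixel wide linear feature of eligible pixels."""
    n_rows, n_cols = eligible.shape
    for _ in range(50):
        width = int(rng.integers(1, 3))
        length = int(rng.integers(10, 31))
        horizontal = bool(rng.integers(0, 2))
        h, w = (width, length) if horizontal else (length, width)
        if n_rows < h or n_cols < w:
            continue
        r0 = int(rng.integers(0, n_rows - h + 1))
        c0 = int(rng.integers(0, n_cols - w + 1))
        block = eligible[r0:r0 + h, c0:c0 + w]
        if block.mean() > 0.8:
            rr, cc = np.nonzero(block)
            return np.column_stack([rr + r0, cc + c0])
    return None


def _blob_pixels(rng, eligible):
    """A diffuse roughly circular blob of eligible pixels."""
    n_rows, n_cols = eligible.shape
    for _ in range(50):
        rad = int(rng.integers(2, 6))
        r0 = int(rng.integers(rad, max(rad + 1, n_rows - rad)))
        c0 = int(rng.integers(rad, max(rad + 1, n_cols - rad)))
        rr, cc = np.mgrid[-rad:rad + 1, -rad:rad + 1]
        disk = rr**2 + cc**2 <= rad**2
        rows = (rr[disk] + r0).clip(0, n_rows - 1)
        cols = (cc[disk] + c0).clip(0, n_cols - 1)
        keep = rng.random(len(rows)) < 0.8
        px = np.unique(np.column_stack([rows[keep], cols[keep]]), axis=0)
        ok = eligible[px[:, 0], px[:, 1]]
        if ok.mean() > 0.7 and ok.sum() >= 4:
            return px[ok]
    return None


def _forced_drops(cls, n_pixels, dnbr, config):
    """Deterministic per-pixel drops for a forced event of known magnitude."""
    dn = np.full(n_pixels, float(dnbr))
    h = config.recovery_halflife_yr
    tcb = {"fire": 0.04, "harvest": -0.15, "road": -0.10, "condition": 0.02}[cls]
    tcg = {"fire": 0.5, "harvest": 0.5, "road": 0.4, "condition": 0.3}[cls]
    tcw = {"fire": 0.35, "harvest": 0.3, "road": 0.2, "condition": 0.2}[cls]
    hl = {"fire": h, "harvest": h / 2.0, "road": 1e6, "condition": 2.0 * h}[cls]
    return ({"nbr": dn, "tcb": np.full(n_pixels, tcb),
             "tcg": tcg * dn, "tcw": tcw * dn}, hl)


def _event_drops(rng, cls, n_pixels, config):
    """Per-pixel index drops (positive = value decreases) for one event."""
    h = config.recovery_halflife_yr
    if cls == "fire":
        dnbr = rng.normal(config.dnbr_fire_mean, config.dnbr_fire_sd, n_pixels)
        dnbr = np.clip(dnbr, 0.15, 0.9)
        drops = {"nbr": dnbr, "tcb": 0.04 + 0.0 * dnbr,
                 "tcg": 0.5 * dnbr, "tcw": 0.35 * dnbr}
        halflife = h
    elif cls == "harvest":
        dnbr = np.clip(rng.normal(0.45, 0.05, n_pixels), 0.2, 0.9)
        drops = {"nbr": dnbr, "tcb": -0.15 + 0.0 * dnbr,
                 "tcg": 0.5 * dnbr, "tcw": 0.3 * dnbr}
        halflife = h / 2.0
    elif cls == "road":
        dnbr = np.clip(rng.normal(0.30, 0.03, n_pixels), 0.15, 0.6)
        drops = {"nbr": dnbr, "tcb": -0.10 + 0.0 * dnbr,
                 "tcg": 0.4 * dnbr, "tcw": 0.2 * dnbr}
        halflife = 1e6  # effectively permanent
    elif cls == "condition":
        dnbr = rng.uniform(0.08, 0.14, n_pixels)
        drops = {"nbr": dnbr, "tcb": 0.02 + 0.0 * dnbr,
                 "tcg": 0.3 * dnbr, "tcw": 0.2 * dnbr}
        halflife = 2.0 * h
    else:  # pragma: no cover
        raise ValueError(cls)
    return drops, halflife


def simulate_landscape(config: LandscapeConfig, render: bool = True):
    """Simulate a disturbance landscape and (optionally) its observations.

    Returns ``(observations, truth)``; ``observations`` is ``None`` when
    ``render=False`` (truth-only mode, used for fast regime-parameter
    studies).  Identical config and seed give bit-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    # Separate stream for observation rendering so the truth process is
    # identical whether or not observations are rendered.
    rng_obs = np.random.default_rng(subseed(config.seed, 1))
    n_rows, n_cols = config.n_rows, config.n_cols
    years = config.years
    n_years = config.n_years
    zone_map = config.make_zone_map()

    burnable = rng.random((n_rows, n_cols)) < config.burnable_mask_fraction
    for zi, name in enumerate(config.zone_names):
        if config.zone_burn_prob[zi] > 0 and not np.any(burnable & (zone_map == zi)):
            raise ValueError(
                f"zone {name!r} has annual_burn_prob > 0 but zero burnable pixels"
            )

    # Per-pixel disturbance state.
    drop = {ix: np.zeros((n_rows, n_cols)) for ix in INDICES}
    halflife = np.full((n_rows, n_cols), np.inf)
    last_year = np.full((n_rows, n_cols), -(10**6), dtype=np.int64)
    min_gap = config.reburn_min_recovery_halflives

    events: list[DisturbanceEvent] = []
    truth = TruthLedger(events=events, shape=(n_rows, n_cols), years=years,
                        burnable=burnable)

    forced_by_year: dict[int, list] = {}
    for fe in config.forced_events:
        forced_by_year.setdefault(fe.year, []).append(fe)

    if render:
        shape = (n_years, config.n_candidates_per_year, n_rows, n_cols)
        obs_values = {ix: np.full(shape, np.nan, dtype=np.float32) for ix in INDICES}
        obs_doy = np.zeros(shape, dtype=np.int16)
        obs_cloud = np.zeros(shape, dtype=np.float32)
        obs_sensor = np.zeros(shape, dtype=np.int8)
        obs_valid = np.zeros(shape, dtype=bool)

    def register(cls, year, pixels, drops, hl):
        nonlocal events
        if len(pixels) < config.min_event_pixels:
            return
        for ix in INDICES:
            drop[ix][pixels[:, 0], pixels[:, 1]] = drops[ix]
        halflife[pixels[:, 0], pixels[:, 1]] = hl
        last_year[pixels[:, 0], pixels[:, 1]] = year
        events.append(
            DisturbanceEvent(
                event_id=len(events), cls=cls, year=int(year),
                pixels=pixels, dnbr_mean=float(np.mean(drops["nbr"])),
            )
        )

    for yi, year in enumerate(years):
        # Recovery: decay drops from earlier events (-1/inf -> 2**0 == 1).
        decay = 2.0 ** (-1.0 / halflife)
        for ix in INDICES:
            drop[ix] *= decay

        # Never-disturbed pixels are always eligible; disturbed ones only
        # after min_gap half-lives of recovery.
        required_gap = np.zeros((n_rows, n_cols))
        disturbed_before = last_year > -(10**5)
        required_gap[disturbed_before] = min_gap * halflife[disturbed_before]
        eligible = burnable & ((year - last_year) >= required_gap)
        disturbed_this_year = np.zeros((n_rows, n_cols), dtype=bool)

        # Forced events first (deterministic scenarios, bypass eligibility).
        for fe in forced_by_year.get(int(year), []):
            px = np.array(fe.pixels, dtype=np.int64)
            drops, hl = _forced_drops(fe.cls, len(px), fe.dnbr, config)
            register(fe.cls, year, px, drops, hl)
            disturbed_this_year[px[:, 0], px[:, 1]] = True

        # Fires, zone by zone.  The annual target burned-pixel count is
        # Binomial(n_burnable, p) -- p is defined per *burnable* pixel, so
        # the realised burn rate stays p even when recovery exclusions
        # shrink the currently eligible pool.
        for zi in range(len(config.zone_names)):
            p = config.zone_burn_prob[zi]
            if p <= 0:
                continue
            zone_elig = eligible & (zone_map == zi) & ~disturbed_this_year
            if not zone_elig.any():
                continue
            n_zone_burnable = int((burnable & (zone_map == zi)).sum())
            target = int(rng.binomial(n_zone_burnable, p))
            avail = np.ascontiguousarray(zone_elig)
            flat = avail.ravel()
            ignition_queue = rng.permutation(np.flatnonzero(flat))
            ptr = 0
            while target > 0 and ptr < len(ignition_queue):
                j = int(ignition_queue[ptr])
                ptr += 1
                if not flat[j]:  # consumed by an earlier patch
                    continue
                patch = _grow_patch(rng, divmod(j, n_cols), avail,
                                    config.spread_prob, target)
                target -= len(patch)
                drops, hl = _event_drops(rng, "fire", len(patch), config)
                register("fire", year, patch, drops, hl)
                disturbed_this_year[patch[:, 0], patch[:, 1]] = True

        # Non-fire events.
        base_elig = eligible & ~disturbed_this_year
        for cls, count, maker in (("harvest", config.n_harvest, _rect_pixels),
                                  ("road", config.n_road, _line_pixels),
                                  ("condition", config.n_condition, _blob_pixels)):
            for _ in range(count):
                px = maker(rng, base_elig & ~disturbed_this_year)
                if px is None:
                    continue
                drops, hl = _event_drops(rng, cls, len(px), config)
                register(cls, year, px, drops, hl)
                disturbed_this_year[px[:, 0], px[:, 1]] = True

        if render:
            nc = config.n_candidates_per_year
            true_vals = {
                ix: np.clip(BASELINES[ix] - drop[ix], -1.0, 1.0)
                if ix == "nbr" else BASELINES[ix] - drop[ix]
                for ix in INDICES
            }
            obs_doy[yi] = rng_obs.integers(DOY_WINDOW[0], DOY_WINDOW[1] + 1,
                                       size=(nc, n_rows, n_cols), dtype=np.int16)
            obs_cloud[yi] = rng_obs.random((nc, n_rows, n_cols), dtype=np.float32)
            obs_sensor[yi] = rng_obs.integers(0, 3, size=(nc, n_rows, n_cols),
                                          dtype=np.int8)
            valid = rng_obs.random((nc, n_rows, n_cols)) >= config.gap_prob
            valid &= burnable[None, :, :]
            obs_valid[yi] = valid
            for ix in INDICES:
                noise = rng_obs.normal(0.0, config.nbr_noise_sd, (nc, n_rows, n_cols))
                vals = (true_vals[ix][None, :, :] + noise).astype(np.float32)
                if ix == "nbr":
                    vals = np.clip(vals, -1.0, 1.0)
                vals[~valid] = np.nan
                obs_values[ix][yi] = vals

    truth.last_disturbance_year = np.where(last_year > -(10**5), last_year, -1)

    observations = None
    if render:
        observations = CandidateStack(
            values=obs_values, doy=obs_doy, cloud_distance=obs_cloud,
            sensor=obs_sensor, valid=obs_valid, years=years,
            burnable=burnable, pixel_size_m=config.pixel_size_m,
        )
    return observations, truth


def truth_regime_summary(truth: TruthLedger, config: LandscapeConfig) -> pd.DataFrame:
    """Per zone-year truth burned area table (truth-side regime twin).

    Columns: zone, year, burned_ha, burnable_ha, n_patches.
    """
    zone_map = config.make_zone_map()
    burnable = truth.burnable
    area = config.pixel_area_ha
    rows = []
    burnable_by_zone = {
        zi: float((burnable & (zone_map == zi)).sum()) * area
        for zi in range(len(config.zone_names))
    }
    burned = {
        (zi, int(y)): 0.0
        for zi in range(len(config.zone_names)) for y in truth.years
    }
    patches = {k: 0 for k in burned}
    for ev in truth.events:
        if ev.cls != "fire":
            continue
        zones, counts = np.unique(zone_map[ev.pixels[:, 0], ev.pixels[:, 1]],
                                  return_counts=True)
        for zi, n in zip(zones, counts):
            burned[(int(zi), ev.year)] += float(n) * area
        patches[(int(zones[np.argmax(counts)]), ev.year)] += 1
    for zi, name in enumerate(config.zone_names):
        for y in truth.years:
            rows.append({
                "zone": name, "year": int(y),
                "burned_ha": burned[(zi, int(y))],
                "burnable_ha": burnable_by_zone[zi],
                "n_patches": patches[(zi, int(y))],
            })
    return pd.DataFrame(rows)
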
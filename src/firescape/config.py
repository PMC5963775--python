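"""Configuration dataclasses for the simulation and analysis pipeline.

All spatial quantities follow one convention: 0-based row/col indices, grid
origin at the upper-left, pixel-is-area, areas in hectares.  A 30 m pixel
covers 0.09 ha.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Attribution classes in fixed tie-break order.
CLASS_ORDER = ("fire", "harvest", "road", "condition")

#: Spectral indices rendered by the simulator and tracked downstream.
INDICES = ("nbr", "tcb", "tcg", "tcw")


@dataclass
class ForcedEvent:
    """A deterministic disturbance injected into the simulation.

    Used to construct controlled test scenarios (e.g. a single noiseless
    fire of known magnitude at a known year).
    """

    cls: str
    year: int
    pixels: tuple[tuple[int, int], ...]
    dnbr: float

    def __post_init__(self) -> None:
        if self.cls not in CLASS_ORDER:
            raise ValueError(f"unknown event class {self.cls!r}")
        self.pixels = tuple((int(r), int(c)) for r, c in self.pixels)


@dataclass
class LandscapeConfig:
    """Parameters of the synthetic multi-year landscape.

    The grid is partitioned into vertical bands, one per entry of
    ``zone_names`` (left to right), unless an explicit ``zone_map`` is
    supplied.  ``zone_burn_prob`` gives each zone's annual per-pixel burn
    probability p; the expected annual burned area of a zone is
    ``n_burnable * p * pixel_area_ha`` and the implied fire return
    interval is 1/p years.
    """

    n_rows: int = 150
    n_cols: int = 150
    pixel_size_m: float = 30.0
    year_start: int = 1984
    year_end: int = 2015
    zone_names: tuple[str, ...] = ("west", "east")
    zone_burn_prob: tuple[float, ...] = (1.0 / 150.0, 1.0 / 300.0)
    zone_map: np.ndarray | None = None
    burnable_mask_fraction: float = 0.9
    spread_prob: float = 0.35
    n_harvest: int = 3
    n_road: int = 1
    n_condition: int = 4
    nbr_forest_mean: float = 0.55
    nbr_noise_sd: float = 0.02
    dnbr_fire_mean: float = 0.40
    dnbr_fire_sd: float = 0.08
    recovery_halflife_yr: float = 8.0
    reburn_min_recovery_halflives: float = 2.0
    gap_prob: float = 0.15
    n_candidates_per_year: int = 3
    min_event_pixels: int = 1
    forced_events: tuple[ForcedEvent, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one pixel")
        if self.year_end < self.year_start:
            raise ValueError("year_end must be >= year_start")
        if len(self.zone_names) != len(self.zone_burn_prob):
            raise ValueError("zone_names and zone_burn_prob lengths differ")
        if len(self.zone_names) < 1:
            raise ValueError("at least one zone is required")
        for p in self.zone_burn_prob:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"annual_burn_prob {p} outside [0, 1]")
        for p in (self.burnable_mask_fraction, self.spread_prob, self.gap_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.n_candidates_per_year < 1:
            raise ValueError("need at least one candidate per year")
        if self.zone_map is not None:
            zm = np.asarray(self.zone_map)
            if zm.shape != (self.n_rows, self.n_cols):
                raise ValueError("zone_map shape does not match grid")
            if zm.min() < 0 or zm.max() >= len(self.zone_names):
                raise ValueError("zone_map labels outside zone range")
            self.zone_map = zm.astype(np.int32)
        self.forced_events = tuple(
            fe if isinstance(fe, ForcedEvent) else ForcedEvent(**fe)
            for fe in self.forced_events
        )

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    @property
    def n_years(self) -> int:
        return self.year_end - self.year_start + 1

    @property
    def pixel_area_ha(self) -> float:
        return self.pixel_size_m**2 / 10_000.0

    def make_zone_map(self) -> np.ndarray:
        """Zone label raster: supplied map, or equal vertical bands."""
        if self.zone_map is not None:
            return self.zone_map
        edges = np.linspace(0, self.n_cols, len(self.zone_names) + 1)
        cols = np.arange(self.n_cols)
        labels = np.searchsorted(edges[1:-1], cols, side="right")
        return np.broadcast_to(labels, (self.n_rows, self.n_cols)).astype(np.int32)


@dataclass
class SegmentationParams:
    """Knobs of the bottom-up breakpoint detector.

    ``mse_improvement_tol`` is expressed relative to the series' total sum
    of squares: merging continues while the cheapest merge adds less than
    ``mse_improvement_tol * n * var(y)`` to the residual SSE.
    """

    max_segments: int = 6
    mse_improvement_tol: float = 0.15
    min_delta_nbr: float = 0.1
    spike_tol: float = 0.1

    def __post_init__(self) -> None:
        if self.max_segments < 2:
            raise ValueError("max_segments must be >= 2")
        for v in (self.mse_improvement_tol, self.min_delta_nbr, self.spike_tol):
            if v <= 0:
                raise ValueError("thresholds must be positive")


@dataclass
class RunConfig:
    """Full pipeline configuration; round-trips losslessly through YAML/JSON."""

    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    target_doy: int = 213  # August 1st
    score_weights: tuple[float, float, float] = (0.5, 0.3, 0.2)
    min_object_pixels: int = 1
    n_eval_per_class: int = 25
    spatial_bins: int = 9
    rf_trees: int = 500
    alpha: float = 0.05
    large_patch_threshold_ha: float = 200.0
    cell_km: float = 50.0
    epoch_yr: int = 5
    analysis_start_year: int = 1985
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.landscape, dict):
            self.landscape = LandscapeConfig(**self.landscape)
        if isinstance(self.segmentation, dict):
            self.segmentation = SegmentationParams(**self.segmentation)
        self.score_weights = tuple(float(w) for w in self.score_weights)
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["landscape"]["zone_map"] is not None:
            d["landscape"]["zone_map"] = np.asarray(
                d["landscape"]["zone_map"]
            ).tolist()
        d["landscape"]["forced_events"] = [
            {"cls": fe.cls, "year": fe.year,
             "pixels": [list(p) for p in fe.pixels], "dnbr": fe.dnbr}
            for fe in self.landscape.forced_events
        ]
        return _plainify(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        land = dict(d.get("landscape", {}))
        if land.get("zone_map") is not None:
            land["zone_map"] = np.asarray(land["zone_map"], dtype=np.int32)
        for key in ("zone_names", "zone_burn_prob"):
            if key in land:
                land[key] = tuple(land[key])
        if "forced_events" in land:
            land["forced_events"] = tuple(
                ForcedEvent(cls=fe["cls"], year=fe["year"],
                            pixels=tuple(tuple(p) for p in fe["pixels"]),
                            dnbr=fe["dnbr"])
                for fe in land["forced_events"]
            )
        d["landscape"] = LandscapeConfig(**land)
        d["segmentation"] = SegmentationParams(**d.get("segmentation", {}))
        return cls(**d)


def _plainify(obj):
    """Recursively convert numpy scalars/tuples to JSON/YAML-native types."""
    if isinstance(obj, dict):
        return {k: _plainify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plainify(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def subseed(seed: int, offset: int) -> int:
    """Derive a stream-specific seed below 2**31 from a master seed."""
    return (int(seed) * 2654435761 + int(offset)) % (2**31 - 1)
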
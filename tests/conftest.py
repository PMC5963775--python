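"""Shared fixtures: small simulated landscapes run through the chain."""

from __future__ import annotations

import numpy as np
import pytest

from firescape.composite import build_bap, fill_gaps
from firescape.config import LandscapeConfig, SegmentationParams
from firescape.detect import detect_stack
from firescape.objects import build_objects
from firescape.attribute import match_truth
from firescape.synth import simulate_landscape


@pytest.fixture(scope="session")
def bench_chain():
    """Default-condition landscape run through detection and objects.

    150 x 150 pixels, two zones (burn probabilities 1/150 and 1/300),
    harvest/road/condition events at default rates, 1984-2015.
    """
    config = LandscapeConfig(seed=1)
    obs, truth = simulate_landscape(config)
    comp = build_bap(obs)
    filled, unusable = fill_gaps(comp)
    detection = detect_stack(filled, SegmentationParams(),
                             usable=filled.burnable & ~unusable)
    objects = build_objects(detection, filled)
    truth_labels = match_truth(objects, truth)
    return {
        "config": config, "obs": obs, "truth": truth,
        "composite": filled, "unusable": unusable,
        "detection": detection, "objects": objects,
        "truth_labels": truth_labels,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
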
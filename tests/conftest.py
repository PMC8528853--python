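"""Shared fixtures: one synthetic session pair reused across test modules."""

import numpy as np
import pytest

from ensemblelat import SimulationConfig, placefields as pf, synth
from ensemblelat.types import DecodingTemplate


def build_templates(place_units, position, tau=0.020, directions=(1, -1)):
    """Direction-specific decoding templates from exploration rate maps."""
    templates = {}
    for d in directions:
        maps = [pf.compute_ratemap(u, position, d) for u in place_units]
        templates[d] = DecodingTemplate(
            unit_ids=np.array([u.unit_id for u in place_units]),
            rates=np.array([m.rate_hz for m in maps]),
            bin_centers=maps[0].bin_centers, direction=d, tau=tau)
    return templates


@pytest.fixture(scope="session")
def explore_session():
    cfg = SimulationConfig(seed=2)
    position, units, truth = synth.generate_exploration(cfg)
    return cfg, position, units, truth


@pytest.fixture(scope="session")
def rest_session():
    cfg = SimulationConfig(seed=2, rest_duration=300.0)
    position, units, lfp_l, lfp_r, truth = synth.generate_rest(cfg)
    return cfg, position, units, lfp_l, lfp_r, truth


@pytest.fixture(scope="session")
def exploration_templates(explore_session):
    _, position, units, _ = explore_session
    place = pf.filter_units(units, position)
    return place, build_templates(place, position)
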
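"""Shared fixtures: small simulated datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial import cKDTree

from prism.simulate import PaintConfig, SimConfig, simulate_confocal_dataset, simulate_localization_dataset


@pytest.fixture(scope="session")
def small_confocal():
    """A compact confocal dataset (fast): 60 synapses on a 128 px field."""
    cfg = SimConfig(image_size=128, n_synapses=60, n_dendrites=10, seed=11)
    image_set, gt = simulate_confocal_dataset(cfg)
    return cfg, image_set, gt


@pytest.fixture(scope="session")
def default_confocal():
    """The default study conditions: 200 synapses, 224 px field."""
    cfg = SimConfig(seed=1)
    image_set, gt = simulate_confocal_dataset(cfg)
    return cfg, image_set, gt


@pytest.fixture(scope="session")
def paint_dataset():
    """A PAINT acquisition: synapse disc + 2 fiducials, smooth drift, 3000 frames."""
    rng = np.random.default_rng(21)
    from prism.simulate import disc_sites

    sites = disc_sites((2000.0, 2000.0), 150.0, 300, rng)
    cfg = PaintConfig(
        n_frames=3000,
        sites_nm=sites,
        fiducials_nm=np.array([[500.0, 500.0], [3500.0, 3500.0]]),
        seed=21,
    )
    locs, gt = simulate_localization_dataset(cfg)
    return cfg, locs, gt


def match_rates(detected_xy_um: np.ndarray, true_xy_um: np.ndarray, radius_um: float = 1.0):
    """Precision/recall of detected vs planted positions at a matching radius."""
    if len(detected_xy_um) == 0:
        return 0.0, 0.0
    d_to_true, _ = cKDTree(true_xy_um).query(detected_xy_um)
    precision = float(np.mean(d_to_true < radius_um))
    d_to_det, _ = cKDTree(detected_xy_um).query(true_xy_um)
    recall = float(np.mean(d_to_det < radius_um))
    return precision, recall
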
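from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from cosolvmap.pmap import (
    compute_max_pmap,
    compute_pmap,
    grid_geometry_for,
    preferable_surface,
)
from cosolvmap.probes import get_probe
from cosolvmap.synthetic import generate_reference_runs


@pytest.fixture()
def rng():
    return np.random.default_rng(20260904)


@pytest.fixture(scope="session")
def vprobe():
    return get_probe("vprobe")


@pytest.fixture(scope="session")
def small_reference():
    """Scaled-down planted-hotspot dataset for unit tests (4 runs, 60 frames)."""
    runs, truth, probe = generate_reference_runs(7, n_runs=4, n_frames=60)
    return runs, truth, probe


@pytest.fixture(scope="session")
def small_surface(small_reference):
    runs, truth, probe = small_reference
    geometry = grid_geometry_for(runs[0], align_point=truth.hotspots[0].center)
    pmaps = []
    mask = None
    for traj in runs:
        pmap = compute_pmap(traj, geometry, probe.resname, mask=mask)
        mask = pmap.mask
        pmaps.append(pmap)
    max_pmap = compute_max_pmap(pmaps)
    return geometry, pmaps, max_pmap, preferable_surface(max_pmap, 0.2)
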
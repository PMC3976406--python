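import numpy as np
import pytest

import restica as r


@pytest.fixture(scope="session")
def grid():
    """Small analysis grid with an ellipsoidal brain mask."""
    return r.default_grid((16, 16, 12))


@pytest.fixture(scope="session")
def study_grid():
    """The grid the group-study tests run on."""
    return r.default_grid((24, 24, 16))


@pytest.fixture(scope="session")
def atlas(grid):
    return r.make_atlas(grid, n_networks=3, fwhm_mm=6.0, seed=11)


@pytest.fixture(scope="session")
def disjoint_atlas():
    """Three hand-placed, spatially disjoint spherical sources (no overlap)."""
    g = r.default_grid((18, 18, 12))
    centers = [(5, 5, 6), (12, 12, 6), (5, 12, 6)]
    maps, cores = [], []
    for c in centers:
        x, y, z = np.ogrid[:18, :18, :12]
        sphere = ((x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2) <= 2.5**2
        sphere &= g.brain_mask
        maps.append(g.from_volume(sphere.astype(float)))
        cores.append(g.from_volume(sphere))
    return r.NetworkAtlas(grid=g, maps=np.stack(maps), core_masks=np.stack(cores))


@pytest.fixture(scope="session")
def group_study(study_grid):
    """One seeded 8-subject study at the default planted-effect pattern."""
    scans, confounds, behavior, truth = r.simulate_group_study(
        n_subjects=8, grid=study_grid, n_networks=5, n_vol=120, seed=2024
    )
    return scans, confounds, behavior, truth


@pytest.fixture(scope="session")
def baseline_component_sets(group_study):
    """Preprocessed + decomposed baseline (T1) scans of the study fixture."""
    scans, confounds, _, _ = group_study
    sets = []
    for scan in scans:
        if scan.timepoint != "T1":
            continue
        clean = r.preprocess_scan(scan, confounds[(scan.subject, scan.condition)])
        seed = r.scan_seed(77, int(scan.subject[-2:]), scan.condition)
        sets.append(r.decompose_scan(clean, k=10, seed=seed))
    return sets
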
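import numpy as np
import pytest
from scipy import ndimage

from lutedr import synthetic


@pytest.fixture(scope="session")
def default_phantom():
    """One noisy phantom at the default stated world (seeded)."""
    spec = synthetic.PhantomSpec(seed=11)
    return spec, synthetic.generate_phantom(spec)


@pytest.fixture(scope="session")
def noiseless_phantom():
    spec = synthetic.PhantomSpec(seed=11, background_suv_sd=0.0)
    return spec, synthetic.generate_phantom(spec)


def random_blob_mask(shape, seed, sigma=2.0, fill=0.2):
    """A connected-ish random mask: thresholded smoothed white noise."""
    rng = np.random.default_rng(seed)
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    mask = field > np.quantile(field, 1.0 - fill)
    if not mask.any():  # pragma: no cover - fill > 0 guarantees voxels
        mask[tuple(s // 2 for s in shape)] = True
    return mask


def brute_force_sphere(mask, spacing, max_radius_mm=25.0, chunk=128):
    """Exhaustive oracle for background-sphere placement.

    For every in-mask voxel, computes the exact minimum Euclidean
    distance from its center to any exterior voxel center (grid boundary
    counts as exterior); returns (center_index, radius) for the first
    (lowest linear index) voxel attaining the maximum distance, with the
    radius capped at max_radius_mm.
    """
    from scipy.spatial.distance import cdist

    mask = np.asarray(mask, dtype=bool)
    sp = np.asarray(spacing, dtype=float)
    padded = np.pad(mask, 1, constant_values=False)
    out_pos = (np.argwhere(~padded) - 1) * sp
    in_idx = np.argwhere(mask)
    in_pos = in_idx * sp
    best_d = -np.inf
    best_i = None
    for start in range(0, len(in_idx), chunk):
        pos = in_pos[start:start + chunk]
        dmin = cdist(pos, out_pos).min(axis=1)
        for off, d in enumerate(dmin):
            if d > best_d:  # strict: ties keep the lowest linear index
                best_d = d
                best_i = tuple(in_idx[start + off])
    return best_i, min(max_radius_mm, best_d)
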
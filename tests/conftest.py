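import math

import numpy as np
import pytest
from hypothesis import settings

from copemorph.morphometrics import ParticleMask
from copemorph.shapes import Antenna, ShapeSpec

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def exhaustive_feret(mask: ParticleMask) -> tuple[float, float]:
    """Independent feret oracle: exact polygon diameter and width.

    feret_max is the maximum pairwise distance between pixel-corner points;
    feret_min is the minimum, over convex-hull edges, of the largest
    distance from the edge's supporting line to any hull point.
    """
    from scipy.spatial import ConvexHull, QhullError

    rr, cc = np.nonzero(mask.pixels)
    pts = np.concatenate(
        [np.stack([rr + dr, cc + dc], axis=1) for dr in (0, 1) for dc in (0, 1)]
    ).astype(float)
    pts = np.unique(pts, axis=0)
    diff = pts[:, None, :] - pts[None, :, :]
    fmax = math.sqrt((diff**2).sum(axis=2).max())
    try:
        hull_pts = pts[ConvexHull(pts).vertices]
    except QhullError:
        hull_pts = pts
    widths = []
    m = len(hull_pts)
    for i in range(m):
        p, q = hull_pts[i], hull_pts[(i + 1) % m]
        edge = q - p
        norm = np.linalg.norm(edge)
        if norm == 0:
            continue
        normal = np.array([-edge[1], edge[0]]) / norm
        widths.append(np.abs((hull_pts - p) @ normal).max())
    fmin = min(widths) if widths else 0.0
    return fmax * mask.pixel_size, fmin * mask.pixel_size


@pytest.fixture
def plain_spec():
    """Antenna-free calanoid silhouette: L=400, W=100 um at 1 um/px."""
    return ShapeSpec("calanoid_copepodite", 400.0, 100.0, pixel_size=1.0)


@pytest.fixture
def antenna_spec():
    """Antenna-bias fixture: long thin antennae sweeping forward of the prosome."""
    ants = (Antenna(240.0, 5.0, 35.0), Antenna(240.0, 5.0, -35.0))
    return ShapeSpec(
        "calanoid_copepodite", 400.0, 100.0, antennae=ants, pixel_size=1.0, seed=2
    )


@pytest.fixture
def disk_mask_factory():
    """Rasterized disk of a given diameter (um) and pixel size."""

    def make(diameter_um: float, pixel_size: float = 1.0) -> ParticleMask:
        from skimage.draw import disk

        r_px = diameter_um / (2.0 * pixel_size)
        n = int(math.ceil(2 * r_px)) + 6
        grid = np.zeros((n, n), dtype=bool)
        rr, cc = disk((n / 2.0, n / 2.0), r_px, shape=grid.shape)
        grid[rr, cc] = True
        return ParticleMask(grid, pixel_size)

    return make


@pytest.fixture
def random_blob_factory():
    """Small random connected masks for feret-oracle comparisons."""

    def make(seed: int, size: int = 20) -> ParticleMask:
        from scipy.ndimage import gaussian_filter
        from skimage.measure import label

        rng = np.random.default_rng(seed)
        field = gaussian_filter(rng.normal(size=(size, size)), sigma=2.0)
        mask = field > np.quantile(field, 0.75)
        labels = label(mask, connectivity=2)
        if labels.max() == 0:  # degenerate draw: fall back to one pixel
            mask = np.zeros((size, size), bool)
            mask[size // 2, size // 2] = True
            return ParticleMask(mask, 1.0)
        largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
        return ParticleMask(labels == largest, 1.0)

    return make
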
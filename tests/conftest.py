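from __future__ import annotations

import numpy as np
import pytest

from dwiradiomics import ClassSpec, make_cohort


def random_connected_mask(rng: np.random.Generator, shape=(8, 8), n_pixels=20) -> np.ndarray:
    """Grow a random 8-connected mask pixel by pixel (always connected)."""
    nr, nc = shape
    n_pixels = min(n_pixels, nr * nc)
    mask = np.zeros(shape, dtype=bool)
    r, c = rng.integers(0, nr), rng.integers(0, nc)
    mask[r, c] = True
    frontier = {(r, c)}
    while mask.sum() < n_pixels:
        candidates = set()
        for (r, c) in frontier:
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < nr and 0 <= cc < nc and not mask[rr, cc]:
                        candidates.add((rr, cc))
        pick = sorted(candidates)[rng.integers(0, len(candidates))]
        mask[pick] = True
        frontier.add(pick)
    return mask


def random_blob_mask(rng: np.random.Generator, shape=(8, 8)) -> np.ndarray:
    """A small rasterized ellipse for geometry tests (fat, simply connected)."""
    nr, nc = shape
    cy = rng.uniform(nr / 2 - 0.5, nr / 2 + 0.5)
    cx = rng.uniform(nc / 2 - 0.5, nc / 2 + 0.5)
    a = rng.uniform(2.2, nr / 2 - 0.4)
    b = rng.uniform(2.2, nc / 2 - 0.4)
    yy, xx = np.mgrid[0:nr, 0:nc]
    return ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny two-class cohort with a strong texture contrast, reused across tests."""
    specs = (
        ClassSpec("smooth", corr_length=3.6),
        ClassSpec("rough", corr_length=1.2),
    )
    return make_cohort(specs, (6, 6), seed=42, image_shape=(40, 40))
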
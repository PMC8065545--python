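from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from radpipe import DiscretizedVoi, ImageVolume


@pytest.fixture
def rng():
    return np.random.default_rng(20210326)


def make_voi(levels: np.ndarray, mask: np.ndarray | None = None,
             n_bins: int | None = None,
             spacing=(1.0, 1.0, 1.0)) -> DiscretizedVoi:
    """Build a DiscretizedVoi from an integer level grid (0 = outside)."""
    levels = np.asarray(levels, dtype=np.int64)
    if levels.ndim < 3:
        levels = levels.reshape(levels.shape + (1,) * (3 - levels.ndim))
    if mask is None:
        mask = levels > 0
    if n_bins is None:
        n_bins = max(int(levels.max()), 1)
    return DiscretizedVoi(levels=levels, mask=np.asarray(mask, dtype=bool),
                          n_bins=n_bins, spacing_mm=spacing)


def random_voi(rng: np.random.Generator, max_side: int = 6,
               max_levels: int = 4) -> DiscretizedVoi:
    """Random small VOI: random mask (nonempty) and levels in 1..max_levels."""
    shape = tuple(rng.integers(2, max_side + 1, size=3))
    mask = rng.random(shape) < 0.7
    if not mask.any():
        mask.flat[0] = True
    levels = np.zeros(shape, dtype=np.int64)
    levels[mask] = rng.integers(1, max_levels + 1, size=int(mask.sum()))
    return make_voi(levels, mask, n_bins=max_levels)


def ball_mask(radius_vox: int, pad: int = 2) -> np.ndarray:
    n = 2 * (radius_vox + pad) + 1
    c = n // 2
    x, y, z = np.ogrid[:n, :n, :n]
    return (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= radius_vox ** 2


def volume(data, spacing=(1.0, 1.0, 1.0)) -> ImageVolume:
    return ImageVolume(np.asarray(data, dtype=float), spacing)
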
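import numpy as np
import pytest

from mpadbn import ImageTile, generate_tiles


@pytest.fixture(scope="session")
def small_tiles():
    """30 synthetic 32x32 tiles, 6 per class."""
    return generate_tiles(6, size=32, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def blobs_5class():
    """Linearly separable 5-class 2-D blobs, 100 per class, standardized."""
    from sklearn.datasets import make_blobs

    X, y = make_blobs(n_samples=500, centers=5, n_features=2,
                      cluster_std=0.5, random_state=0)
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    return X, y


def brute_force_clahe_lut(pixels, clip_limit, n_bins=256):
    """Independent clipped-histogram/CDF oracle for one block.

    Plain-Python arithmetic on the pixel list: build the histogram, clip
    each bin at clip_limit * n_pixels / n_bins, spread the total excess
    evenly over all bins, accumulate the CDF and scale to [0, 255].
    """
    pixels = [int(p) for p in np.asarray(pixels).ravel()]
    n = len(pixels)
    hist = [0.0] * n_bins
    for p in pixels:
        hist[(p * n_bins) // 256] += 1
    clip = clip_limit * n / n_bins
    excess = sum(max(h - clip, 0.0) for h in hist)
    hist = [min(h, clip) + excess / n_bins for h in hist]
    lut, cum = [], 0.0
    for h in hist:
        cum += h
        lut.append(round(cum / n * 255.0))
    return lut
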
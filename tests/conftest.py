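import numpy as np
import pytest

from atlasfusion.image_model import ImageGrid, ProbSegVolume, ScalarVolume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_grid():
    return ImageGrid((12, 12, 12), (1.0, 1.0, 1.0))


def make_volume(grid, values, fov=None, modality="T2"):
    return ScalarVolume(grid, np.asarray(values, dtype=np.float64), fov, modality)


def random_volume(grid, rng, fov=None, loc=50.0, scale=10.0, modality="T2"):
    return make_volume(grid, rng.normal(loc, scale, grid.shape), fov, modality)


def random_simplex_seg(grid, rng, n_labels):
    p = rng.random(grid.shape + (n_labels,)) + 1e-3
    p /= p.sum(axis=-1, keepdims=True)
    return ProbSegVolume(grid, p.astype(np.float32))


def gaussian_kernel_3d(sigma):
    """The truncated separable kernel the implementation's smoother uses."""
    r = int(3.0 * sigma + 0.5)
    k = np.exp(-0.5 * (np.arange(-r, r + 1) / sigma) ** 2)
    k /= k.sum()
    return k[:, None, None] * k[None, :, None] * k[None, None, :], r


def brute_gaussian_conv(arr, sigma):
    """Direct zero-padded windowed convolution; oracle for gaussian_smooth."""
    K, r = gaussian_kernel_3d(sigma)
    ap = np.pad(np.asarray(arr, dtype=np.float64), r)
    out = np.empty(arr.shape)
    for i in range(arr.shape[0]):
        for j in range(arr.shape[1]):
            for k in range(arr.shape[2]):
                out[i, j, k] = (ap[i : i + 2 * r + 1, j : j + 2 * r + 1, k : k + 2 * r + 1] * K).sum()
    return out
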
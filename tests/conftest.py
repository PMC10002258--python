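import math

import numpy as np
import pytest
from scipy import ndimage


def render_disks(shape, disks, amp=200.0, blur=0.0, noise=0.0, bg=0.0, seed=0, amps=None):
    """Additive anti-aliased disk renderer for detector fixtures.

    ``disks`` is a list of (row, col, radius); intensities add where disks
    overlap, as fluorescence does in projection.
    """
    img = np.zeros(shape, float)
    for i, (r0, c0, r) in enumerate(disks):
        rr = np.arange(shape[0])[:, None]
        cc = np.arange(shape[1])[None, :]
        d = np.hypot(rr - r0, cc - c0)
        a = amps[i] if amps is not None else amp
        img += a * np.clip(r + 0.5 - d, 0, 1)
    if blur:
        img = ndimage.gaussian_filter(img, blur)
    rng = np.random.default_rng(seed)
    img = img + bg
    if noise:
        img = img + rng.normal(0, noise, shape)
    return np.clip(img, 0, 255)


def rasterize_disk(radius, pad=5, center=None):
    """Binary disk of the given radius (pixels with center distance < r+0.5)."""
    size = int(2 * radius) + 2 * pad + 1
    cy = cx = size // 2 if center is None else None
    if center is not None:
        cy, cx = center
    rr = np.arange(size)[:, None]
    cc = np.arange(size)[None, :]
    return (np.hypot(rr - cy, cc - cx) < radius + 0.5).astype(np.uint8)


def brute_force_otsu(plane):
    """Exhaustive-search Otsu: try all integer thresholds, maximize the
    between-class variance of the {<=t} / {>t} split; lowest tie wins."""
    x = np.asarray(plane, dtype=float).ravel()
    n_levels = 65536 if np.asarray(plane).dtype.itemsize > 1 else 256
    best_t, best_v = 0, -1.0
    for t in range(n_levels - 1):
        hi = x > t
        n1 = hi.sum()
        if n1 == 0 or n1 == x.size:
            continue
        w1 = n1 / x.size
        w0 = 1.0 - w1
        v = w0 * w1 * (x[hi].mean() - x[~hi].mean()) ** 2
        if v > best_v + 1e-12:
            best_t, best_v = t, v
    return best_t


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
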
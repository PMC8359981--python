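"""Shared fixtures: phantoms, voxel fixtures and brute-force oracles."""

import numpy as np
import pytest

from trabkit import (
    ImageStack,
    PhantomSpec,
    extract_graph,
    generate_phantom,
    split_bone,
    thin_volume,
)


# ---------------------------------------------------------------- oracles

def brute_dilate(img: np.ndarray, pattern: np.ndarray) -> np.ndarray:
    """Sliding-window dilation: OR of the image shifted by every active
    structuring-element offset (independent of scipy's implementation)."""
    img = img.astype(bool)
    h, w = img.shape
    ph, pw = pattern.shape
    rh, rw = ph // 2, pw // 2
    out = np.zeros_like(img)
    for a in range(-rh, rh + 1):
        for b in range(-rw, rw + 1):
            if not pattern[a + rh, b + rw]:
                continue
            src = img[
                max(0, -a) : h - max(0, a),
                max(0, -b) : w - max(0, b),
            ]
            out[
                max(0, a) : h - max(0, -a),
                max(0, b) : w - max(0, -b),
            ] |= src
    return out.astype(np.uint8)


def brute_erode(img: np.ndarray, pattern: np.ndarray) -> np.ndarray:
    """Sliding-window erosion with foreground padding (dual of brute_dilate)."""
    return 1 - brute_dilate(1 - img.astype(np.uint8), pattern[::-1, ::-1])


def brute_otsu(data: np.ndarray) -> int:
    """Exhaustive-scan Otsu: the 8-bit threshold maximizing between-class
    variance over all 256 candidates."""
    hist = np.bincount(data.ravel().astype(np.uint8), minlength=256).astype(float)
    total = hist.sum()
    levels = np.arange(256, dtype=float)
    best_t, best_var = 0, -1.0
    for t in range(255):
        w0 = hist[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (levels[: t + 1] * hist[: t + 1]).sum() / w0
        mu1 = (levels[t + 1 :] * hist[t + 1 :]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


# ---------------------------------------------------------------- voxel fixtures

def make_stack(vox: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> ImageStack:
    return ImageStack(vox.astype(np.uint8), spacing=spacing, is_binary=True)


@pytest.fixture
def plus_sign_stack() -> ImageStack:
    """Four 5-voxel arms meeting at one voxel, embedded in one slice."""
    vol = np.zeros((13, 13, 3), dtype=np.uint8)
    c = 6
    vol[c, c, 1] = 1
    for i in range(1, 6):
        vol[c + i, c, 1] = 1
        vol[c - i, c, 1] = 1
        vol[c, c + i, 1] = 1
        vol[c, c - i, 1] = 1
    return make_stack(vol)


@pytest.fixture
def diamond_loop_stack() -> ImageStack:
    """A closed diamond path (|x| + |y| = r): every voxel has exactly two
    neighbors, so the skeleton graph must contain exactly one cycle."""
    r = 6
    vol = np.zeros((2 * r + 3, 2 * r + 3, 3), dtype=np.uint8)
    c = r + 1
    for x in range(-r, r + 1):
        y = r - abs(x)
        vol[c + x, c + y, 1] = 1
        vol[c + x, c - y, 1] = 1
    return make_stack(vol)


@pytest.fixture(scope="session")
def torus_stack() -> ImageStack:
    n = 64
    x, y, z = np.mgrid[0:n, 0:n, 0:n].astype(float)
    c = (n - 1) / 2
    rad = np.sqrt((x - c) ** 2 + (y - c) ** 2)
    torus = ((rad - 20) ** 2 + (z - c) ** 2) <= 5**2
    return make_stack(torus)


# ---------------------------------------------------------------- phantoms

@pytest.fixture(scope="session")
def default_phantom():
    spec = PhantomSpec()
    binary, truth = generate_phantom(spec)
    return spec, binary, truth


@pytest.fixture(scope="session")
def pipeline_graph(default_phantom):
    """Skeleton graph measured by the full clean pipeline on the default
    phantom (split -> thin -> graph)."""
    _, binary, _ = default_phantom
    parts = split_bone(binary)
    return extract_graph(thin_volume(parts.cancellous))
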
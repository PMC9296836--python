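import numpy as np
import pytest

from isac2d import SearchGrid, make_synthetic_stack
from isac2d.polar_align import normalize
from isac2d.stack_io import motif


@pytest.fixture(scope="session")
def grid32():
    return SearchGrid.for_box(32, s_max=2)


@pytest.fixture(scope="session")
def grid24():
    return SearchGrid.for_box(24, s_max=2)


@pytest.fixture(scope="session")
def motif32():
    return normalize(motif(0, 32))


@pytest.fixture(scope="session")
def blob_image():
    """Smooth asymmetric 32x32 test image (sum of off-center Gaussians)."""
    b = 32
    jj, ii = np.meshgrid(np.arange(b), np.arange(b))
    x = jj - b // 2
    y = b // 2 - ii
    img = np.zeros((b, b))
    for bx, by, s, a in [(3, 2, 2.5, 1.0), (-4, 1, 2.0, 0.7), (1, -5, 1.5, 1.2)]:
        img += a * np.exp(-((x - bx) ** 2 + (y - by) ** 2) / (2 * s**2))
    return normalize(img)


@pytest.fixture(scope="session")
def two_motif_stack():
    """Well-separated two-class stack for clustering tests."""
    return make_synthetic_stack(
        2, 50, 32, snr=2.0, max_shift=2, mirror_allowed=True, seed=5
    )


def circular_mask(box: int, radius: float) -> np.ndarray:
    c = box // 2
    jj, ii = np.meshgrid(np.arange(box), np.arange(box))
    return (jj - c) ** 2 + (ii - c) ** 2 <= radius**2


def masked_ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    av = a[mask] - a[mask].mean()
    bv = b[mask] - b[mask].mean()
    return float(av @ bv / np.sqrt((av @ av) * (bv @ bv)))
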
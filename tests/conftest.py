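import numpy as np
import pytest

from pollenstack.geometry import Box


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


def random_box(rng, lo=0, hi=64, integer=True) -> Box:
    """Random valid box with corners inside [lo, hi]."""
    while True:
        if integer:
            vals = rng.integers(lo, hi + 1, size=4)
        else:
            vals = rng.uniform(lo, hi, size=4)
        x0, x1 = sorted((float(vals[0]), float(vals[1])))
        y0, y1 = sorted((float(vals[2]), float(vals[3])))
        if x1 > x0 and y1 > y0:
            return Box(x0, y0, x1, y1)


def pixel_iou(a: Box, b: Box, grid=64) -> float:
    """Independent IoU oracle: rasterize both boxes on a unit grid and
    count covered cells.  Valid for integer-coordinate boxes."""
    ga = np.zeros((grid, grid), dtype=bool)
    gb = np.zeros((grid, grid), dtype=bool)
    ga[int(a.y0): int(a.y1), int(a.x0): int(a.x1)] = True
    gb[int(b.y0): int(b.y1), int(b.x0): int(b.x1)] = True
    inter = np.logical_and(ga, gb).sum()
    union = np.logical_or(ga, gb).sum()
    return inter / union if union else 0.0
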
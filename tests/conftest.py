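import numpy as np
import pytest

from scalesdm.grids import Grid2D, LayerStack
from scalesdm.synthetic import SyntheticTruth, generate_landscape, true_suitability


@pytest.fixture(scope="session")
def default_truth():
    return SyntheticTruth(seed=0)


@pytest.fixture(scope="session")
def landscape(default_truth):
    return generate_landscape(64, 64, 1000.0, default_truth)


@pytest.fixture(scope="session")
def suitability(landscape, default_truth):
    return true_suitability(landscape, default_truth)


@pytest.fixture()
def small_grid():
    """3x3 grid with values 1..9 row-major."""
    return Grid2D(np.arange(1.0, 10.0).reshape(3, 3), cell_size=1000.0, origin=(0.0, 3000.0))


def naive_focal_mean(values, mask, radius):
    """Double-loop enumeration oracle for circular-window focal means."""
    rows, cols = values.shape
    out = np.full((rows, cols), np.nan)
    r_int = int(np.floor(radius))
    for i in range(rows):
        for j in range(cols):
            if mask[i, j]:
                continue
            acc, cnt = 0.0, 0
            for di in range(-r_int, r_int + 1):
                for dj in range(-r_int, r_int + 1):
                    if di * di + dj * dj > radius * radius + 1e-9:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < rows and 0 <= jj < cols and not mask[ii, jj]:
                        acc += values[ii, jj]
                        cnt += 1
            if cnt:
                out[i, j] = acc / cnt
    return out


def naive_focal_fraction(values, mask, code, radius):
    ind = (values == code).astype(float)
    return naive_focal_mean(ind, mask, radius)
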
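import numpy as np
import pytest

from landsig import (
    ActivityVector,
    FingerprintSet,
    SimilarityMatrix,
    TestConfig,
    similarity_matrix,
)


@pytest.fixture
def small_fps() -> FingerprintSet:
    """Four molecules, eight bits, hand-checkable overlaps."""
    bits = np.array([
        [1, 1, 1, 0, 0, 0, 0, 0],
        [0, 1, 1, 1, 0, 0, 0, 0],
        [0, 0, 0, 0, 1, 1, 0, 0],
        [1, 0, 1, 0, 1, 0, 1, 0],
    ])
    return FingerprintSet(["a", "b", "c", "d"], bits, "toy")


@pytest.fixture
def small_acts(small_fps) -> ActivityVector:
    return ActivityVector(small_fps.molecule_ids, np.array([7.0, 5.0, 6.2, 4.1]))


@pytest.fixture
def small_sim(small_fps) -> SimilarityMatrix:
    return similarity_matrix(small_fps)


@pytest.fixture
def fast_cfg() -> TestConfig:
    return TestConfig(n_iterations=50, seed=11)


def naive_sali(acts: np.ndarray, sim: np.ndarray, cap=None):
    """Double-loop SALI oracle: list of (i, j, value-or-None)."""
    m = len(acts)
    out = []
    for i in range(m):
        for j in range(i + 1, m):
            da = abs(acts[i] - acts[j])
            if sim[i, j] >= 1.0:
                if da == 0:
                    out.append((i, j, 0.0))
                elif cap is not None:
                    out.append((i, j, cap))
                else:
                    out.append((i, j, None))
            else:
                out.append((i, j, da / (1.0 - sim[i, j])))
    return out


def brute_ks_statistic(x, y) -> float:
    """Sup of |ECDF_x(t) - ECDF_y(t)| scanned over every sample point."""
    x = np.sort(np.asarray(x, float))
    y = np.sort(np.asarray(y, float))
    best = 0.0
    for t in np.concatenate([x, y]):
        fx = np.searchsorted(x, t, side="right") / len(x)
        fy = np.searchsorted(y, t, side="right") / len(y)
        best = max(best, abs(fx - fy))
    return best
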
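import itertools

import numpy as np
import pytest

from flexcompare.core import (
    FlexibilitySignal,
    RigidityStateEnsemble,
    SignalKind,
    SusceptibilityImage,
)


def brute_force_dtw(a, b):
    """Independent DTW oracle: explicitly enumerate every admissible warping
    path (monotone, continuous, spanning both sequences end to end) and
    return the minimum cumulative squared-difference cost."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = len(a), len(b)
    best = [np.inf]

    def cost(i, j):
        return (a[i] - b[j]) ** 2

    def walk(i, j, acc):
        if acc >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = min(best[0], acc)
            return
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            ni, nj = i + di, j + dj
            if ni < n and nj < m:
                walk(ni, nj, acc + cost(ni, nj))

    walk(0, 0, cost(0, 0))
    return best[0]


def brute_force_susceptibility(realizations):
    """Independent variance oracle: literal two-loop recomputation per pixel."""
    R = len(realizations)
    m = realizations[0].shape[0]
    chi = np.zeros((m, m))
    for j in range(m):
        for k in range(m):
            vals = [float(mat[j, k]) for mat in realizations]
            mean = sum(vals) / R
            mean_sq = sum(v * v for v in vals) / R
            chi[j, k] = mean_sq - mean * mean
    return chi


def random_state_ensemble(rng, m, n_realizations, protein_id="rand"):
    """A random valid ensemble: symmetric {-1,0,+1} matrices with -1 diagonal."""
    mats = []
    for _ in range(n_realizations):
        upper = rng.integers(-1, 2, size=(m, m))
        mat = np.triu(upper, 1)
        mat = mat + mat.T
        np.fill_diagonal(mat, -1)
        mats.append(mat)
    return RigidityStateEnsemble(protein_id=protein_id, realizations=mats)


def signal(values, protein_id="s", kind=SignalKind.OTHER, gap_mask=None):
    return FlexibilitySignal(
        protein_id=protein_id, values=np.asarray(values, float),
        kind=kind, gap_mask=gap_mask,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def smooth_image():
    """A smooth, symmetric, gap-free test image (good for warping tests)."""
    m = 48
    x = np.linspace(0, 1, m)
    chi = 0.25 + 0.2 * np.add.outer(np.sin(3 * x), np.sin(3 * x))
    chi += 0.15 * np.outer(np.cos(5 * x), np.cos(5 * x))
    chi = np.clip(0.5 * (chi + chi.T), 0.0, 1.0)
    return SusceptibilityImage("smooth", chi)
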
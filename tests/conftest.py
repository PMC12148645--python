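"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's own code paths: voxel
traversal is re-derived by clipping each segment against every candidate
voxel cube (Liang-Barsky), BH FDR by literal enumeration of the step-up
definition, and OLS by the normal equations.
"""

from __future__ import annotations

import numpy as np
import pytest

from ufiber import SimDesign, simulate_cohort, simulate_phantom
from ufiber.tractometry import VolumeGrid


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def segment_box_intersects(p0, p1, lo, hi) -> bool:
    """Liang-Barsky: does the open segment (p0, p1) pass inside the box?"""
    p0 = np.asarray(p0, float)
    d = np.asarray(p1, float) - p0
    tmin, tmax = 0.0, 1.0
    for ax in range(3):
        if d[ax] == 0.0:
            if p0[ax] < lo[ax] or p0[ax] > hi[ax]:
                return False
        else:
            t1 = (lo[ax] - p0[ax]) / d[ax]
            t2 = (hi[ax] - p0[ax]) / d[ax]
            if t1 > t2:
                t1, t2 = t2, t1
            tmin = max(tmin, t1)
            tmax = min(tmax, t2)
            if tmin >= tmax:
                return False
    return True


def oracle_streamline_voxels(streamline: np.ndarray, grid: VolumeGrid) -> set:
    """All in-grid voxels intersected by the polyline, by brute-force clip."""
    vox = grid.world_to_voxel(streamline)
    visited = set()
    for i in range(len(vox) - 1):
        p0, p1 = vox[i], vox[i + 1]
        lo = np.floor(np.minimum(p0, p1) + 0.5).astype(int) - 1
        hi = np.floor(np.maximum(p0, p1) + 0.5).astype(int) + 1
        for x in range(lo[0], hi[0] + 1):
            for y in range(lo[1], hi[1] + 1):
                for z in range(lo[2], hi[2] + 1):
                    c = np.array([x, y, z], float)
                    if segment_box_intersects(p0, p1, c - 0.5, c + 0.5):
                        visited.add((x, y, z))
    shape = grid.shape
    return {
        c
        for c in visited
        if 0 <= c[0] < shape[0] and 0 <= c[1] < shape[1] and 0 <= c[2] < shape[2]
    }


def oracle_bh_stepup(pvalues: np.ndarray, alpha: float = 0.05):
    """Literal BH step-up: reject the k smallest p-values where k is the
    largest i with p_(i) <= i*alpha/m; q_i = min over j >= i of m*p_(j)/j."""
    p = np.asarray(pvalues, float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    k = 0
    for i in range(1, m + 1):
        if sorted_p[i - 1] <= i * alpha / m:
            k = i
    reject_sorted = np.arange(1, m + 1) <= k
    q_sorted = np.empty(m)
    running = np.inf
    for i in range(m, 0, -1):
        running = min(running, m * sorted_p[i - 1] / i)
        q_sorted[i - 1] = min(running, 1.0)
    q = np.empty(m)
    reject = np.empty(m, dtype=bool)
    q[order] = q_sorted
    reject[order] = reject_sorted
    return q, reject


def oracle_ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Closed-form normal equations (independent of lstsq-based fits)."""
    return np.linalg.solve(X.T @ X, X.T @ y)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def default_phantom():
    return simulate_phantom(seed=7)


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free cohort: features are an exact linear function of the design."""
    design = SimDesign(
        n_participants=120,
        pathways=("AF", "CST"),
        noise_sd=0.0,
        seed=11,
    )
    cohort, features, echo = simulate_cohort(design)
    return cohort, features, echo


@pytest.fixture(scope="session")
def noisy_cohort():
    design = SimDesign(
        n_participants=616,
        pathways=("AF", "CST", "CC"),
        noise_sd=1.0,
        coupling_assoc=0.6,
        coupling_nonassoc=0.2,
        seed=13,
    )
    cohort, features, echo = simulate_cohort(design)
    return cohort, features, echo
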
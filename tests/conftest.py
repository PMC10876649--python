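"""Shared fixtures and independent oracles for the test suite."""

from itertools import combinations

import numpy as np
import pytest

from tilecyte.datatypes import LINING, SUBLINING, RegionMask
from tilecyte.pipeline import RunConfig, analyse_sample
from tilecyte.synthetic import comparator_config, simulate_sample


# ---------------------------------------------------------------- oracles
def brute_force_voronoi(centroids: np.ndarray, ids: np.ndarray, roi: np.ndarray):
    """Exhaustive per-pixel nearest-centroid scan; ties -> smallest id.

    Independent of the package's KD-tree implementation: plain squared
    distances, argmin in id order.
    """
    labels = np.zeros(roi.shape, dtype=np.int32)
    rows, cols = np.nonzero(roi)
    pts = np.column_stack([rows, cols]).astype(float)
    d2 = ((pts[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    labels[rows, cols] = np.asarray(ids)[np.argmin(d2, axis=1)]
    return labels


def pair_count_u(a, b) -> float:
    """U for sample a by direct pair counting (ties count one half)."""
    u = 0.0
    for x in a:
        for y in b:
            u += 1.0 if x > y else (0.5 if x == y else 0.0)
    return u


def enumeration_two_sided_p(a, b) -> float:
    """Exact two-sided Mann-Whitney p by full enumeration of assignments.

    Enumerates all C(n1+n2, n1) splits of the pooled values, computing U by
    pair counting (not ranks), and accumulates the probability mass of
    splits at least as far from n1*n2/2 as the observed U.
    """
    pooled = list(a) + list(b)
    n1, n = len(a), len(a) + len(b)
    mu = n1 * (n - n1) / 2.0
    obs = abs(pair_count_u(a, b) - mu)
    hits = total = 0
    for chosen in combinations(range(n), n1):
        rest = [pooled[i] for i in range(n) if i not in set(chosen)]
        u = pair_count_u([pooled[i] for i in chosen], rest)
        hits += abs(u - mu) >= obs - 1e-12
        total += 1
    return hits / total


# --------------------------------------------------------------- fixtures
@pytest.fixture(scope="session")
def band_mask():
    """64x64 all-ROI mask: 16-px lining band on top, sub-lining below."""
    labels = np.full((64, 64), SUBLINING, dtype=np.int8)
    labels[:16, :] = LINING
    return RegionMask(labels, pixel_size=0.5)


@pytest.fixture(scope="session")
def small_config():
    """Down-scaled comparator sample config used across unit tests."""
    return comparator_config(
        image_height=128, image_width=128, lining_depth=16, n_nuclei=80, min_spacing=8
    )


@pytest.fixture(scope="session")
def small_sample(small_config):
    return simulate_sample(small_config, seed=42, sample_id="s1", group="comparator")


@pytest.fixture(scope="session")
def small_result(small_sample):
    return analyse_sample(
        small_sample.image,
        small_sample.region_mask,
        RunConfig.from_dict({}),
        sample_id="s1",
        group="comparator",
    )
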
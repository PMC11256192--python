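"""Band-mass features and cluster-validity metrics against brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shapedx import (
    COMBINATION_10,
    COMBINATION_12,
    band_mass,
    build_distribution,
    connectivity_score,
    dunn_index,
    enumerate_combinations,
    feature_point,
    kmeans_two,
    select_combination,
)
from shapedx.distribution import RoundnessDistribution
from shapedx.featurespace import RangeCombination

UNIFORM = build_distribution(np.arange(0.05, 1.0, 0.1))
TOP_HEAVY = build_distribution([0.95] * 10)


def test_band_mass_examples():
    assert band_mass(UNIFORM, 0.2, 0.5) == pytest.approx(0.3)
    assert band_mass(TOP_HEAVY, 0.2, 0.8) == 0.0
    assert band_mass(UNIFORM, 0.0, 1.0) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        band_mass(UNIFORM, 0.25, 0.5)
    with pytest.raises(ValueError):
        band_mass(UNIFORM, 0.5, 0.2)


@given(
    counts=st.lists(st.integers(0, 20), min_size=10, max_size=10).filter(lambda c: sum(c) > 0),
    split=st.integers(1, 9),
)
@settings(derandomize=True, max_examples=50)
def test_band_mass_additive_at_lattice_points(counts, split):
    d = RoundnessDistribution(np.array(counts, float) / sum(counts), sum(counts))
    x = split / 10
    assert band_mass(d, 0, x) + band_mass(d, x, 1) == pytest.approx(band_mass(d, 0, 1))


def test_feature_point_examples():
    pt = feature_point(UNIFORM, COMBINATION_10)
    assert (pt.P1, pt.P2) == (pytest.approx(0.3), pytest.approx(0.3))
    corner = feature_point(TOP_HEAVY, COMBINATION_10)
    assert (corner.P1, corner.P2) == (0.0, 0.0)


def test_enumerate_combinations_lattice():
    width3 = enumerate_combinations(widths=(0.3,))
    assert len(width3) == 5
    spans = {(c.p1_range[0], c.p1_range[1], c.p2_range[1]) for c in width3}
    assert (0.2, 0.5, 0.8) in spans and (0.4, 0.7, 1.0) in spans
    assert len(enumerate_combinations(widths=(0.5,))) == 1
    full = enumerate_combinations()
    assert len(full) == 25  # 9 + 7 + 5 + 3 + 1
    # pinned named combinations
    assert COMBINATION_10.p1_range == (0.2, 0.5) and COMBINATION_10.p2_range == (0.5, 0.8)
    assert COMBINATION_12.p1_range == (0.4, 0.7) and COMBINATION_12.p2_range == (0.7, 1.0)
    with pytest.raises(ValueError):
        RangeCombination((0.2, 0.5), (0.6, 0.9))  # not adjacent


def _best_sse_partition(pts: np.ndarray):
    """Exhaustive minimum-SSE 2-partition (point 0 pinned to side 0)."""
    n = len(pts)
    best, best_labels = np.inf, None
    for bits in range(2 ** (n - 1)):
        labels = np.array([0] + [(bits >> i) & 1 for i in range(n - 1)])
        if labels.min() == labels.max():
            continue
        sse = 0.0
        for side in (0, 1):
            grp = pts[labels == side]
            sse += ((grp - grp.mean(axis=0)) ** 2).sum()
        if sse < best - 1e-12:
            best, best_labels = sse, labels
    return best_labels


def test_kmeans_two_blobs_and_canonical_labels():
    rng = np.random.default_rng(0)
    near = rng.normal(0.05, 0.01, size=(8, 2))
    far = rng.normal(0.6, 0.01, size=(8, 2))
    pts = np.vstack([near, far])
    labels = kmeans_two(pts, seed=1)
    assert set(labels[:8]) == {0} and set(labels[8:]) == {1}
    # invariance to point order after canonical labelling
    perm = rng.permutation(16)
    relabeled = kmeans_two(pts[perm], seed=1)
    np.testing.assert_array_equal(relabeled, labels[perm])
    with pytest.raises(ValueError):
        kmeans_two(np.ones((5, 2)))


def test_kmeans_matches_exhaustive_best_partition():
    rng = np.random.default_rng(3)
    pts = np.vstack(
        [rng.normal(0.1, 0.05, size=(6, 2)), rng.normal(0.5, 0.07, size=(6, 2))]
    )
    labels = kmeans_two(pts, seed=0)
    oracle = _best_sse_partition(pts)
    same = np.array_equal(labels, oracle) or np.array_equal(labels, 1 - oracle)
    assert same


def _connectivity_oracle(pts, labels, L):
    """Direct enumeration with an explicit sorted neighbour list."""
    total = 0.0
    for i in range(len(pts)):
        dists = sorted(
            (float(np.linalg.norm(pts[i] - pts[j])), j)
            for j in range(len(pts))
            if j != i
        )
        for rank, (_, j) in enumerate(dists[:L], start=1):
            if labels[j] != labels[i]:
                total += 1.0 / rank
    return total


def test_connectivity_pure_and_impure_neighbourhoods():
    rng = np.random.default_rng(1)
    blob_a = rng.normal(0.0, 0.01, size=(12, 2))
    blob_b = rng.normal((5.0, 5.0), 0.01, size=(12, 2))
    pts = np.vstack([blob_a, blob_b])
    labels = np.repeat([0, 1], 12)
    assert connectivity_score(pts, labels, L=10) == 0.0
    # splitting one tight cluster in half must score positive
    split = np.array([0, 1] * 12)
    assert connectivity_score(pts, split, L=10) > 0
    with pytest.raises(ValueError):
        connectivity_score(pts[:5], labels[:5], L=10)


def test_connectivity_matches_enumeration_oracle():
    rng = np.random.default_rng(2)
    pts = rng.uniform(0, 1, size=(24, 2))
    labels = rng.integers(0, 2, size=24)
    got = connectivity_score(pts, labels, L=10)
    assert got == pytest.approx(_connectivity_oracle(pts, labels, 10), abs=1e-12)


def _dunn_oracle(pts, labels):
    inter = min(
        float(np.linalg.norm(pts[i] - pts[j]))
        for i, j in itertools.combinations(range(len(pts)), 2)
        if labels[i] != labels[j]
    )
    diams = [
        float(np.linalg.norm(pts[i] - pts[j]))
        for i, j in itertools.combinations(range(len(pts)), 2)
        if labels[i] == labels[j]
    ]
    return inter / max(diams)


def test_dunn_index_fixture_and_properties():
    pts = np.array([[0, 0], [0, 0.1], [1, 1], [1, 1.1]])
    labels = np.array([0, 0, 1, 1])
    val = dunn_index(pts, labels)
    assert val == pytest.approx(13.45, abs=0.01)
    assert val == pytest.approx(_dunn_oracle(pts, labels), rel=1e-12)
    # overlapping identical clusters score below 1
    rng = np.random.default_rng(4)
    cloud = rng.uniform(0, 1, size=(20, 2))
    mixed = rng.integers(0, 2, size=20)
    assert dunn_index(cloud, mixed) < 1
    assert dunn_index(cloud, mixed) == pytest.approx(_dunn_oracle(cloud, mixed), rel=1e-12)
    # scale invariance
    assert dunn_index(cloud * 7.3, mixed) == pytest.approx(dunn_index(cloud, mixed))
    # singleton handling: diameter taken over multi-point clusters only
    pts_s = np.array([[0, 0], [1, 0], [1, 0.2]])
    assert dunn_index(pts_s, np.array([0, 1, 1])) == pytest.approx(1.0 / 0.2, rel=1e-9)
    with pytest.raises(ValueError):
        dunn_index(np.array([[0, 0], [1, 1]]), np.array([0, 1]))


def _law_distribution(rng, mixture, n=200):
    """Distribution sampled straight from per-class roundness laws."""
    from scipy.stats import truncnorm

    vals = []
    for (mean, sd), frac in mixture:
        k = int(round(frac * n))
        a, b = (0 - mean) / sd, (1 - mean) / sd
        vals.extend(truncnorm.rvs(a, b, loc=mean, scale=sd, size=k, random_state=rng))
    return build_distribution(np.clip(vals, 0, 1))


def test_select_combination_ranking_mechanics():
    """Combination ranking on a training cohort built the way the classifier
    is trained: sickled = SCD under slow deoxygenation plus SCT under fast,
    unsickled = healthy under fast."""
    rng = np.random.default_rng(9)
    scd_low = [((0.45, 0.035), 0.34), ((0.56, 0.05), 0.37), ((0.68, 0.05), 0.18), ((0.88, 0.04), 0.11)]
    sct_high = [((0.56, 0.05), 0.60), ((0.45, 0.035), 0.19), ((0.68, 0.05), 0.15), ((0.88, 0.04), 0.06)]
    healthy = [((0.88, 0.04), 1.0)]
    samples = []
    for _ in range(8):
        samples.append((_law_distribution(rng, scd_low), "c_low", True))
    for _ in range(8):
        samples.append((_law_distribution(rng, sct_high), "c_high", True))
    for _ in range(8):
        samples.append((_law_distribution(rng, healthy), "c_high", False))
    table = select_combination(samples, seed=0)
    # full report covers the whole lattice, ranked by (connectivity, -dunn)
    assert len(table) == 25
    assert table.connectivity.is_monotonic_increasing or (
        table.sort_values(["connectivity", "dunn"], ascending=[True, False])
        .reset_index(drop=True)
        .equals(table.drop(columns="rank").assign(rank=table["rank"]))
    )
    # the deployed band pair attains the optimal connectivity score
    row10 = table[(table.p1_lo == 0.2) & (table.p1_hi == 0.5) & (table.p2_hi == 0.8)]
    assert len(row10) == 1
    assert row10.connectivity.iloc[0] == pytest.approx(table.connectivity.min())
    # ranking is deterministic for a fixed seed
    again = select_combination(samples, seed=0)
    assert again.equals(table)
    # single-combination input returns exactly that combination
    only = select_combination(samples, combos=[COMBINATION_10], seed=0)
    assert len(only) == 1 and only.combo_index[0] == 10
    # degenerate identical distributions propagate the k-means error
    same = [(TOP_HEAVY, "c_low", True)] * 24
    with pytest.raises(ValueError):
        select_combination(same, combos=[COMBINATION_10], seed=0)
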
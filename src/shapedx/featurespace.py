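"""Band-mass feature space and cluster-validity ranking of band combinations.

Each image's roundness distribution is reduced to a point (P1, P2): the
distribution mass inside two adjacent, equal-width roundness bands.  The
combination actually used downstream spans roundness 0.2-0.8 (P1 over
0.2-0.5, P2 over 0.5-0.8); candidate combinations are ranked by how cleanly
k-means (k=2) splits the training points, scored by Handl connectivity
(10 nearest neighbours; lower is better) and the Dunn index (higher is
better).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .distribution import RoundnessDistribution

__all__ = [
    "RangeCombination",
    "FeaturePoint",
    "COMBINATION_10",
    "COMBINATION_12",
    "band_mass",
    "feature_point",
    "enumerate_combinations",
    "kmeans_two",
    "connectivity_score",
    "dunn_index",
    "select_combination",
]


def _lattice(x: float) -> int:
    """Roundness bound -> bin-edge index, validating 0.1 alignment."""
    k = round(x * 10)
    if abs(x * 10 - k) > 1e-9 or not (0 <= k <= 10):
        raise ValueError(f"bound {x} is not a multiple of 0.1 in [0, 1]")
    return int(k)


@dataclass(frozen=True)
class RangeCombination:
    p1_range: tuple[float, float]
    p2_range: tuple[float, float]
    index: int = -1

    def __post_init__(self) -> None:
        (a, b), (c, d) = self.p1_range, self.p2_range
        for lo, hi in (self.p1_range, self.p2_range):
            if not (0 <= lo < hi <= 1):
                raise ValueError(f"invalid range ({lo}, {hi})")
        if abs(b - c) > 1e-9:
            raise ValueError("ranges must be adjacent (p1.hi == p2.lo)")
        if abs((b - a) - (d - c)) > 1e-9:
            raise ValueError("ranges must have equal widths")


@dataclass(frozen=True)
class FeaturePoint:
    P1: float
    P2: float
    condition: str = ""
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.P1 < 0 or self.P2 < 0 or self.P1 + self.P2 > 1 + 1e-9:
            raise ValueError("P1, P2 must be non-negative with P1 + P2 <= 1")


# The two band combinations singled out during feature selection; the first
# is the one the deployed classifier uses.
COMBINATION_10 = RangeCombination((0.2, 0.5), (0.5, 0.8), index=10)
COMBINATION_12 = RangeCombination((0.4, 0.7), (0.7, 1.0), index=12)


def band_mass(dist: RoundnessDistribution, lo: float, hi: float) -> float:
    """Distribution mass in the band (lo, hi]; bounds on the 0.1 lattice."""
    i, j = _lattice(lo), _lattice(hi)
    if i >= j:
        raise ValueError("lower bound must be below upper bound")
    return float(dist.heights[i:j].sum())


def feature_point(
    dist: RoundnessDistribution,
    combo: RangeCombination = COMBINATION_10,
    condition: str = "",
    sample_id: str = "",
) -> FeaturePoint:
    return FeaturePoint(
        P1=band_mass(dist, *combo.p1_range),
        P2=band_mass(dist, *combo.p2_range),
        condition=condition,
        sample_id=sample_id,
    )


def enumerate_combinations(
    widths=(0.1, 0.2, 0.3, 0.4, 0.5), start_step: float = 0.1
) -> list[RangeCombination]:
    """All adjacent equal-width band pairs inside [0, 1] on the start lattice.

    Ordered by (width, start).  With the default grid this yields 25
    combinations (9 + 7 + 5 + 3 + 1 over widths 0.1 ... 0.5).
    """
    combos = []
    step = _lattice(start_step)
    for w in widths:
        wk = _lattice(w)
        for s in range(0, 10 - 2 * wk + 1, step):
            combos.append(
                RangeCombination(
                    (s / 10, (s + wk) / 10),
                    ((s + wk) / 10, (s + 2 * wk) / 10),
                    index=len(combos) + 1,
                )
            )
    return combos


def _as_array(points) -> np.ndarray:
    pts = np.asarray(
        [(p.P1, p.P2) if isinstance(p, FeaturePoint) else tuple(p) for p in points],
        dtype=float,
    )
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be 2-D")
    return pts


def kmeans_two(points, seed: int = 0) -> np.ndarray:
    """k-means (k=2, k-means++ init, 50 restarts) with canonical labels.

    Label 0 is the cluster whose centroid is nearer the origin, so the
    labelling does not depend on initialization or point order.
    """
    pts = _as_array(points)
    if len(np.unique(pts, axis=0)) < 2:
        raise ValueError("k-means with k=2 needs at least 2 distinct points")
    km = KMeans(n_clusters=2, n_init=50, random_state=seed).fit(pts)
    labels = km.labels_
    norms = np.linalg.norm(km.cluster_centers_, axis=1)
    if norms[1] < norms[0]:
        labels = 1 - labels
    return labels.astype(int)


def connectivity_score(points, labels, L: int = 10) -> float:
    """Handl connectivity: sum of 1/j over each point's j-th nearest
    neighbours (j = 1..L) that sit in a different cluster.  Zero means every
    point's L-neighbourhood is pure; lower is better."""
    pts = _as_array(points)
    labels = np.asarray(labels)
    n = len(pts)
    if n <= L:
        raise ValueError(f"need more than L={L} points, got {n}")
    score = 0.0
    for i in range(n):
        d = np.linalg.norm(pts - pts[i], axis=1)
        d[i] = np.inf
        order = np.argsort(d, kind="stable")  # ties resolve by index
        for j, nb in enumerate(order[:L], start=1):
            if labels[nb] != labels[i]:
                score += 1.0 / j
    return score


def dunn_index(points, labels) -> float:
    """Min inter-cluster distance over max intra-cluster diameter.

    Single-linkage numerator, complete-diameter denominator.  Singleton
    clusters have zero diameter; the denominator is the maximum over
    clusters with at least two points, and all-singleton input is an error.
    """
    pts = _as_array(points)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least two clusters")
    inter = np.inf
    for a in range(len(uniq)):
        for b in range(a + 1, len(uniq)):
            pa, pb = pts[labels == uniq[a]], pts[labels == uniq[b]]
            d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
            inter = min(inter, d.min())
    diam = 0.0
    any_multi = False
    for u in uniq:
        pu = pts[labels == u]
        if len(pu) >= 2:
            any_multi = True
            d = np.linalg.norm(pu[:, None, :] - pu[None, :, :], axis=-1)
            diam = max(diam, d.max())
    if not any_multi:
        raise ValueError("all clusters are singletons; diameter undefined")
    return inter / diam


def select_combination(
    training_samples, combos: list[RangeCombination] | None = None, seed: int = 0, L: int = 10
) -> pd.DataFrame:
    """Rank band combinations by cluster validity of their k-means split.

    ``training_samples`` is a list of (distribution, condition, truth_label)
    triples; the truth label is carried through for inspection but the
    metrics are computed on the unsupervised k-means partition.  Ranked by
    connectivity ascending, then Dunn index descending.
    """
    combos = combos if combos is not None else enumerate_combinations()
    rows = []
    n_valid = 0
    last_error: Exception | None = None
    for combo in combos:
        pts = [
            feature_point(dist, combo, condition=str(cond))
            for dist, cond, _label in training_samples
        ]
        try:
            labels = kmeans_two(pts, seed=seed)
            conn = connectivity_score(pts, labels, L=L)
            dunn = dunn_index(pts, labels)
            n_valid += 1
        except ValueError as exc:
            # a band pair where every sample has the same mass carries no
            # information; rank it last instead of aborting the scan
            conn, dunn = np.inf, -np.inf
            last_error = exc
        rows.append(
            {
                "combo_index": combo.index,
                "p1_lo": combo.p1_range[0],
                "p1_hi": combo.p1_range[1],
                "p2_lo": combo.p2_range[0],
                "p2_hi": combo.p2_range[1],
                "connectivity": conn,
                "dunn": dunn,
            }
        )
    if n_valid == 0:
        raise ValueError("every candidate combination is degenerate") from last_error
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["connectivity", "dunn"], ascending=[True, False], kind="stable"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table
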
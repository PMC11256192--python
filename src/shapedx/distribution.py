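"""Ten-bin roundness distributions: build, pool, summarize.

Roundness values are binned into ten half-open bins (lower, upper] of width
0.1; a value of exactly 0 falls into the first bin.  Bins are labelled by
their upper edge (0.1 ... 1.0), matching the convention that distribution
peaks are quoted at edge values such as 0.5 or 0.9.  Heights are per-bin
cell fractions, so each distribution integrates to one and band masses are
direct sums of heights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RoundnessDistribution",
    "BIN_EDGES",
    "BIN_LABELS",
    "build_distribution",
    "modal_bin",
    "pool_distributions",
]

BIN_EDGES = np.arange(11) / 10.0  # 0.0, 0.1, ..., 1.0
BIN_LABELS = BIN_EDGES[1:]  # upper-edge labels


@dataclass(frozen=True)
class RoundnessDistribution:
    heights: np.ndarray  # 10 fractions summing to 1
    n_cells: int

    def __post_init__(self) -> None:
        h = np.asarray(self.heights, dtype=float)
        object.__setattr__(self, "heights", h)
        if h.shape != (10,):
            raise ValueError("exactly 10 bins required")
        if np.any(h < 0):
            raise ValueError("heights must be non-negative")
        if self.n_cells > 0 and abs(h.sum() - 1.0) > 1e-9:
            raise ValueError(f"heights sum to {h.sum()}, expected 1")

    @property
    def counts(self) -> np.ndarray:
        return self.heights * self.n_cells


def build_distribution(roundness_values) -> RoundnessDistribution:
    """Histogram of roundness values into 10 half-open (lo, hi] bins."""
    vals = np.asarray(list(roundness_values), dtype=float)
    if vals.size == 0:
        raise ValueError("cannot build a distribution from no cells")
    if np.any(vals < 0) or np.any(vals > 1):
        raise ValueError("roundness values must lie in [0, 1]")
    idx = np.digitize(vals, BIN_EDGES, right=True)  # value == edge -> lower bin
    idx = np.clip(idx, 1, 10)  # exact 0 joins the first bin
    counts = np.bincount(idx - 1, minlength=10).astype(float)
    return RoundnessDistribution(heights=counts / vals.size, n_cells=int(vals.size))


def modal_bin(dist: RoundnessDistribution) -> float:
    """Upper-edge label of the maximal bin; ties break toward the lowest label."""
    return float(BIN_LABELS[int(np.argmax(dist.heights))])


def pool_distributions(dists) -> RoundnessDistribution:
    """Pool by summing counts and renormalizing (e.g., fields of one cohort)."""
    dists = list(dists)
    if not dists:
        raise ValueError("cannot pool an empty list of distributions")
    counts = np.zeros(10)
    n = 0
    for d in dists:
        counts += d.counts
        n += d.n_cells
    if n == 0:
        raise ValueError("pooled distribution has no cells")
    return RoundnessDistribution(heights=counts / n, n_cells=n)


def distribution_table(dist: RoundnessDistribution) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bin_label": BIN_LABELS,
            "height": dist.heights,
            "count": np.rint(dist.counts).astype(int),
        }
    )
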
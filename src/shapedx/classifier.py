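"""Linear boundary in (P1, P2) space and the four-way decision matrix.

A sample contributes two feature points, one per scavenger condition.  Each
point falls on the GRAY (unsickled) or WHITE (sickled) side of a linear
boundary; the pair of regions maps to a call:

    (GRAY,  GRAY)  -> HEALTHY
    (WHITE, WHITE) -> SCD
    (GRAY,  WHITE) -> SCT
    (WHITE, GRAY)  -> INVALID (repeat the experiment)

The deployed boundary is P2 = -1.527 * P1 + 0.633 with GRAY below the line;
points exactly on the line read as WHITE so a borderline sample triggers a
re-test rather than a silent healthy call.  Retraining uses a soft-margin
linear SVM (cost 10) on unscaled features.
"""

from __future__ import annotations

import enum
import importlib.resources
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .featurespace import FeaturePoint

__all__ = [
    "Region",
    "Call",
    "LinearBoundary",
    "Diagnosis",
    "published_boundary",
    "train_linear_svm",
    "region_of",
    "diagnose",
    "load_boundary",
    "save_boundary",
]


class Region(enum.Enum):
    GRAY = "gray"
    WHITE = "white"


class Call(enum.Enum):
    HEALTHY = "healthy"
    SCD = "scd"
    SCT = "sct"
    INVALID = "invalid"


@dataclass(frozen=True)
class LinearBoundary:
    slope: float
    intercept: float
    gray_below: bool = True  # GRAY <=> P2 < slope*P1 + intercept

    def __post_init__(self) -> None:
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise ValueError("slope and intercept must be finite")


@dataclass(frozen=True)
class Diagnosis:
    call: Call
    region_low: Region
    region_high: Region


def published_boundary() -> LinearBoundary:
    """The versioned boundary shipped with the package (slope -1.527,
    intercept 0.633, GRAY below)."""
    ref = importlib.resources.files("shapedx").joinpath("data/published_boundary.txt")
    with importlib.resources.as_file(ref) as path:
        return load_boundary(path)


def load_boundary(path) -> LinearBoundary:
    """Read a plain-text key=value model file."""
    fields: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            fields[key.strip()] = value.strip()
    try:
        return LinearBoundary(
            slope=float(fields["slope"]),
            intercept=float(fields["intercept"]),
            gray_below=fields.get("orientation", "gray_below") == "gray_below",
        )
    except KeyError as exc:
        raise ValueError(f"model file {path} missing field {exc}") from exc


def save_boundary(boundary: LinearBoundary, path, provenance: str = "trained") -> None:
    with open(path, "w") as fh:
        fh.write(f"slope = {float(boundary.slope)!r}\n")
        fh.write(f"intercept = {float(boundary.intercept)!r}\n")
        orient = "gray_below" if boundary.gray_below else "gray_above"
        fh.write(f"orientation = {orient}\n")
        fh.write(f"provenance = {provenance}\n")


def train_linear_svm(points, labels, cost: float = 10.0, tol: float = 1e-6) -> LinearBoundary:
    """Soft-margin linear SVM on raw (unscaled) feature points.

    ``labels`` are truthy for sickled and falsy for unsickled samples; the
    returned orientation puts the unsickled class on the GRAY side.
    """
    pts = np.asarray(
        [(p.P1, p.P2) if isinstance(p, FeaturePoint) else tuple(p) for p in points],
        dtype=float,
    )
    y = np.asarray([1 if bool(l) else 0 for l in labels])
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    svm = SVC(kernel="linear", C=cost, tol=tol).fit(pts, y)
    w = svm.coef_[0]
    b = svm.intercept_[0]
    if abs(w[1]) < 1e-12:
        raise ValueError("degenerate vertical boundary; cannot express as P2 = f(P1)")
    slope = float(-w[0] / w[1])
    intercept = float(-b / w[1])
    # decision w.x + b is positive for label 1 (sickled); GRAY is the
    # unsickled side.  If sickled is above the line, gray is below.
    gray_below = bool(w[1] > 0)
    return LinearBoundary(slope=slope, intercept=intercept, gray_below=gray_below)


def region_of(point: FeaturePoint, boundary: LinearBoundary) -> Region:
    """GRAY iff strictly on the gray side; on-line points read WHITE."""
    line = boundary.slope * point.P1 + boundary.intercept
    below = point.P2 < line
    gray = below if boundary.gray_below else (point.P2 > line)
    return Region.GRAY if gray else Region.WHITE


_DECISION_MATRIX = {
    (Region.GRAY, Region.GRAY): Call.HEALTHY,
    (Region.WHITE, Region.WHITE): Call.SCD,
    (Region.GRAY, Region.WHITE): Call.SCT,
    (Region.WHITE, Region.GRAY): Call.INVALID,
}


def diagnose(region_low: Region, region_high: Region) -> Diagnosis:
    """Decision matrix over the (C_low region, C_high region) pair."""
    call = _DECISION_MATRIX[(Region(region_low), Region(region_high))]
    return Diagnosis(call=call, region_low=region_low, region_high=region_high)
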
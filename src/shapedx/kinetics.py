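"""Deoxygenation and sickling kinetics.

Dissolved-oxygen decay under a chemical scavenger follows
y(t) = A exp(-t/tau) + B; the time constant tau summarizes how fast the
chamber deoxygenates (about 12 min at the lowest scavenger concentration
down to under 2 min at the highest).  Sickling onset is summarized by the
delay time t_d (first cell whose roundness falls and stays below a
threshold) and by the sickled fraction n_sickle at a fixed time point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .synth import OxygenSeries

__all__ = [
    "DecayFit",
    "fit_deoxygenation",
    "delay_time",
    "sickled_fraction",
    "NO_SICKLING",
    "R_THRESHOLD",
]

R_THRESHOLD = 0.6  # roundness below this counts as sickled
PERSISTENCE = 3  # consecutive samples below threshold required for onset
NO_SICKLING = math.inf  # sentinel returned when no track ever sickles


@dataclass(frozen=True)
class DecayFit:
    A: float  # %
    tau: float  # min
    B: float  # %
    rmse: float  # %

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")


def _model(t, A, tau, B):
    return A * np.exp(-t / tau) + B


def fit_deoxygenation(series: OxygenSeries) -> DecayFit:
    """Nonlinear least squares fit of y = A exp(-t/tau) + B.

    Initialized at A = y0 - y_last, B = y_last, tau = span/3, with tau
    bounded in (0, 10*span].
    """
    t, y = series.times, series.values
    if t.size < 4:
        raise ValueError("need at least 4 points to fit the decay")
    if np.allclose(y, y[0]):
        raise ValueError("constant series: decay undefined")
    span = t[-1] - t[0]
    p0 = [y[0] - y[-1], span / 3.0, y[-1]]
    bounds = ([-np.inf, 1e-9, -np.inf], [np.inf, 10.0 * span, np.inf])
    try:
        popt, _ = curve_fit(_model, t, y, p0=p0, bounds=bounds, maxfev=20_000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"decay fit did not converge (n={t.size}, span={span} min): {exc}"
        ) from exc
    resid = y - _model(t, *popt)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return DecayFit(A=float(popt[0]), tau=float(popt[1]), B=float(popt[2]), rmse=rmse)


def delay_time(
    cell_roundness_tracks: dict,
    r_threshold: float = R_THRESHOLD,
    persistence: int = PERSISTENCE,
) -> float:
    """Delay time t_d: earliest time any cell's roundness drops below the
    threshold and stays below for ``persistence`` consecutive samples.

    ``cell_roundness_tracks`` maps cell id -> (times, roundness) arrays.
    Returns the NO_SICKLING sentinel (inf) if no track qualifies.
    """
    if not cell_roundness_tracks:
        raise ValueError("no tracks supplied")
    best = NO_SICKLING
    for cid, (times, values) in cell_roundness_tracks.items():
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        if times.size < persistence:
            raise ValueError(f"track {cid} shorter than persistence window")
        below = values < r_threshold
        run = 0
        for i, b in enumerate(below):
            run = run + 1 if b else 0
            if run >= persistence:
                onset = times[i - persistence + 1]
                best = min(best, onset)
                break
    return best


def sickled_fraction(cells, r_cutoff: float = R_THRESHOLD) -> float:
    """n_sickle: percentage of cells with roundness below the cutoff."""
    cells = list(cells)
    if not cells:
        raise ValueError("no cells supplied")
    rs = np.array([c.roundness for c in cells])
    return 100.0 * float(np.mean(rs < r_cutoff))
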
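"""Artefact detection and correction for RR-interval series.

Ectopic beats, missed detections and movement artefacts appear in an RR
tachogram as isolated intervals far from their local neighbourhood.  The
filter implemented here flags any beat whose relative deviation from the
median of its nearest unflagged neighbours exceeds a threshold (default
5%), then replaces flagged values by cubic-spline interpolation of the
surrounding clean beats, so the series keeps its length and a consistent
time axis for spectral analysis.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.interpolate import CubicSpline

from .core import RRSeries

log = logging.getLogger(__name__)

#: fraction of corrected beats above which a warning is logged
WARN_CORRECTED_FRACTION = 0.05
#: fraction of corrected beats above which correction refuses to run
MAX_CORRECTED_FRACTION = 0.20

_N_NEIGHBOURS = 5


def detect_artifacts(series: RRSeries, threshold: float = 0.05) -> np.ndarray:
    """Flag artefactual beats.

    A beat ``i`` is flagged iff ``|rr_i - m_i| / m_i > threshold`` where
    ``m_i`` is the median of the nearest 5 unflagged neighbours of ``i``
    (beat ``i`` itself excluded).  Flags are assigned in a single
    left-to-right pass: already-flagged earlier beats are excluded from
    later neighbourhoods, later beats are provisionally trusted.

    Parameters
    ----------
    series : RRSeries
    threshold : float
        Relative deviation threshold in (0, 1); default 0.05.

    Returns
    -------
    ndarray of bool, one flag per beat.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    rr = series.rr
    n = rr.size
    if n < _N_NEIGHBOURS:
        raise ValueError(
            f"series of length {n} too short for a {_N_NEIGHBOURS}-beat "
            "neighbourhood")
    flagged = np.zeros(n, dtype=bool)
    for i in range(n):
        neigh: list[float] = []
        dist = 1
        while len(neigh) < _N_NEIGHBOURS and dist < n:
            for j in (i - dist, i + dist):  # earlier neighbour first on ties
                if 0 <= j < n and not flagged[j]:
                    neigh.append(rr[j])
            dist += 1
        m = float(np.median(neigh[:_N_NEIGHBOURS]))
        if abs(rr[i] - m) / m > threshold:
            flagged[i] = True
    return flagged


def correct_artifacts(series: RRSeries, mask: np.ndarray) -> RRSeries:
    """Replace flagged RR values by cubic-spline interpolation.

    The spline is fitted to the unflagged ``(t, rr)`` pairs on the
    original beat-time axis and evaluated at the flagged beat times; beat
    times of the returned series are rebuilt from the corrected
    intervals.  Unflagged values are untouched and series length is
    preserved.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size != len(series):
        raise ValueError("mask length must equal series length")
    if not mask.any():
        return series.with_rr(series.rr)
    frac = mask.mean()
    if frac > MAX_CORRECTED_FRACTION:
        raise ValueError(
            f"{100 * frac:.1f}% of beats flagged — series unusable "
            f"(limit {100 * MAX_CORRECTED_FRACTION:.0f}%)")
    if mask.all():
        raise ValueError("all beats flagged — nothing to interpolate from")
    if frac > WARN_CORRECTED_FRACTION:
        log.warning(
            "sub %s phase %s test %s: %.1f%% of beats corrected "
            "(above the %.0f%% filter ceiling)", series.sub_id,
            series.phase_id, series.test_id, 100 * frac,
            100 * WARN_CORRECTED_FRACTION)
    t = series.t
    tu, ru = t[~mask], series.rr[~mask]
    spline = CubicSpline(tu, ru)
    rr = series.rr.copy()
    inside = mask & (t >= tu[0]) & (t <= tu[-1])
    rr[inside] = spline(t[inside])
    # spline extrapolation is unreliable: edge beats take the nearest
    # unflagged value instead
    edge = mask & ~inside
    if edge.any():
        rr[edge & (t < tu[0])] = ru[0]
        rr[edge & (t > tu[-1])] = ru[-1]
    if np.any(rr <= 0):
        raise ValueError("spline correction produced non-positive RR")
    log.info("sub %s phase %s test %s: corrected %d/%d beats",
             series.sub_id, series.phase_id, series.test_id,
             int(mask.sum()), mask.size)
    return series.with_rr(rr)


def clean(series: RRSeries, threshold: float = 0.05) -> RRSeries:
    """Detect-and-correct convenience wrapper used by the pipeline."""
    return correct_artifacts(series, detect_artifacts(series, threshold))
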
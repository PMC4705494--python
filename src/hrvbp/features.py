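"""The 22 short-term HRV measures.

Time domain: MeanRR, STDNN, RMSSD, NN50, pNN50 plus the geometric
histogram measures HRVtri and TINN.  Frequency domain: absolute LF and
HF band powers of the Burg autoregressive spectrum of the resampled
tachogram and their ratio.  Non-linear: Poincaré SD1/SD2, approximate
and sample entropy, Grassberger–Procaccia correlation dimension,
short/long-range DFA exponents, and five recurrence-plot statistics
(mean/max diagonal line length, recurrence rate, determinism, Shannon
entropy of the diagonal line-length distribution).

Measures that cannot be computed for a given series (too short, no
scaling region, zero denominator) are returned as NaN and the reason is
logged — never silently zero.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.interpolate import CubicSpline
from scipy.spatial.distance import pdist, squareform

from .core import FEATURE_NAMES, FeatureConfig, RRSeries

log = logging.getLogger(__name__)


# ---------------------------------------------------------------- time domain

def time_domain(rr: np.ndarray) -> dict[str, float]:
    """MeanRR, STDNN (sample SD), RMSSD, NN50 (|Δrr| > 50 ms) and
    pNN50 = 100·NN50/(N−1), the share of successive pairs."""
    rr = np.asarray(rr, dtype=float)
    if rr.size < 2:
        raise ValueError("time-domain measures need at least 2 intervals")
    d = np.diff(rr)
    nn50 = int(np.sum(np.abs(d) > 50.0))
    return {
        "MeanRR": float(np.mean(rr)),
        "STDNN": float(np.std(rr, ddof=1)),
        "RMSSD": float(np.sqrt(np.mean(d ** 2))),
        "NN50": float(nn50),
        "pNN50": 100.0 * nn50 / (rr.size - 1),
    }


# ----------------------------------------------------------------- geometric

def triangular(rr: np.ndarray, hist_bin_s: float = 1.0 / 128.0
               ) -> dict[str, float]:
    """Triangular index and TINN from the RR histogram.

    The histogram uses bins of width ``hist_bin_s`` (default 1/128 s)
    aligned to multiples of the bin width.  HRVtri is the total count
    divided by the modal count.  TINN is the baseline width (ms) of the
    best least-squares triangular interpolation of the histogram: a
    function rising linearly from zero at bin N to the modal height and
    falling to zero at bin M, with (N, M) found by exhaustive search
    (ties broken toward the smallest width).
    """
    rr = np.asarray(rr, dtype=float)
    if rr.size < 20:
        raise ValueError("triangular measures need at least 20 intervals")
    bw = hist_bin_s * 1000.0  # ms
    lo = np.floor(rr.min() / bw) * bw
    hi = np.ceil(rr.max() / bw + 1e-12) * bw
    nbins = max(1, int(round((hi - lo) / bw)))
    counts, _ = np.histogram(rr, bins=nbins, range=(lo, hi))
    hrvtri = rr.size / counts.max()
    if nbins == 1 or np.count_nonzero(counts) == 1:
        log.warning("degenerate RR histogram (single occupied bin); TINN=0")
        return {"HRVtri": float(hrvtri), "TINN": 0.0}

    # pad zero bins so the triangle may extend past the occupied range
    pad = nbins
    h = np.concatenate([np.zeros(pad), counts.astype(float), np.zeros(pad)])
    k_star = int(np.argmax(h))
    peak = h[k_star]
    ks = np.arange(h.size, dtype=float)
    best: tuple[float, float, int] | None = None  # (sse, width, n)
    for n_idx in range(0, k_star):
        left = np.zeros(h.size)
        sel = (ks >= n_idx) & (ks <= k_star)
        left[sel] = peak * (ks[sel] - n_idx) / (k_star - n_idx)
        sse_left = float(np.sum((h[: k_star] - left[: k_star]) ** 2))
        for m_idx in range(k_star + 1, h.size):
            tri = left.copy()
            sel_r = (ks > k_star) & (ks <= m_idx)
            tri[sel_r] = peak * (m_idx - ks[sel_r]) / (m_idx - k_star)
            sse = sse_left + float(
                np.sum((h[k_star:] - tri[k_star:]) ** 2))
            width = (m_idx - n_idx) * bw
            cand = (sse, width, n_idx)
            if best is None or cand < best:
                best = cand
    assert best is not None
    return {"HRVtri": float(hrvtri), "TINN": float(best[1])}


# ------------------------------------------------------------------ spectral

def burg_ar(x: np.ndarray, order: int) -> tuple[np.ndarray, float]:
    """Burg's method for AR coefficient estimation.

    Returns (rho, sigma2) with x_t = Σ rho_i x_{t-i} + e_t and sigma2
    the innovation variance from the lattice recursion.  The input is
    assumed mean-removed.
    """
    x = np.asarray(x, dtype=float)
    if x.size <= order:
        raise ValueError("series shorter than AR order")
    ef = x.copy()
    eb = x.copy()
    a = np.array([1.0])
    e = float(x @ x) / x.size
    for _ in range(order):
        efp = ef[1:]
        ebp = eb[:-1]
        den = float(efp @ efp) + float(ebp @ ebp)
        if den == 0.0:
            raise ValueError("degenerate (all-zero) series")
        k = -2.0 * float(efp @ ebp) / den
        ef, eb = efp + k * ebp, ebp + k * efp
        a = np.concatenate([a, [0.0]])
        a = a + k * a[::-1]
        e *= (1.0 - k * k)
    return -a[1:], e


def _spectral_grid(rho: np.ndarray, fs: float, nbase: int = 2048
                   ) -> np.ndarray:
    """Frequency grid for integrating an AR spectrum: uniform base plus
    geometric refinement around sharp pole angles (the peak width of a
    pole scales with its distance from the unit circle, so a uniform
    grid misses nearly-undamped peaks)."""
    grids = [np.linspace(0.0, fs / 2.0, nbase)]
    poles = np.roots(np.concatenate([[1.0], -rho]))
    for z in poles:
        if np.abs(z) < 0.95 or z.imag < 0.0:
            continue
        fc = float(np.angle(z)) / (2.0 * np.pi) * fs
        width = max(1.0 - float(np.abs(z)), 1e-12) * fs
        offs = np.geomspace(width * 1e-3, 0.02 * fs, 200)
        grids.append(fc + offs)
        grids.append(fc - offs)
        grids.append(np.array([fc]))
    f = np.unique(np.concatenate(grids))
    return f[(f >= 0.0) & (f <= fs / 2.0)]


def _ar_band_powers(x: np.ndarray, fs: float, order: int,
                    bands: list[tuple[float, float]]) -> list[float]:
    """Absolute band powers of the Burg AR(order) spectrum of ``x``."""
    rho, sigma2 = burg_ar(x - x.mean(), order)
    k = np.arange(1, order + 1)
    grid = _spectral_grid(rho, fs)
    out = []
    for lo, hi in bands:
        f = np.concatenate([[lo], grid[(grid > lo) & (grid < hi)], [hi]])
        # transfer denominator |1 - sum rho_k e^{-i 2 pi f k / fs}|^2
        e = np.exp(-2j * np.pi * np.outer(f / fs, k))
        denom = np.abs(1.0 - e @ rho) ** 2
        psd = 2.0 * sigma2 / fs / denom  # one-sided
        out.append(float(np.trapezoid(psd, f)))
    return out


def spectral(series: RRSeries, config: FeatureConfig = FeatureConfig()
             ) -> dict[str, float]:
    """LF and HF absolute powers (ms²) of the autoregressive spectrum.

    The mean-removed tachogram is cubic-spline resampled at
    ``resample_hz`` and a Burg AR model of order ``ar_order`` is fitted;
    band powers are numerical integrals of the one-sided AR spectrum
    over the LF and HF bands.  LF/HF is NaN when HF is zero.
    """
    if series.duration_s < 120.0:
        raise ValueError("spectral analysis needs at least 2 minutes")
    t = series.t
    x = series.rr - series.rr.mean()
    fs = config.resample_hz
    tt = np.arange(t[0], t[-1], 1.0 / fs)
    xx = CubicSpline(t, x)(tt)
    lf, hf = _ar_band_powers(xx, fs, config.ar_order,
                             [config.lf_band, config.hf_band])
    if hf <= 0.0:
        log.warning("HF power is zero; LF/HF reported as missing")
        ratio = float("nan")
    else:
        ratio = lf / hf
    return {"LF": lf, "HF": hf, "LFHF": ratio}


# ------------------------------------------------------------------ Poincaré

def poincare(rr: np.ndarray) -> dict[str, float]:
    """SD1/SD2 of the lag-1 Poincaré plot.

    SD1 = SD(successive differences)/√2 (dispersion perpendicular to the
    identity line); SD2 = sqrt(2·STDNN² − SD1²) (dispersion along it).
    """
    rr = np.asarray(rr, dtype=float)
    if rr.size < 3:
        raise ValueError("Poincaré measures need at least 3 intervals")
    sd1 = float(np.std(np.diff(rr) / np.sqrt(2.0), ddof=1))
    stdnn = float(np.std(rr, ddof=1))
    sd2 = float(np.sqrt(max(0.0, 2.0 * stdnn ** 2 - sd1 ** 2)))
    return {"SD1": sd1, "SD2": sd2}


# ------------------------------------------------------------------ entropy

def _template_matches(x: np.ndarray, m: int, r: float, n_templates: int
                      ) -> np.ndarray:
    """Chebyshev match matrix of the first ``n_templates`` m-windows."""
    w = sliding_window_view(x, m)[:n_templates]
    d = np.max(np.abs(w[:, None, :] - w[None, :, :]), axis=2)
    return d <= r


def approximate_entropy(rr: np.ndarray, m: int = 2, r: float | None = None,
                        r_factor: float = 0.2) -> float:
    """ApEn(m, r): Φ_m − Φ_{m+1} with self-matches included (Pincus)."""
    x = np.asarray(rr, dtype=float)
    if x.size < m + 2:
        raise ValueError("series too short for ApEn")
    if r is None:
        r = r_factor * np.std(x, ddof=1)

    def phi(mm: int) -> float:
        nt = x.size - mm + 1
        c = _template_matches(x, mm, r, nt).sum(axis=1) / nt
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def sample_entropy(rr: np.ndarray, m: int = 2, r: float | None = None,
                   r_factor: float = 0.2) -> float:
    """SampEn(m, r): −ln(A/B) with self-matches excluded
    (Richman–Moorman); NaN when no template pair matches at m+1."""
    x = np.asarray(rr, dtype=float)
    if x.size < m + 2:
        raise ValueError("series too short for SampEn")
    if r is None:
        r = r_factor * np.std(x, ddof=1)
    nt = x.size - m  # same template count at m and m+1
    b = int(_template_matches(x, m, r, nt).sum()) - nt
    a = int(_template_matches(x, m + 1, r, nt).sum()) - nt
    if b == 0 or a == 0:
        log.warning("SampEn: no template matches within r; reported missing")
        return float("nan")
    return float(-np.log(a / b))


# ------------------------------------------- correlation dimension (GP)

def _embed(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    n = x.size - (m - 1) * tau
    if n < 2:
        raise ValueError("series too short to embed")
    idx = np.arange(n)[:, None] + tau * np.arange(m)[None, :]
    return x[idx]


def correlation_dimension(rr: np.ndarray, m: int = 10, tau: int = 1,
                          theiler: int | None = None) -> float:
    """Grassberger–Procaccia correlation-dimension estimate.

    The series is delay-embedded (dimension ``m``, delay ``tau``), pairs
    closer in time than the Theiler window (default ``m``) are excluded,
    and the slope of log C(r) versus log r is fitted over the scaling
    region where the correlation sum lies in [0.005, 0.5].  Returns NaN
    when no scaling region is found; a slope near the embedding
    dimension (no saturation, as for white noise) is logged.
    """
    x = np.asarray(rr, dtype=float)
    if x.size < 200:
        raise ValueError("correlation dimension needs at least 200 beats")
    if theiler is None:
        theiler = m
    emb = _embed(x, m, tau)
    nv = emb.shape[0]
    dmat = squareform(pdist(emb))
    iu = np.triu_indices(nv, k=theiler + 1)
    d = dmat[iu]
    if d.size == 0:
        return float("nan")
    d = np.sort(d)
    rmin = max(d[max(0, int(0.005 * d.size))], 1e-12)
    rmax = d[-1]
    if rmax <= rmin:
        log.warning("D2: degenerate distance distribution; missing")
        return float("nan")
    rs = np.geomspace(rmin, rmax, 40)
    c = np.searchsorted(d, rs, side="right") / d.size
    sel = (c >= 0.005) & (c <= 0.5)
    if sel.sum() < 5:
        log.warning("D2: no scaling region found; reported missing")
        return float("nan")
    slope = float(np.polyfit(np.log(rs[sel]), np.log(c[sel]), 1)[0])
    if slope > 0.7 * m:
        log.warning("D2 slope %.2f close to embedding dimension %d: "
                    "no saturation (noise-like series)", slope, m)
    return slope


# ----------------------------------------------------------------------- DFA

def _fluctuation(y: np.ndarray, n: int) -> float:
    k = y.size // n
    seg = y[: k * n].reshape(k, n)
    x = np.arange(n, dtype=float)
    xm = x - x.mean()
    denom = float(np.sum(xm ** 2))
    slope = (seg @ xm) / denom
    inter = seg.mean(axis=1)
    resid = seg - inter[:, None] - slope[:, None] * xm[None, :]
    return float(np.sqrt(np.mean(resid ** 2)))


def dfa(rr: np.ndarray, short_range: tuple[int, int] = (4, 16),
        long_range: tuple[int, int] = (16, 64)) -> dict[str, float]:
    """Detrended fluctuation analysis exponents.

    The mean-centred series is integrated, split into non-overlapping
    boxes of each size, linearly detrended per box, and the root-mean-
    square fluctuation F(n) computed.  DFA1 is the log–log slope over
    box sizes 4–16 (every integer), DFA2 over 16–64 (log-spaced
    integers).  DFA2 is NaN for series shorter than 300 beats.
    """
    x = np.asarray(rr, dtype=float)
    if x.size < 100:
        raise ValueError("DFA needs at least 100 beats")
    y = np.cumsum(x - x.mean())

    def slope(sizes: np.ndarray) -> float:
        fl = np.array([_fluctuation(y, int(n)) for n in sizes])
        ok = fl > 0
        if ok.sum() < 3:
            return float("nan")
        return float(np.polyfit(np.log10(sizes[ok]), np.log10(fl[ok]), 1)[0])

    s1 = np.arange(short_range[0], short_range[1] + 1)
    dfa1 = slope(s1)
    if x.size < 300:
        log.info("DFA2 missing: series shorter than 300 beats")
        dfa2 = float("nan")
    else:
        s2 = np.unique(np.geomspace(long_range[0], long_range[1],
                                    12).astype(int))
        dfa2 = slope(s2)
    return {"DFA1": dfa1, "DFA2": dfa2}


# ----------------------------------------------------------------------- RQA

def rqa(rr: np.ndarray, m: int = 10, tau: int = 1,
        r_factor: float = 1.0, lmin: int = 2) -> dict[str, float]:
    """Recurrence quantification of the delay-embedded series.

    The recurrence matrix is R_ij = 1 iff the Euclidean distance between
    embedded points is at most r = r_factor·sqrt(m)·STDNN.  Statistics
    exclude the main diagonal; diagonal lines are maximal runs of
    recurrent points parallel to it, kept when at least ``lmin`` long.

    Returns RPREC (recurrence rate, %), RPDET (share of recurrent points
    on diagonal lines, %), RPLmean/RPLmax (mean/max line length, beats)
    and RPShan (Shannon entropy, nats, of the line-length distribution).
    """
    x = np.asarray(rr, dtype=float)
    if x.size < m * tau + 50:
        raise ValueError("series too short for recurrence analysis")
    emb = _embed(x, m, tau)
    nv = emb.shape[0]
    r = r_factor * np.sqrt(m) * np.std(x, ddof=1)
    rec = squareform(pdist(emb)) <= r
    total = nv * nv - nv
    npoints = int(rec.sum()) - nv  # main diagonal (distance 0) excluded
    out = {"RPREC": 100.0 * npoints / total}
    if npoints == 0:
        log.warning("RQA: no recurrent points; line statistics missing")
        out.update({k: float("nan")
                    for k in ("RPDET", "RPLmean", "RPLmax", "RPShan")})
        return out
    lengths: list[int] = []
    for k in range(1, nv):
        diag = np.diagonal(rec, offset=k)
        if not diag.any():
            continue
        d = np.diff(np.concatenate(([0], diag.astype(np.int8), [0])))
        runs = np.flatnonzero(d == -1) - np.flatnonzero(d == 1)
        lengths.extend(runs.tolist())
    lengths = np.asarray(lengths + lengths)  # lower triangle mirrors upper
    lines = lengths[lengths >= lmin]
    if lines.size == 0:
        out.update({"RPDET": 0.0, "RPLmean": float("nan"),
                    "RPLmax": float("nan"), "RPShan": float("nan")})
        return out
    out["RPDET"] = 100.0 * float(lines.sum()) / npoints
    out["RPLmean"] = float(lines.mean())
    out["RPLmax"] = float(lines.max())
    _, cnt = np.unique(lines, return_counts=True)
    p = cnt / cnt.sum()
    out["RPShan"] = float(-np.sum(p * np.log(p)))
    return out


# ----------------------------------------------------------------- assembly

_GROUPS: dict[str, tuple[str, ...]] = {
    "time": ("MeanRR", "STDNN", "RMSSD", "NN50", "pNN50"),
    "geometric": ("HRVtri", "TINN"),
    "spectral": ("LF", "HF", "LFHF"),
    "poincare": ("SD1", "SD2"),
    "entropy": ("ApEn", "SampEn"),
    "d2": ("D2",),
    "dfa": ("DFA1", "DFA2"),
    "rqa": ("RPLmean", "RPLmax", "RPREC", "RPDET", "RPShan"),
}


def extract_all(series: RRSeries, config: FeatureConfig = FeatureConfig(),
                features: list[str] | None = None) -> pd.Series:
    """Compute the full 22-measure vector (or the groups covering a
    requested subset of names) for one corrected series.

    Measures whose preconditions fail are NaN; the reason is logged with
    the feature name.  Returns a Series indexed by the canonical names.
    """
    wanted = set(FEATURE_NAMES if features is None else features)
    unknown = wanted - set(FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unknown feature names: {sorted(unknown)}")
    out = pd.Series(np.nan, index=list(FEATURE_NAMES), dtype=float)
    rr = series.rr
    for group, names in _GROUPS.items():
        if not wanted & set(names):
            continue
        try:
            if group == "time":
                vals = time_domain(rr)
            elif group == "geometric":
                vals = triangular(rr, config.hist_bin_s)
            elif group == "spectral":
                vals = spectral(series, config)
            elif group == "poincare":
                vals = poincare(rr)
            elif group == "entropy":
                if rr.size < 50:
                    raise ValueError("entropy needs at least 50 beats")
                vals = {
                    "ApEn": approximate_entropy(
                        rr, config.entropy_m,
                        r_factor=config.entropy_r_factor),
                    "SampEn": sample_entropy(
                        rr, config.entropy_m,
                        r_factor=config.entropy_r_factor),
                }
            elif group == "d2":
                vals = {"D2": correlation_dimension(rr, config.d2_m)}
            elif group == "dfa":
                vals = dfa(rr, config.dfa_short, config.dfa_long)
            else:
                vals = rqa(rr, config.rqa_m, config.rqa_tau,
                           config.rqa_r_factor, config.rqa_lmin)
        except ValueError as exc:
            log.info("sub %s phase %s test %s: %s missing (%s)",
                     series.sub_id, series.phase_id, series.test_id,
                     "/".join(names), exc)
            continue
        for k, v in vals.items():
            out[k] = v
    return out


def extract_features_table(series_list: list[RRSeries],
                           config: FeatureConfig = FeatureConfig()
                           ) -> pd.DataFrame:
    """Feature table with one row per (sub_id, phase_id, test_id)."""
    rows = []
    for s in series_list:
        row = {"sub_id": s.sub_id, "phase_id": s.phase_id,
               "test_id": s.test_id}
        row.update(extract_all(s, config).to_dict())
        rows.append(row)
    return pd.DataFrame(rows, columns=["sub_id", "phase_id", "test_id",
                                       *FEATURE_NAMES])
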
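"""Shared domain types for the HRV → orthostatic blood-pressure-drop pipeline.

The pipeline operates on short RR-interval series (the times between
consecutive normal heart beats, in milliseconds), summarised by 22
heart-rate-variability (HRV) measures spanning the time domain, the
frequency domain (autoregressive band powers) and a battery of non-linear
statistics (Poincaré descriptors, entropies, correlation dimension,
detrended fluctuation analysis and recurrence quantification).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Canonical feature order used everywhere (CSV columns, model subsets).
FEATURE_NAMES: tuple[str, ...] = (
    "MeanRR", "STDNN", "RMSSD", "NN50", "pNN50", "HRVtri", "TINN",
    "LF", "HF", "LFHF",
    "SD1", "SD2", "ApEn", "SampEn", "D2", "DFA1", "DFA2",
    "RPLmean", "RPLmax", "RPREC", "RPDET", "RPShan",
)

PHASE_SITTING = 1
PHASE_LYING = 2
PHASE_STANDING = 3


@dataclass
class RRSeries:
    """One RR-interval excerpt with its protocol identity.

    Parameters
    ----------
    rr : ndarray
        RR intervals in milliseconds, all positive and finite.
    sub_id, phase_id, test_id : int
        Subject, protocol phase (1 sitting, 2 lying, 3 standing) and
        repetition (1..4; 0 for the single sitting excerpt).
    """

    rr: np.ndarray
    sub_id: int = 0
    phase_id: int = 0
    test_id: int = 0

    def __post_init__(self) -> None:
        self.rr = np.asarray(self.rr, dtype=float)
        if self.rr.ndim != 1 or self.rr.size == 0:
            raise ValueError("rr must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.rr)) or np.any(self.rr <= 0):
            raise ValueError("RR intervals must be positive and finite")

    @property
    def t(self) -> np.ndarray:
        """Cumulative beat times in seconds (t_i - t_{i-1} = rr_i / 1000)."""
        return np.cumsum(self.rr) / 1000.0

    @property
    def duration_s(self) -> float:
        return float(self.rr.sum() / 1000.0)

    def __len__(self) -> int:
        return int(self.rr.size)

    def with_rr(self, rr: np.ndarray) -> "RRSeries":
        return RRSeries(np.asarray(rr, dtype=float), self.sub_id,
                        self.phase_id, self.test_id)


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable parameters of the HRV feature battery.

    Defaults follow the conventional settings of widely used HRV analysis
    software: 4 Hz cubic-spline resampling with a Burg autoregressive
    spectrum of order 16 and the standard 0.04–0.15 / 0.15–0.40 Hz bands;
    1/128 s histogram bins for the geometric measures; entropies with
    m = 2, r = 0.2·SDNN; recurrence analysis with embedding 10, delay 1,
    radius sqrt(m)·SDNN and minimum line length 2; DFA box ranges 4–16
    and 16–64 beats; correlation-dimension embedding 10.
    """

    resample_hz: float = 4.0
    ar_order: int = 16
    lf_band: tuple[float, float] = (0.04, 0.15)
    hf_band: tuple[float, float] = (0.15, 0.40)
    hist_bin_s: float = 1.0 / 128.0
    entropy_m: int = 2
    entropy_r_factor: float = 0.2
    rqa_m: int = 10
    rqa_tau: int = 1
    rqa_r_factor: float = 1.0
    rqa_lmin: int = 2
    dfa_short: tuple[int, int] = (4, 16)
    dfa_long: tuple[int, int] = (16, 64)
    d2_m: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.lf_band[0] < self.lf_band[1] <= self.hf_band[0]
                < self.hf_band[1]):
            raise ValueError("LF/HF bands must be ordered and disjoint")
        for name in ("ar_order", "entropy_m", "rqa_m", "rqa_tau",
                     "rqa_lmin", "d2_m"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be a positive integer")


@dataclass
class SubjectParams:
    """Generator parameters describing one synthetic subject.

    The RR process is a mean interval modulated by one low-frequency and
    one high-frequency sinusoid (the two classical autonomic bands) plus
    white noise; blood pressure is a subject baseline plus measurement
    noise.
    """

    mu_rr: float = 850.0          # mean RR (ms)
    a_lf: float = 25.0            # LF modulation amplitude (ms)
    f_lf: float = 0.095           # LF modulation frequency (Hz)
    a_hf: float = 30.0            # HF modulation amplitude (ms)
    f_hf: float = 0.25            # HF modulation frequency (Hz)
    sigma_rr: float = 8.0         # white-noise SD (ms)
    sys_base: float = 120.0       # baseline lying systolic BP (mmHg)
    dia_base: float = 75.0        # baseline lying diastolic BP (mmHg)
    sigma_bp: float = 3.0         # BP measurement noise SD (mmHg)

    def validate(self) -> None:
        if self.mu_rr <= 0:
            raise ValueError("mu_rr must be positive")
        for name in ("a_lf", "a_hf", "sigma_rr", "sigma_bp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0.04 <= self.f_lf < 0.15 <= self.f_hf <= 0.40):
            raise ValueError("need 0.04 <= f_lf < 0.15 <= f_hf <= 0.40")
        if self.mu_rr <= self.a_lf + self.a_hf:
            raise ValueError("mu_rr must exceed a_lf + a_hf")

    def standing(self) -> "SubjectParams":
        """Parameters for the upright posture: faster heart rate and
        vagal withdrawal (reduced HF modulation)."""
        return replace(self, mu_rr=self.mu_rr * 0.85, a_hf=self.a_hf * 0.6,
                       a_lf=self.a_lf * 1.1)


@dataclass
class TrueModel:
    """Ground-truth linear dependence of the standing BP drop on
    lying-phase HRV features:  ΔBP = c0 + Σ c_j f_j + ε,  ε ~ N(0, eps_sd²).
    """

    c0: float
    coeffs: dict[str, float] = field(default_factory=dict)
    eps_sd: float = 0.0

    def validate(self) -> None:
        bad = [k for k in self.coeffs if k not in FEATURE_NAMES]
        if bad:
            raise ValueError(f"unknown feature names in coeffs: {bad}")
        if self.eps_sd < 0:
            raise ValueError("eps_sd must be non-negative")

    @property
    def feature_names(self) -> list[str]:
        """Model features in canonical order."""
        return [f for f in FEATURE_NAMES if f in self.coeffs]

    def linear_predictor(self, features) -> float:
        """c0 + Σ c_j f_j for a mapping/Series of feature values."""
        return float(self.c0 + sum(c * float(features[name])
                                   for name, c in self.coeffs.items()))
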
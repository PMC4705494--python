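"""Raw and predictive datasets.

The raw database holds nine instances per subject (one sitting, four
lying, four standing), each carrying its BP readings and HRV feature
vector.  The predictive dataset pairs the lying-phase features of each
repetition with the blood-pressure change measured after the matching
stand: ΔBP = BP7 − mean(BP2..BP5), where readings are numbered 1–9
across the session (1 sitting, 2–5 lying, 6–9 standing), so BP7 is the
second standing reading — the one taken during the second minute after
standing.  Negative ΔBP means a drop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (FEATURE_NAMES, PHASE_LYING, PHASE_SITTING,
                   PHASE_STANDING)

log = logging.getLogger(__name__)

#: readings expected per phase
_N_READINGS = {PHASE_SITTING: 1, PHASE_LYING: 4, PHASE_STANDING: 4}
#: index (1-based, within phase) of the standing reading used for ΔBP
BP7_READING_INDEX = 2


@dataclass
class RawInstance:
    """One row of the raw database."""

    sub_id: int
    phase_id: int
    test_id: int
    symptom_id: int
    sys_bp: np.ndarray
    dia_bp: np.ndarray
    features: pd.Series | None = None

    def __post_init__(self) -> None:
        self.sys_bp = np.asarray(self.sys_bp, dtype=float)
        self.dia_bp = np.asarray(self.dia_bp, dtype=float)
        n = _N_READINGS.get(self.phase_id)
        if n is not None and (self.sys_bp.size != n
                              or self.dia_bp.size != n):
            raise ValueError(
                f"phase {self.phase_id} carries {n} BP reading(s), got "
                f"{self.sys_bp.size}/{self.dia_bp.size}")
        for v in np.concatenate([self.sys_bp, self.dia_bp]):
            if not (40.0 < v < 260.0):
                raise ValueError(f"BP reading {v:.1f} outside (40, 260) mmHg")


def delta_bp_error(nominal_error: float, n: int) -> float:
    """Measurement error of ΔBP from a device of nominal error NE when
    the reference pressure is the mean of ``n`` repeated readings:
    NE + NE/sqrt(n).  (With NE = 3 mmHg and n = 4: 4.5 mmHg.)"""
    if nominal_error < 0:
        raise ValueError("nominal_error must be non-negative")
    n = int(n)
    if n < 1:
        raise ValueError("n must be a positive integer")
    return nominal_error + nominal_error / np.sqrt(n)


def compute_delta_bp(standing_bp_minute2: float, lying_bps) -> float:
    """ΔBP = BP7 − mean of the four lying readings (negative = drop)."""
    lying = np.asarray(lying_bps, dtype=float)
    if lying.size != 4 or not np.all(np.isfinite(lying)):
        raise ValueError("exactly 4 finite lying readings required")
    if not np.isfinite(standing_bp_minute2):
        raise ValueError("standing reading missing")
    return float(standing_bp_minute2 - lying.mean())


def build_raw_dataset(bp: pd.DataFrame,
                      features: pd.DataFrame | None = None,
                      symptoms: pd.DataFrame | None = None
                      ) -> list[RawInstance]:
    """Assemble raw instances from the BP reading table and, when
    available, the feature table (sub_id/phase_id/test_id keyed) and the
    symptom table (sub_id/test_id keyed; grade 0 assumed when absent).
    """
    feat_idx = None
    if features is not None and len(features):
        feat_idx = features.set_index(["sub_id", "phase_id", "test_id"])
    sym_idx = {}
    if symptoms is not None and len(symptoms):
        sym_idx = {(int(r.sub_id), int(r.test_id)): int(r.symptom_id)
                   for r in symptoms.itertuples()}
    out: list[RawInstance] = []
    for (sub, phase, test), grp in bp.groupby(
            ["sub_id", "phase_id", "test_id"], sort=True):
        grp = grp.sort_values("reading_index")
        fv = None
        if feat_idx is not None and (sub, phase, test) in feat_idx.index:
            fv = feat_idx.loc[(sub, phase, test), list(FEATURE_NAMES)]
        out.append(RawInstance(
            sub_id=int(sub), phase_id=int(phase), test_id=int(test),
            symptom_id=sym_idx.get((int(sub), int(test)), 0),
            sys_bp=grp["sys_mmhg"].to_numpy(),
            dia_bp=grp["dia_mmhg"].to_numpy(),
            features=fv))
    return out


def build_predictive_dataset(raw: list[RawInstance]) -> pd.DataFrame:
    """Derive the predictive dataset: one row per (subject, repetition)
    pairing the lying-phase feature vector with ΔSYS/ΔDIA of the
    matching stand.  Repetitions with a missing lying or standing half,
    or without lying features, are skipped with a warning.

    Returns a DataFrame with columns sub_id, test_id, symptom_id,
    delta_sys, delta_dia and the 22 feature columns (lying phase only).
    """
    index: dict[tuple[int, int, int], RawInstance] = {
        (r.sub_id, r.phase_id, r.test_id): r for r in raw}
    pairs = sorted({(r.sub_id, r.test_id) for r in raw
                    if r.phase_id in (PHASE_LYING, PHASE_STANDING)})
    rows = []
    for sub, test in pairs:
        lying = index.get((sub, PHASE_LYING, test))
        standing = index.get((sub, PHASE_STANDING, test))
        if lying is None or standing is None:
            log.warning("subject %d repetition %d: unmatched lying/standing "
                        "pair — instance skipped", sub, test)
            continue
        if lying.features is None:
            log.warning("subject %d repetition %d: lying features missing — "
                        "instance skipped", sub, test)
            continue
        bp7_sys = standing.sys_bp[BP7_READING_INDEX - 1]
        bp7_dia = standing.dia_bp[BP7_READING_INDEX - 1]
        row = {"sub_id": sub, "test_id": test,
               "symptom_id": lying.symptom_id,
               "delta_sys": compute_delta_bp(bp7_sys, lying.sys_bp),
               "delta_dia": compute_delta_bp(bp7_dia, lying.dia_bp)}
        row.update({k: float(lying.features[k]) for k in FEATURE_NAMES})
        rows.append(row)
    return pd.DataFrame(rows, columns=["sub_id", "test_id", "symptom_id",
                                       "delta_sys", "delta_dia",
                                       *FEATURE_NAMES])
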
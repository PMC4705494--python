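"""Protocol-faithful synthetic cohorts.

The study protocol this emulates: each subject contributes one sitting
baseline (2-minute RR excerpt, one BP measurement) and ``n_reps``
lying/standing repetitions (5-minute RR excerpt and four BP measurements
per phase).  The systolic drop injected on the second standing reading
truly follows a linear model in the lying-phase HRV features,
ΔBP = c0 + Σ c_j f_j + ε, so parameter recovery and subset selection are
testable end-to-end with known ground truth.

The RR process is a two-tone sinusoid (one LF, one HF component,
evaluated at the cumulative beat time, i.e. irregularly sampled exactly
as real heart-rate modulation is) plus white noise.  This is the
simplest process with independently controllable LF/HF balance and
SDNN; it does not emulate breathing variability, ectopy or
non-stationarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (PHASE_LYING, PHASE_SITTING, PHASE_STANDING,
                   FeatureConfig, RRSeries, SubjectParams, TrueModel)
from .features import extract_all
from .preprocess import clean

log = logging.getLogger(__name__)

#: factor applied to the second-minute standing reading (the one used for
#: the drop) and the decaying echo applied to the remaining standing
#: readings as pressure recovers
_STANDING_DECAY = {1: 1.1, 2: 1.0, 3: 0.6, 4: 0.3}


def default_true_model(eps_sd: float = 3.0) -> TrueModel:
    """Default ground-truth drop model: plausible coefficient magnitudes
    linking vagal markers (RMSSD, NN50, HF), overall variability (TINN)
    and heart-beat determinism (RPDET) to the systolic drop."""
    return TrueModel(
        c0=-25.67,
        coeffs={"RMSSD": 0.45, "NN50": -0.05, "TINN": -0.02,
                "HF": -0.01, "RPDET": 0.3},
        eps_sd=eps_sd,
    )


def default_subject_params(n_subjects: int, seed: int = 0,
                           sigma_bp: float = 3.0) -> list[SubjectParams]:
    """Deterministically sampled per-subject parameters.

    Ranges span plausible resting adult physiology: mean RR 750–950 ms,
    LF/HF modulation amplitudes 8–25 / 8–22 ms at 0.06–0.12 /
    0.18–0.28 Hz, white-noise SD 3–10 ms, lying baselines 105–140 /
    65–85 mmHg.  Amplitudes and rates are kept in the range where the
    beat-to-beat step of a smooth autonomic oscillation stays below the
    5% artefact-filter threshold, as it does in resting recordings.  The
    BP measurement noise SD defaults to the 3 mmHg nominal device error.
    """
    out = []
    for s in range(1, n_subjects + 1):
        rng = np.random.default_rng(np.random.SeedSequence((seed, s, 99)))
        u = rng.uniform
        out.append(SubjectParams(
            mu_rr=u(750.0, 950.0), a_lf=u(8.0, 25.0), f_lf=u(0.06, 0.12),
            a_hf=u(8.0, 22.0), f_hf=u(0.18, 0.28), sigma_rr=u(3.0, 10.0),
            sys_base=u(105.0, 140.0), dia_base=u(65.0, 85.0),
            sigma_bp=sigma_bp))
    return out


def generate_rr_series(params: SubjectParams, duration: float, seed,
                       sub_id: int = 0, phase_id: int = 0,
                       test_id: int = 0) -> RRSeries:
    """Generate one RR excerpt covering at least ``duration`` seconds.

    RR_i = mu_rr + a_lf·sin(2π f_lf t_i) + a_hf·sin(2π f_hf t_i)
    + sigma_rr·w_i, with t_i the cumulative time at which interval ``i``
    starts and w_i standard normal.  Reproducible for a fixed seed.

    Raises
    ------
    ValueError
        For parameter sets that can produce non-positive intervals
        (mu_rr <= a_lf + a_hf + 5·sigma_rr) or non-positive duration.
    """
    params.validate()
    if duration <= 0:
        raise ValueError("duration must be positive")
    if params.mu_rr <= params.a_lf + params.a_hf + 5.0 * params.sigma_rr:
        raise ValueError(
            "parameters can produce non-positive RR intervals "
            "(need mu_rr > a_lf + a_hf + 5*sigma_rr)")
    rng = np.random.default_rng(seed)
    t = 0.0
    rr: list[float] = []
    two_pi = 2.0 * np.pi
    while t < duration:
        val = (params.mu_rr
               + params.a_lf * np.sin(two_pi * params.f_lf * t)
               + params.a_hf * np.sin(two_pi * params.f_hf * t)
               + params.sigma_rr * rng.standard_normal())
        rr.append(val)
        t += val / 1000.0
    return RRSeries(np.array(rr), sub_id, phase_id, test_id)


@dataclass
class SyntheticCohort:
    """Raw synthetic dataset: RR excerpts, BP reading table, symptom
    table and the ground-truth drop sidecar."""

    rr_series: list[RRSeries]
    bp: pd.DataFrame        # sub_id, phase_id, test_id, reading_index, sys_mmhg, dia_mmhg
    symptoms: pd.DataFrame  # sub_id, test_id, symptom_id
    truth: pd.DataFrame     # sub_id, test_id, delta_sys_true, delta_dia_true
    true_model: TrueModel
    lying_features: pd.DataFrame = field(default_factory=pd.DataFrame)


def _rng_for(seed: int, sub: int, phase: int, test: int, stream: int):
    """Deterministic per-(subject, phase, repetition, stream) generator,
    so cohorts are extensible without reshuffling earlier subjects."""
    return np.random.default_rng(
        np.random.SeedSequence((seed, sub, phase, test, stream)))


def generate_cohort(n_subjects: int, n_reps: int,
                    subject_params: list[SubjectParams] | None = None,
                    true_model: TrueModel | None = None,
                    seed: int = 0,
                    dia_model: TrueModel | None = None,
                    config: FeatureConfig = FeatureConfig(),
                    artifact_threshold: float = 0.05,
                    sitting_minutes: float = 2.0,
                    phase_minutes: float = 5.0,
                    rep_jitter: float = 0.2) -> SyntheticCohort:
    """Generate a full cohort following the three-phase protocol.

    Per subject: one sitting instance (2-min RR, 1 systolic + 1 diastolic
    reading) and ``n_reps`` lying and standing instances (5-min RR, 4
    readings each).  Lying readings are baseline + N(0, sigma_bp).  The
    second-minute standing reading equals the mean of that repetition's
    lying readings plus the true drop c0 + Σ c_j f_j(lying RR) +
    N(0, eps_sd) plus its own measurement noise; the remaining standing
    readings carry a decaying echo of the drop.  The injected drop is
    computed from the lying features *after* artefact filtering, i.e.
    from exactly the feature values the analysis pipeline will measure.

    Repetitions are distinct autonomic states: before each repetition
    the subject's modulation amplitudes, noise SD and (mildly) mean RR
    are multiplied by deterministic per-repetition factors drawn within
    ``±rep_jitter`` (±10·rep_jitter % for mu_rr), emulating the
    visit-to-visit drift seen between real repetitions recorded minutes
    apart.  Set ``rep_jitter=0`` for identical repetitions.

    The drop is injected on systolic pressure; pass ``dia_model`` to
    inject a diastolic drop the same way.  Ground truth (including ε but
    not the BP reading noise) is stored in the ``truth`` sidecar.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if n_reps < 1:
        raise ValueError("need at least 1 repetition")
    if subject_params is None:
        subject_params = default_subject_params(n_subjects, seed=seed)
    if len(subject_params) != n_subjects:
        raise ValueError(
            f"subject_params has {len(subject_params)} entries for "
            f"{n_subjects} subjects")
    if true_model is None:
        true_model = default_true_model()
    true_model.validate()
    if dia_model is not None:
        dia_model.validate()
    needed = sorted(set(true_model.coeffs)
                    | (set(dia_model.coeffs) if dia_model else set()))

    series: list[RRSeries] = []
    bp_rows: list[dict] = []
    sym_rows: list[dict] = []
    truth_rows: list[dict] = []
    feat_rows: list[dict] = []

    for s_idx, p in enumerate(subject_params, start=1):
        p.validate()
        # phase 1: sitting baseline
        sit = generate_rr_series(
            p, sitting_minutes * 60.0,
            np.random.SeedSequence((seed, s_idx, PHASE_SITTING, 0, 0)),
            s_idx, PHASE_SITTING, 0)
        series.append(sit)
        rng = _rng_for(seed, s_idx, PHASE_SITTING, 0, 1)
        bp_rows.append({"sub_id": s_idx, "phase_id": PHASE_SITTING,
                        "test_id": 0, "reading_index": 1,
                        "sys_mmhg": p.sys_base + 5.0
                        + p.sigma_bp * rng.standard_normal(),
                        "dia_mmhg": p.dia_base + 3.0
                        + p.sigma_bp * rng.standard_normal()})

        for rep in range(1, n_reps + 1):
            p_rep = _jittered(p, rep_jitter,
                              _rng_for(seed, s_idx, PHASE_LYING, rep, 3))
            lying = generate_rr_series(
                p_rep, phase_minutes * 60.0,
                np.random.SeedSequence((seed, s_idx, PHASE_LYING, rep, 0)),
                s_idx, PHASE_LYING, rep)
            standing = generate_rr_series(
                p_rep.standing(), phase_minutes * 60.0,
                np.random.SeedSequence((seed, s_idx, PHASE_STANDING, rep, 0)),
                s_idx, PHASE_STANDING, rep)
            series.extend([lying, standing])

            rng_ly = _rng_for(seed, s_idx, PHASE_LYING, rep, 1)
            lying_sys = p.sys_base + p.sigma_bp * rng_ly.standard_normal(4)
            lying_dia = p.dia_base + p.sigma_bp * rng_ly.standard_normal(4)
            for i in range(4):
                bp_rows.append({"sub_id": s_idx, "phase_id": PHASE_LYING,
                                "test_id": rep, "reading_index": i + 1,
                                "sys_mmhg": lying_sys[i],
                                "dia_mmhg": lying_dia[i]})

            feats = extract_all(clean(lying, artifact_threshold), config,
                                features=needed or None)
            feat_rows.append({"sub_id": s_idx, "test_id": rep,
                              **feats.to_dict()})
            rng_eps = _rng_for(seed, s_idx, PHASE_STANDING, rep, 2)
            drop_sys = (true_model.linear_predictor(feats)
                        + true_model.eps_sd * rng_eps.standard_normal())
            drop_dia = 0.0
            if dia_model is not None:
                drop_dia = (dia_model.linear_predictor(feats)
                            + dia_model.eps_sd * rng_eps.standard_normal())

            rng_st = _rng_for(seed, s_idx, PHASE_STANDING, rep, 1)
            base_sys = float(np.mean(lying_sys))
            base_dia = float(np.mean(lying_dia))
            for i in range(4):
                decay = _STANDING_DECAY[i + 1]
                bp_rows.append({
                    "sub_id": s_idx, "phase_id": PHASE_STANDING,
                    "test_id": rep, "reading_index": i + 1,
                    "sys_mmhg": base_sys + decay * drop_sys
                    + p.sigma_bp * rng_st.standard_normal(),
                    "dia_mmhg": base_dia + decay * drop_dia
                    + p.sigma_bp * rng_st.standard_normal()})

            sym_rows.append({"sub_id": s_idx, "test_id": rep,
                             "symptom_id": _symptom_grade(drop_sys)})
            truth_rows.append({"sub_id": s_idx, "test_id": rep,
                               "delta_sys_true": drop_sys,
                               "delta_dia_true": drop_dia})

    cohort = SyntheticCohort(
        rr_series=series,
        bp=pd.DataFrame(bp_rows),
        symptoms=pd.DataFrame(sym_rows),
        truth=pd.DataFrame(truth_rows),
        true_model=true_model,
        lying_features=pd.DataFrame(feat_rows),
    )
    log.info("generated cohort: %d subjects x %d reps, %d RR excerpts, "
             "%d BP readings", n_subjects, n_reps, len(series),
             len(cohort.bp))
    return cohort


def _jittered(p: SubjectParams, jitter: float, rng) -> SubjectParams:
    """Per-repetition autonomic state: amplitudes and noise scaled by
    1 ± jitter, mean RR by 1 ± jitter/10 (heart rate drifts less than
    its variability does)."""
    if jitter == 0.0:
        return p
    f = lambda scale: 1.0 + rng.uniform(-jitter, jitter) * scale  # noqa: E731
    return replace(p, mu_rr=p.mu_rr * f(0.1), a_lf=p.a_lf * f(1.0),
                   a_hf=p.a_hf * f(1.0), sigma_rr=p.sigma_rr * f(1.0))


def _symptom_grade(drop_sys: float) -> int:
    """Vertigo grade stored alongside (never modeled): 2 for a systolic
    drop beyond 20 mmHg, 1 beyond 10 mmHg, else 0."""
    if drop_sys <= -20.0:
        return 2
    if drop_sys <= -10.0:
        return 1
    return 0
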
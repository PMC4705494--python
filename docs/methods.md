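# Methods

This note documents the models, defaults and numerical choices behind
`hrvbp`, in the order data flows through the pipeline.

## 1. Protocol and data model

A session has three phases per subject: sitting baseline (≥2-minute RR
excerpt, one BP measurement), lying (5-minute RR excerpt, four BP
measurements a minute apart) and standing (same as lying), with the
lying/standing pair repeated four times.  Readings are indexed 1–9
across a repetition's session context (1 sitting, 2–5 lying, 6–9
standing), so the drop uses BP₇ — the second standing reading, taken
during the second minute upright, the window where orthostatic falls
are most frequent:

ΔBP = BP₇ − mean(BP₂…BP₅), negative values are drops.

With a device of nominal error NE, referencing the drop to the mean of
n repeated readings propagates to an error NE + NE/√n on ΔBP
(4.5 mmHg at NE = 3, n = 4).  The first term is the error of BP₇
itself, the second the standard error of the n-reading mean.

The raw database holds 9 instances per subject
(sub_id, phase_id, test_id, symptom_id, BP readings, 22-feature vector);
the predictive dataset has one row per (subject, repetition) pairing
*lying-phase* features with the ΔSYS/ΔDIA of the matching stand —
features never come from the sitting or standing excerpts.  The vertigo
grade (symptom_id 0/1/2) is stored for completeness and never modelled.

## 2. RR artefact filter

Beat *i* is artefactual when |rr_i − m_i|/m_i > 5% (configurable),
where m_i is the median of the nearest five unflagged neighbours,
assigned in one left-to-right pass.  Flagged values are replaced by a
cubic spline through the unflagged (t, rr) points, evaluated at the
flagged beat times; beats flagged at the series edges take the nearest
unflagged value instead, because cubic extrapolation is unreliable
there.  Interpolation rather than deletion keeps the beat count and
time axis consistent for spectral analysis.  The threshold is a
per-beat deviation bound; a corrected fraction above 5% additionally
logs a warning (the filter's design ceiling) and above 20% the series
is rejected as unusable.  Re-running the filter on corrected output
flags nothing (idempotence, enforced by test).

## 3. The 22 HRV measures

Time domain: MeanRR; STDNN (sample SD, N−1); RMSSD; NN50 (successive
differences > 50 ms); pNN50 = 100·NN50/(N−1) — the denominator is the
number of successive pairs, the dominant convention, although "total
number of intervals" is sometimes used.

Geometric: histogram with 1/128 s bins aligned to multiples of the bin
width.  HRVtri = N / modal count.  TINN is the base width of the best
least-squares triangular interpolation (zero at bins N and M, modal
height at the mode), found by exhaustive search over (N, M) with
zero-count padding so the triangle may extend beyond the occupied
range; ties go to the smallest width.

Frequency domain: the mean-removed tachogram is cubic-spline resampled
at 4 Hz, an AR(16) model is fitted by Burg's lattice recursion
(implemented in-package; coefficients verified against an independent
implementation to machine precision), and LF (0.04–0.15 Hz) and HF
(0.15–0.40 Hz) are numerical integrals of the one-sided AR spectrum in
ms².  Because AR poles approach the unit circle for nearly periodic
series, the integration grid is refined geometrically around each
sharp pole angle (peak width ∝ distance from the circle); a uniform
grid can miss half the power of a weakly damped peak.  LF/HF is
reported missing when HF = 0.

Poincaré: SD1 = SD(Δrr)/√2, SD2 = √(2·STDNN² − SD1²); the identities
SD1 ≡ SDSD/√2 and SD1² + SD2² ≡ 2·STDNN² hold to 1e-9 by construction
and are property-tested.

Entropies (m = 2, r = 0.2·STDNN, Chebyshev distance): ApEn includes
self-matches (Pincus); SampEn excludes them (Richman–Moorman), with
both template sets of size N−m so the m and m+1 counts are comparable;
SampEn is missing when no template pair matches.  Both are verified
against brute-force double-loop counters on short series.

Correlation dimension (embedding 10, delay 1, Theiler window 10):
Grassberger–Procaccia slope of log C(r) vs log r, fitted over the
automatically selected region 0.005 ≤ C(r) ≤ 0.5 on a 40-point
geometric radius grid; missing when fewer than five grid points fall in
that region, and a slope near the embedding dimension (noise-like, no
saturation) is logged.

DFA: integrated mean-centred series, per-box linear detrend; α1 over
boxes 4–16 (every integer), α2 over 16–64 (12 log-spaced integers);
α2 requires ≥300 beats.  On white noise the small-box α1 estimate
carries the standard finite-size upward bias (≈0.59 at n = 1000 for
boxes 4–16); the acceptance band (0.5 ± 0.1) reflects this.

Recurrence analysis (embedding 10, delay 1, radius √m·STDNN, Euclidean,
lmin = 2): recurrence rate excludes the main diagonal; determinism is
the share of recurrent points on diagonal lines of length ≥ lmin; mean
and max line length and the Shannon entropy (nats) use the lines ≥ lmin
from both triangles.  All five statistics are verified against a
brute-force matrix construction.

Any measure whose precondition fails (e.g. 2-minute sitting excerpts
are too short for D2 and α2) is NaN with a logged reason — never a
silent zero.

## 4. Robust regression

IRLS with the bisquare ψ, tuning 4.685 (95% Gaussian efficiency),
started from OLS.  Residuals are leverage-adjusted (r/√(1−h), h from
the thin QR of the unweighted design) and scaled by the median of the
n−p largest absolute adjusted residuals divided by 0.6745.  Iteration
stops when no coefficient moves by more than 1e-8 or after 50 sweeps
(both configurable); an exactly-fitting model short-circuits (scale 0,
weights irrelevant).  The intercept is always included.  Rank-deficient
designs are rejected with the collinear columns named.  No standard
errors are produced; the model's uncertainty is assessed by
cross-validation instead.

## 5. Subset selection and evaluation

Every subset of 1..5 candidate features is scored by LOSO
cross-validation: one fold per subject, σ_est computed on the held-out
subject's instances with that fold's own N (N−2 guarded to ≥1 for
folds of ≤2 instances), averaged unweighted across folds.  A pooled
variant (single σ_est over all held-out residuals) is available
(`cv_mode="pooled"`) since either reading of "average test error" is
defensible; per-fold is the default.  Ties break toward the smaller
subset, then lexicographic feature order, so results are independent of
enumeration order.  Subsets that fail to fit (collinearity, missing
values such as an unavailable D2) score +∞ and are logged.  The winner
is refitted on all instances; the report carries test (LOSO mean),
train (mean over folds' training σ_est) and full-fit σ_est, and the
prediction-quality metrics computed on the held-out LOSO predictions:

* %CP: share of |error| *strictly* below the ΔBP measurement error
  (default 4.5 mmHg; an error exactly at the threshold counts as
  incorrect);
* false negatives: predicted < measured − 5 mmHg (drop underestimated);
  false positives: predicted > measured + 5 mmHg.  The 5 mmHg margin is
  deliberately distinct from the 4.5 mmHg %CP threshold; both are
  configurable;
* residual histogram in 2 mmHg bins centred on zero (percentages sum
  to 100).

## 6. Synthetic cohorts

No real recordings are available, so a generator produces cohorts whose
drop *truly* follows a known linear model.  The RR process is

rr_i = μ + a_LF·sin(2π f_LF t_i) + a_HF·sin(2π f_HF t_i) + σ·w_i,

with t_i the cumulative beat time (irregular sampling, as real
autonomic modulation), the simplest process with independently
controllable LF/HF balance and SDNN.  Parameter sets that could produce
non-positive intervals (μ ≤ a_LF + a_HF + 5σ) are rejected.  Default
per-subject ranges — μ 750–950 ms, a_LF 8–25 ms at 0.06–0.12 Hz, a_HF
8–22 ms at 0.18–0.28 Hz, σ 3–10 ms, lying baselines 105–140 / 65–85
mmHg, BP noise 3 mmHg (the device's nominal error) — sit in resting
adult physiology and keep the beat-to-beat step of the smooth
oscillation below the 5% artefact threshold, as in real resting data.
Standing excerpts use μ×0.85, a_HF×0.6, a_LF×1.1 (vagal withdrawal).
Repetitions are distinct autonomic states: amplitudes and σ are scaled
per repetition by deterministic factors within ±20% (±2% for μ),
emulating the drift between repetitions recorded many minutes apart.

Lying BP readings are baseline + N(0, σ_bp).  The second-minute
standing reading is mean(lying readings) + Δ + N(0, σ_bp) with
Δ = c₀ + Σ c_j f_j(lying RR) + N(0, eps_sd); the other standing
readings carry a decaying echo of Δ (factors 1.1/—/0.6/0.3).  The
injected Δ is computed from the lying features *after* the artefact
filter, i.e. from exactly the values the analysis pipeline measures, so
the noiseless cohort admits exact (1e-6 relative) coefficient recovery
end-to-end.  Ground truth (Δ including its ε, systolic and diastolic) is written to
a sidecar CSV.  The default planted model uses coefficients of
published-model magnitude over {RMSSD, NN50, TINN, HF, RPDET} with
eps_sd = 3 mmHg.

All randomness derives from one master seed via per-(subject, phase,
repetition, stream) seed sequences, so cohorts are bit-reproducible and
extensible without reshuffling earlier subjects.

What the generator does **not** emulate: breathing-driven frequency
wander, ectopy and true artefacts, non-stationarity within an excerpt,
baroreflex dynamics, or any mechanistic coupling between HRV and
pressure beyond the planted linear law.  Passing recovery tests
therefore demonstrates the correctness of the pipeline's machinery, not
the physiological validity of the linear model on real subjects.

### A note on planted-subset identifiability

Because every feature of the two-tone process is a smooth function of
six latent subject parameters, small feature subsets can linearly
approximate one another across a 10-subject cohort: the best subset
*not* containing a planted pair typically reaches a residual floor of
≈0.5–0.8 mmHg.  The planted-subset selection test therefore uses a
planted model whose noise (0.25 mmHg) lies below that structural floor,
and per-repetition parameter drift so that instance-level variation is
informative; with noise comparable to the proxy floor, selection
between near-equivalent subsets is genuinely undetermined — a property
of the cohort model, not of the search.

## 7. Problem sizes and defaults in the shipped tests

The test suite exercises the study-scale cohort (10 subjects × 4
repetitions, 40 predictive instances), oracle comparisons on series of
60–200 beats, 200-replicate bias checks, and the reduced 10-feature
exhaustive search (637 subsets × 10 folds × 20 seeds).  The full
22-feature search (35,442 subsets) is supported and its enumeration
count is asserted; the CLI runs it by default (`--candidates` restricts
it, as in the README example).
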
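"""End-to-end orchestration: simulate → preprocess → extract → build →
select/fit → evaluate → report.

Every stage reads and writes the tidy CSV dialects of :mod:`hrvbp.io`,
so stages can be re-run individually; ``run_pipeline`` chains them and
writes a manifest (config hash + seed) making each run reproducible.
All randomness flows from the single configured seed, so a rerun with
the same configuration produces byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io
from .core import FEATURE_NAMES, PHASE_LYING, FeatureConfig
from .dataset import build_predictive_dataset, build_raw_dataset
from .features import extract_features_table
from .preprocess import clean
from .selection import (SelectionResult, exhaustive_search,
                        residual_histogram)
from .features import extract_all
from .synthetic import SyntheticCohort, generate_cohort

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of a full run.

    ``extract_phases`` restricts feature extraction (the predictive
    model only ever uses lying-phase features; extracting all phases
    reproduces the full raw database).
    """

    out_dir: str = "hrvbp_out"
    rr_csv: str | None = None
    bp_csv: str | None = None
    symptom_csv: str | None = None
    simulate: bool = True
    n_subjects: int = 10
    n_reps: int = 4
    seed: int = 0
    artifact_threshold: float = 0.05
    max_k: int = 5
    candidate_features: list[str] | None = None
    outcome: str = "delta_sys"
    error_threshold: float = 4.5
    fpfn_margin: float = 5.0
    cv_mode: str = "per_fold"
    extract_phases: list[int] = field(default_factory=lambda: [1, 2, 3])
    residual_bin_width: float = 2.0
    features: FeatureConfig = field(default_factory=FeatureConfig)

    def __post_init__(self) -> None:
        for name in ("artifact_threshold", "error_threshold", "fpfn_margin",
                     "residual_bin_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.candidate_features is not None:
            bad = set(self.candidate_features) - set(FEATURE_NAMES)
            if bad:
                raise ValueError(f"unknown candidate features: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        feat = raw.pop("features", None)
        cfg = cls(**raw)
        if feat:
            cfg.features = FeatureConfig(**feat)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()


def predictive_from_cohort(cohort: SyntheticCohort,
                           config: FeatureConfig = FeatureConfig(),
                           artifact_threshold: float = 0.05,
                           feature_subset: list[str] | None = None
                           ) -> pd.DataFrame:
    """In-memory shortcut from a synthetic cohort to the predictive
    dataset: artefact-filter the lying excerpts, extract features
    (optionally only the groups covering ``feature_subset``) and pair
    them with the ΔBP outcomes."""
    rows = []
    for s in cohort.rr_series:
        if s.phase_id != PHASE_LYING:
            continue
        feats = extract_all(clean(s, artifact_threshold), config,
                            features=feature_subset)
        rows.append({"sub_id": s.sub_id, "phase_id": s.phase_id,
                     "test_id": s.test_id, **feats.to_dict()})
    table = pd.DataFrame(rows, columns=["sub_id", "phase_id", "test_id",
                                        *FEATURE_NAMES])
    raw = build_raw_dataset(cohort.bp, table, cohort.symptoms)
    return build_predictive_dataset(raw)


def simulate_stage(config: PipelineConfig) -> dict[str, Path]:
    """Generate a synthetic cohort and write RR/BP/symptom/truth CSVs."""
    out = io.ensure_dir(config.out_dir)
    cohort = generate_cohort(
        config.n_subjects, config.n_reps, seed=config.seed,
        config=config.features,
        artifact_threshold=config.artifact_threshold)
    paths = {"rr": out / "rr.csv", "bp": out / "bp.csv",
             "symptoms": out / "symptoms.csv", "truth": out / "truth.csv"}
    io.write_rr_csv(cohort.rr_series, paths["rr"])
    io.write_bp_csv(cohort.bp, paths["bp"])
    io.write_symptom_csv(cohort.symptoms, paths["symptoms"])
    io.write_truth_csv(cohort.truth, paths["truth"])
    log.info("simulate: wrote %d RR excerpts and %d BP readings to %s",
             len(cohort.rr_series), len(cohort.bp), out)
    return paths


def extract_stage(config: PipelineConfig, rr_csv) -> pd.DataFrame:
    """Artefact-filter every excerpt and extract the 22-measure table."""
    series = io.read_rr_csv(rr_csv)
    series = [s for s in series if s.phase_id in config.extract_phases]
    cleaned = [clean(s, config.artifact_threshold) for s in series]
    table = extract_features_table(cleaned, config.features)
    out = io.ensure_dir(config.out_dir) / "features.csv"
    table.to_csv(out, index=False)
    log.info("extract: %d feature rows -> %s", len(table), out)
    return table


def build_stage(config: PipelineConfig, features: pd.DataFrame,
                bp_csv, symptom_csv=None) -> pd.DataFrame:
    """Assemble the predictive dataset CSV."""
    bp = io.read_bp_csv(bp_csv)
    symptoms = io.read_symptom_csv(symptom_csv) if symptom_csv else None
    raw = build_raw_dataset(bp, features, symptoms)
    pred = build_predictive_dataset(raw)
    out = io.ensure_dir(config.out_dir) / "predictive.csv"
    pred.to_csv(out, index=False)
    log.info("build: %d predictive instances -> %s", len(pred), out)
    return pred


def select_stage(config: PipelineConfig, predictive: pd.DataFrame
                 ) -> SelectionResult:
    """Exhaustive subset search + final fit; writes model and report."""
    result = exhaustive_search(
        predictive, max_k=config.max_k,
        candidate_features=config.candidate_features,
        outcome=config.outcome, error_threshold=config.error_threshold,
        margin=config.fpfn_margin, cv_mode=config.cv_mode)
    out = io.ensure_dir(config.out_dir)
    (out / "model.json").write_text(result.model.to_json() + "\n")
    (out / "report.json").write_text(result.report.to_json() + "\n")
    result.report.predictions_frame().to_csv(out / "predictions.csv",
                                             index=False)
    residual_histogram(result.report.residuals,
                       config.residual_bin_width).to_csv(
        out / "residual_histogram.csv", index=False)
    return result


def run_pipeline(config: PipelineConfig) -> SelectionResult:
    """Run every stage and write all artifacts plus the run manifest."""
    out = io.ensure_dir(config.out_dir)
    if config.simulate:
        paths = simulate_stage(config)
        rr_csv, bp_csv = paths["rr"], paths["bp"]
        symptom_csv = paths["symptoms"]
    else:
        if not config.rr_csv or not config.bp_csv:
            raise ValueError("rr_csv and bp_csv required when simulate=False")
        rr_csv, bp_csv = config.rr_csv, config.bp_csv
        symptom_csv = config.symptom_csv
    features = extract_stage(config, rr_csv)
    lying = features[features["phase_id"] == PHASE_LYING]
    if lying[list(FEATURE_NAMES)].isna().all(axis=None):
        raise ValueError("no lying-phase features could be extracted")
    predictive = build_stage(config, features, bp_csv, symptom_csv)
    result = select_stage(config, predictive)
    manifest = {"config": config.to_dict(), "config_sha256": config.digest(),
                "seed": config.seed,
                "n_predictive_instances": int(len(predictive)),
                "n_subsets_evaluated": result.n_subsets_evaluated}
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return result
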
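"""End-to-end experiment orchestration.

``run_experiment`` executes the whole analysis on synthetic data: simulate
the ambulatory cohort, train stage 2 (MAP -> SBP/DBP), calibrate the PPG
ground truth and simulate the paired usability protocol, train stage 1
(PPG -> MAP), run the two-stage cascade on the paired records, and emit the
validation report plus per-participant and continuous-monitoring summaries.

Two evaluation protocols are reported side by side: ``in_sample`` scores the
cascade on all paired records (training data included — the historical
single-session protocol), and ``held_out`` restricts scoring to stage 1's
test split. Artifacts are deterministic functions of the configuration and
global seed; no timestamps are written into report files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import Schedule, average_real_variability, write_recordings
from .metrics import ValidationReport, evaluate_predictions, per_participant_report
from .network import (
    CombinatorialModel,
    TrainConfig,
    fit_stage1_ppg_to_map,
    fit_stage2_map_to_bp,
)
from .simulate import (
    CohortSpec,
    GroundTruthMap,
    ProtocolSpec,
    calibrate_ground_truth,
    simulate_cohort,
    simulate_protocol,
    write_paired,
)

__all__ = [
    "TruthSpec",
    "ExperimentConfig",
    "RunManifest",
    "run_experiment",
    "continuous_monitoring_summary",
    "load_config",
]

log = logging.getLogger("ppgbp")


@dataclass(frozen=True)
class TruthSpec:
    """Calibration targets and noise for the PPG ground-truth map."""

    target_ppg_mean: float = 4100.7
    target_ppg_sd: float = 107.7
    noise_sd: float = 50.0
    curvature: float = 0.3
    map_dist_mean: float = 88.9
    map_dist_sd: float = 16.1

    def calibrate(self, n_avg: int) -> GroundTruthMap:
        return calibrate_ground_truth(
            self.target_ppg_mean,
            self.target_ppg_sd,
            (self.map_dist_mean, self.map_dist_sd),
            noise_sd=self.noise_sd,
            n_avg=n_avg,
            curvature=self.curvature,
        )


@dataclass(frozen=True)
class ExperimentConfig:
    """Full experiment configuration; the global seed drives all sub-seeds."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)
    truth: TruthSpec = field(default_factory=TruthSpec)
    stage1_train: TrainConfig = field(default_factory=TrainConfig)
    stage2_train: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build(cls, section: str, d: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown keys in '{section}' config: {sorted(unknown)}")
    kwargs = dict(d)
    if "schedule" in kwargs and isinstance(kwargs["schedule"], dict):
        kwargs["schedule"] = Schedule(**kwargs["schedule"])
    for key in ("rounds", "split_fractions"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)


def config_from_dict(d: dict) -> ExperimentConfig:
    """Build an ExperimentConfig from a nested dict; unknown keys rejected."""
    sections = {
        "cohort": CohortSpec,
        "protocol": ProtocolSpec,
        "truth": TruthSpec,
        "stage1_train": TrainConfig,
        "stage2_train": TrainConfig,
    }
    unknown = set(d) - set(sections) - {"seed"}
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs = {
        name: _build(cls, name, d.get(name, {})) for name, cls in sections.items()
    }
    return ExperimentConfig(seed=int(d.get("seed", 0)), **kwargs)


def load_config(path) -> ExperimentConfig:
    """Load a YAML or JSON experiment configuration file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError("experiment config must be a mapping")
    return config_from_dict(doc)


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic sub-seeds (< 2^31) spawned from the global seed."""
    return [
        int(child.generate_state(1)[0] % 2**31)
        for child in np.random.SeedSequence(seed).spawn(n)
    ]


@dataclass
class RunManifest:
    """Record of one experiment run: config snapshot, seeds, artifact paths."""

    config: dict
    sub_seeds: dict
    artifacts: dict
    stop_reasons: dict
    version: str = __version__

    def to_json(self, path=None) -> str:
        doc = {
            "version": self.version,
            "config": self.config,
            "sub_seeds": self.sub_seeds,
            "stop_reasons": self.stop_reasons,
            "artifacts": self.artifacts,
        }
        text = json.dumps(doc, indent=1, sort_keys=True, default=str)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def continuous_monitoring_summary(frame: pd.DataFrame) -> dict:
    """Mean BP level and ARV of each subject's predicted series.

    Expects columns participant, sbp_pred, dbp_pred, map_pred, ordered as
    the readings were taken. Requires >= 2 predictions per subject.
    """
    required = {"participant", "sbp_pred", "dbp_pred", "map_pred"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"monitoring table missing columns: {sorted(missing)}")
    out: dict[str, dict] = {}
    for pid, grp in frame.groupby("participant", sort=True):
        if len(grp) < 2:
            raise ValueError(
                f"participant {pid}: variability needs at least two predictions"
            )
        out[str(pid)] = {
            quantity: {
                "mean": float(grp[col].mean()),
                "arv": average_real_variability(grp[col].to_numpy()),
            }
            for quantity, col in (
                ("sbp", "sbp_pred"),
                ("dbp", "dbp_pred"),
                ("map", "map_pred"),
            )
        }
    return out


def run_experiment(
    config: ExperimentConfig, outdir
) -> tuple[RunManifest, dict[str, ValidationReport]]:
    """Execute the full pipeline and write all artifacts under ``outdir``.

    Returns the manifest and the validation reports keyed by protocol
    (``in_sample`` over all paired records, ``held_out`` over stage 1's test
    split).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort_seed, protocol_seed, s1_seed, s2_seed = _child_seeds(config.seed, 4)
    cohort_spec = dataclasses.replace(config.cohort, seed=cohort_seed)
    protocol_spec = dataclasses.replace(config.protocol, seed=protocol_seed)
    stage1_cfg = dataclasses.replace(config.stage1_train, seed=s1_seed)
    stage2_cfg = dataclasses.replace(config.stage2_train, seed=s2_seed)
    artifacts: dict[str, str] = {}

    def _save(name: str, path: Path) -> Path:
        artifacts[name] = path.name  # relative to outdir, keeps runs comparable
        return path

    t0 = time.perf_counter()
    recordings, pooled = simulate_cohort(cohort_spec)
    log.info(
        "cohort: %d/%d subjects pass quality filter, %d pooled readings (%.2fs)",
        pooled.subject_id.nunique(), cohort_spec.n_subjects, len(pooled),
        time.perf_counter() - t0,
    )
    write_recordings(recordings, _save("recordings", outdir / "recordings.csv"),
                     seed=cohort_seed)
    with open(_save("cohort", outdir / "cohort.csv"), "w") as fh:
        fh.write(f"# seed={cohort_seed}\n")
        pooled.to_csv(fh, index=False)

    t0 = time.perf_counter()
    stage2, rec2 = fit_stage2_map_to_bp(pooled, stage2_cfg)
    log.info("stage 2 (MAP->BP): %d epochs, stop=%s (%.2fs)",
             rec2.n_epochs, rec2.stop_reason, time.perf_counter() - t0)
    stage2.to_json(_save("stage2_model", outdir / "stage2.json"),
                   seed=s2_seed, stop_reason=rec2.stop_reason)

    truth = config.truth.calibrate(n_avg=protocol_spec.raw_samples_per_record)
    paired = simulate_protocol(protocol_spec, truth, cohort_spec.structure())
    log.info("protocol: %d paired records from %d participants",
             len(paired), protocol_spec.n_participants)
    write_paired(paired, _save("paired", outdir / "paired.csv"), seed=protocol_seed)

    t0 = time.perf_counter()
    stage1, rec1 = fit_stage1_ppg_to_map(paired, stage1_cfg)
    log.info("stage 1 (PPG->MAP): %d epochs, stop=%s (%.2fs)",
             rec1.n_epochs, rec1.stop_reason, time.perf_counter() - t0)
    stage1.to_json(_save("stage1_model", outdir / "stage1.json"),
                   seed=s1_seed, stop_reason=rec1.stop_reason)

    model = CombinatorialModel(stage1, stage2)
    model.to_json(_save("combinatorial_model", outdir / "model.json"))

    sbp_hat, dbp_hat, map_hat = model.predict_bp(paired.ppg.to_numpy())
    predictions = paired.assign(sbp_pred=sbp_hat, dbp_pred=dbp_hat, map_pred=map_hat)
    predictions = predictions.rename(columns={"sbp": "sbp_ref", "dbp": "dbp_ref"})
    with open(_save("predictions", outdir / "predictions.csv"), "w") as fh:
        fh.write(f"# seed={config.seed}\n")
        predictions.to_csv(fh, index=False)

    reports: dict[str, ValidationReport] = {}
    subsets = {
        "in_sample": predictions,
        "held_out": predictions.iloc[np.sort(rec1.test_idx)],
    }
    for label, subset in subsets.items():
        report = evaluate_predictions(
            subset.sbp_ref, subset.sbp_pred, subset.dbp_ref, subset.dbp_pred,
            label=label,
        )
        reports[label] = report
        report.to_json(_save(f"report_{label}", outdir / f"report_{label}.json"))
        md_path = _save(f"report_{label}_md", outdir / f"report_{label}.md")
        with open(md_path, "w") as fh:
            fh.write(report.to_markdown())
        for quantity in ("sbp", "dbp"):
            points = getattr(report, quantity).ba_points
            points.to_csv(
                _save(f"bland_altman_{quantity}_{label}",
                      outdir / f"bland_altman_{quantity}_{label}.csv"),
                index=False,
            )

    per_part = per_participant_report(predictions)
    per_part.to_csv(_save("per_participant", outdir / "per_participant.csv"),
                    index=False)

    monitoring = continuous_monitoring_summary(predictions)
    with open(_save("monitoring", outdir / "monitoring_summary.json"), "w") as fh:
        json.dump(monitoring, fh, indent=1, sort_keys=True)
        fh.write("\n")

    manifest = RunManifest(
        config=config.to_dict(),
        sub_seeds={
            "cohort": cohort_seed, "protocol": protocol_seed,
            "stage1": s1_seed, "stage2": s2_seed,
        },
        artifacts=artifacts,
        stop_reasons={"stage1": rec1.stop_reason, "stage2": rec2.stop_reason},
    )
    manifest.to_json(outdir / "manifest.json")
    missing = [p for p in artifacts.values() if not (outdir / p).exists()]
    if missing:  # pragma: no cover - defensive
        raise RuntimeError(f"manifest lists missing artifacts: {missing}")
    return manifest, reports
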
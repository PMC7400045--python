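"""Synthetic data generators for the two acquisition protocols.

Two study designs are emulated from a known ground truth so that every
downstream stage (network training, combinatorial prediction, validation
statistics) is testable without access to clinical data:

* a cohort of 24-hour ambulatory BP recordings on a 15-min-day / 30-min-night
  schedule, pooled into a MAP -> (SBP, DBP) fitting table after the
  >70 %-valid-readings quality filter; and
* a seated usability protocol in which an optical (PPG) sensor samples light
  absorption every 0.6 s for 30 s alongside a reference oscillometric cuff,
  in three rounds targeting 20, 20 and 10 valid records per participant.

The generative model is driven by a latent mean arterial pressure (MAP):
DBP is affine in MAP plus residual pulse-pressure scatter, and SBP is then
fixed by the identity SBP = 3*MAP - 2*DBP, so the MAP column of every pooled
table satisfies MAP = (2*DBP + SBP)/3 exactly. The affine coefficients and
residual SD are solved in closed form from the target pooled moments (see
``bp_structure``). Day-night structure, AR(1) reading-to-reading
autocorrelation and random invalid readings mimic ambulatory data; the PPG
ground truth is a strictly monotone (affine plus mild tanh saturation) map
from MAP to mean light-absorption level, calibrated to target PPG moments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    AmbulatoryRecording,
    BPReading,
    PairedObservation,
    Schedule,
    compute_map,
    passes_quality,
)

__all__ = [
    "BPStructure",
    "bp_structure",
    "CohortSpec",
    "ProtocolSpec",
    "GroundTruthMap",
    "calibrate_ground_truth",
    "simulate_ambulatory_recording",
    "simulate_cohort",
    "simulate_ppg_session",
    "simulate_protocol",
]

#: minimum plausible pulse pressure (mmHg); residual scatter is truncated so
#: SBP - DBP never falls below this.
MIN_PULSE_PRESSURE = 10.0


@dataclass(frozen=True)
class BPStructure:
    """Affine structural relation DBP = intercept + slope*MAP (+ scatter)."""

    map_mean: float
    map_sd: float
    dbp_intercept: float
    dbp_slope: float
    resid_sd: float

    def dbp_given_map(self, map_values: np.ndarray) -> np.ndarray:
        return self.dbp_intercept + self.dbp_slope * np.asarray(map_values, float)


def bp_structure(
    sbp_mean: float = 131.1,
    sbp_sd: float = 21.4,
    dbp_mean: float = 74.9,
    dbp_sd: float = 14.4,
    map_sd: float = 15.3,
) -> BPStructure:
    """Solve the latent-MAP structural model from pooled moments.

    With MAP ~ (mean m, variance V), DBP = a + b*MAP + eps and
    SBP = 3*MAP - 2*DBP, matching Var(DBP) and Var(SBP) gives

        b = (9V - (Var(SBP) - 4*Var(DBP))) / (12V),
        Var(eps) = Var(DBP) - b^2 * V.

    The MAP mean is taken Eq-2-consistent, m = (2*dbp_mean + sbp_mean)/3.
    """
    if min(sbp_sd, dbp_sd, map_sd) <= 0:
        raise ValueError("all SDs must be positive")
    map_mean = (2.0 * dbp_mean + sbp_mean) / 3.0
    v = map_sd**2
    slope = (9.0 * v - (sbp_sd**2 - 4.0 * dbp_sd**2)) / (12.0 * v)
    resid_var = dbp_sd**2 - slope**2 * v
    if resid_var < 0 or not 0 < slope < 1.5:
        raise ValueError(
            "pooled moments are mutually inconsistent with the affine DBP|MAP model"
        )
    return BPStructure(map_mean, map_sd, dbp_mean - slope * map_mean, slope,
                       math.sqrt(resid_var))


def _sample_bp(
    rng: np.random.Generator,
    map_latent: np.ndarray,
    structure: BPStructure,
    resid_sd: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (SBP, DBP) around the structural conditional mean.

    Residual pulse-pressure scatter is truncated so SBP - DBP stays above
    MIN_PULSE_PRESSURE (SBP > DBP by construction).
    """
    map_latent = np.asarray(map_latent, float)
    eps = rng.normal(0.0, resid_sd, map_latent.shape) if resid_sd > 0 else 0.0
    dbp = structure.dbp_given_map(map_latent) + eps
    # PP = 3*(MAP - DBP); cap DBP so the pulse pressure keeps a floor
    dbp = np.minimum(dbp, map_latent - MIN_PULSE_PRESSURE / 3.0)
    dbp = np.maximum(dbp, 1.0)
    sbp = 3.0 * map_latent - 2.0 * dbp
    return sbp, dbp


# ---------------------------------------------------------------------------
# ambulatory cohort


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for the ambulatory cohort generator.

    Pooled calibration targets default to 131.1 (21.4) mmHg systolic,
    74.9 (14.4) diastolic and a 15.3 mmHg pooled MAP SD. The latent MAP of
    each subject splits its variance between a stable subject level, an
    AR(1) within-subject process, and the day-night dip.
    """

    n_subjects: int = 50
    sbp_mean: float = 131.1
    sbp_sd: float = 21.4
    dbp_mean: float = 74.9
    dbp_sd: float = 14.4
    map_sd: float = 15.3
    nocturnal_dip_fraction: float = 0.10
    ar1_rho: float = 0.6
    invalid_prob: float = 0.10
    between_subject_frac: float = 0.65
    pulse_scatter_sd: float | None = None  # None -> solved from the pooled SDs
    schedule: Schedule = field(default_factory=Schedule)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0.0 <= self.nocturnal_dip_fraction <= 0.3:
            raise ValueError("nocturnal_dip_fraction must lie in [0, 0.3]")
        if not 0.0 <= self.ar1_rho < 1.0:
            raise ValueError("ar1_rho must lie in [0, 1)")
        if not 0.0 <= self.invalid_prob <= 1.0:
            raise ValueError("invalid_prob must lie in [0, 1]")
        if not 0.0 < self.between_subject_frac < 1.0:
            raise ValueError("between_subject_frac must lie in (0, 1)")

    def structure(self) -> BPStructure:
        return bp_structure(self.sbp_mean, self.sbp_sd, self.dbp_mean,
                            self.dbp_sd, self.map_sd)


def _cohort_levels(spec: CohortSpec) -> tuple[float, float, float]:
    """(daytime MAP level, between-subject SD, within-subject SD).

    The daytime level is calibrated so the pooled latent MAP mean over the
    day/night slot mix equals the structural MAP mean despite the dip, and
    the dip's between-window variance is subtracted from the total before
    splitting the remainder between and within subjects.
    """
    structure = spec.structure()
    slots = spec.schedule.slots()
    n_day = sum(spec.schedule.is_day(t) for t in slots)
    n_night = len(slots) - n_day
    w_day = n_day / len(slots)
    w_night = n_night / len(slots)
    dip = spec.nocturnal_dip_fraction
    day_level = structure.map_mean / (w_day + w_night * (1.0 - dip))
    dip_var = w_day * w_night * (day_level * dip) ** 2
    remaining = structure.map_sd**2 - dip_var
    if remaining <= 0:
        raise ValueError("nocturnal dip alone exceeds the target MAP variance")
    between_sd = math.sqrt(spec.between_subject_frac * remaining)
    within_sd = math.sqrt((1.0 - spec.between_subject_frac) * remaining)
    return day_level, between_sd, within_sd


def simulate_ambulatory_recording(
    spec: CohortSpec,
    subject_id: str,
    subject_index: int = 0,
    base_level: float | None = None,
) -> AmbulatoryRecording:
    """One subject's 24-hour recording on the day/night schedule.

    The default schedule yields 68 daytime + 14 nighttime = 82 scheduled
    readings. Each reading is independently invalid with ``invalid_prob``
    (invalid readings keep their measured values but are excluded from
    pooled tables). ``base_level`` pins the subject's daytime MAP level;
    when None it is drawn from the cohort's between-subject distribution.
    """
    rng = np.random.default_rng([spec.seed, subject_index])
    structure = spec.structure()
    day_level, between_sd, within_sd = _cohort_levels(spec)
    resid_sd = (
        structure.resid_sd if spec.pulse_scatter_sd is None else spec.pulse_scatter_sd
    )

    base = rng.normal(day_level, between_sd) if base_level is None else base_level
    slots = spec.schedule.slots()
    rho = spec.ar1_rho
    dev = rng.normal(0.0, within_sd)
    readings: list[BPReading] = []
    for t in slots:
        level = base if spec.schedule.is_day(t) else base * (1.0 - spec.nocturnal_dip_fraction)
        map_latent = max(level + dev, 40.0)
        sbp, dbp = _sample_bp(rng, np.array([map_latent]), structure, resid_sd)
        valid = bool(rng.random() >= spec.invalid_prob)
        readings.append(BPReading(t, float(sbp[0]), float(dbp[0]), valid))
        dev = rho * dev + math.sqrt(1.0 - rho**2) * rng.normal(0.0, within_sd)
    return AmbulatoryRecording(subject_id, readings, spec.schedule)


def simulate_cohort(
    spec: CohortSpec,
) -> tuple[list[AmbulatoryRecording], pd.DataFrame]:
    """Simulate the cohort and pool the valid readings of passing subjects.

    Returns all simulated recordings plus the pooled table (columns
    subject_id, timestamp_min, sbp, dbp, map) restricted to recordings that
    pass the strict >70 %-valid quality filter. The MAP column is Eq 2
    applied row-wise.

    Subject daytime levels are drawn once at the cohort level and
    standardized to the exact between-subject mean and SD (a variance
    reduction that keeps the pooled moments on their calibration targets at
    modest cohort sizes); all within-subject structure stays random.
    """
    day_level, between_sd, _ = _cohort_levels(spec)
    level_rng = np.random.default_rng([spec.seed, 2**32 - 1])
    z = level_rng.normal(size=spec.n_subjects)
    if spec.n_subjects > 1:
        z = (z - z.mean()) / max(z.std(), 1e-12)
    else:
        z = np.zeros(1)
    bases = day_level + between_sd * z
    recordings = [
        simulate_ambulatory_recording(spec, f"S{i:04d}", i, base_level=bases[i])
        for i in range(spec.n_subjects)
    ]
    passing = [rec for rec in recordings if passes_quality(rec)]
    if not passing:
        raise ValueError(
            "all subjects excluded by the >70% valid-readings quality filter"
        )
    rows = [
        (rec.subject_id, r.timestamp, r.sbp, r.dbp, compute_map(r.sbp, r.dbp))
        for rec in passing
        for r in rec.valid_readings()
    ]
    pooled = pd.DataFrame(
        rows, columns=["subject_id", "timestamp_min", "sbp", "dbp", "map"]
    )
    return recordings, pooled


# ---------------------------------------------------------------------------
# PPG ground truth


@dataclass(frozen=True)
class GroundTruthMap:
    """Strictly monotone MAP (mmHg) -> mean PPG level (a.u.) relation.

    g(m) = intercept + slope * h(m) with
    h(m) = m + curvature * width * tanh((m - center) / width): affine with a
    mild saturation; strictly monotone for curvature > -1 and slope != 0.
    ``noise_sd`` is the SD of a single raw light-absorption sample around
    g(MAP).
    """

    intercept: float
    slope: float
    noise_sd: float = 50.0
    curvature: float = 0.3
    center: float = 90.0
    width: float = 40.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.curvature <= -1.0 or self.slope == 0.0:
            raise ValueError("ground-truth map must be strictly monotone")

    def shape(self, map_values) -> np.ndarray:
        m = np.asarray(map_values, float)
        return m + self.curvature * self.width * np.tanh((m - self.center) / self.width)

    def mean_response(self, map_values) -> np.ndarray:
        """Noise-free PPG level g(MAP)."""
        return self.intercept + self.slope * self.shape(map_values)


def calibrate_ground_truth(
    target_ppg_mean: float = 4100.7,
    target_ppg_sd: float = 107.7,
    map_distribution: tuple[float, float] | Sequence[float] = (88.9, 16.1),
    noise_sd: float = 50.0,
    n_avg: int = 50,
    curvature: float = 0.3,
    center: float = 90.0,
    width: float = 40.0,
) -> GroundTruthMap:
    """Fit (intercept, slope) so simulated averaged PPG matches the targets.

    ``map_distribution`` is either (mean, sd) of a Normal MAP distribution
    (moments of the saturating shape are then taken by Gauss-Hermite
    quadrature) or an explicit array of MAP values (empirical moments).
    The variance contributed by averaging ``n_avg`` raw samples of noise is
    subtracted from the target variance before solving, so the calibration
    targets refer to the per-record averaged PPG value.
    """
    if target_ppg_mean <= 0 or target_ppg_sd <= 0:
        raise ValueError("PPG calibration targets must be positive")
    proto = GroundTruthMap(0.0, 1.0, noise_sd, curvature, center, width)
    dist = np.asarray(map_distribution, float)
    if dist.shape == (2,):
        mu, sd = dist
        if sd <= 0:
            raise ValueError("MAP distribution must have positive spread")
        nodes, weights = np.polynomial.hermite_e.hermegauss(64)
        m = mu + sd * nodes
        w = weights / weights.sum()
        h = proto.shape(m)
        h_mean = float(w @ h)
        h_sd = math.sqrt(float(w @ (h - h_mean) ** 2))
    else:
        h = proto.shape(dist)
        if h.size < 2 or float(np.std(h)) == 0.0:
            raise ValueError("MAP distribution must have positive spread")
        h_mean = float(np.mean(h))
        h_sd = float(np.std(h))
    signal_var = target_ppg_sd**2 - noise_sd**2 / max(n_avg, 1)
    if signal_var <= 0:
        raise ValueError(
            f"cannot reach PPG SD {target_ppg_sd} a.u.: averaged noise alone exceeds it"
        )
    slope = math.sqrt(signal_var) / h_sd
    intercept = target_ppg_mean - slope * h_mean
    return GroundTruthMap(intercept, slope, noise_sd, curvature, center, width)


# ---------------------------------------------------------------------------
# usability protocol (paired PPG / reference BP sessions)


@dataclass(frozen=True)
class ProtocolSpec:
    """Study conditions for the seated paired-measurement protocol.

    Defaults mirror a three-participant single-session design with rounds
    targeting 20, 20 and 10 valid records (50 per participant), readings
    every 5 minutes, and a 30 s PPG acquisition window sampled every 0.6 s.
    The reference cuff contributes independent Gaussian noise (SD 1.5 mmHg,
    within a +/-3 mmHg device accuracy) to the recorded SBP and DBP.
    """

    n_participants: int = 3
    rounds: tuple[int, ...] = (20, 20, 10)
    reading_interval_min: float = 5.0
    ppg_sample_period_s: float = 0.6
    acquisition_window_s: float = 30.0
    map_mean: float = 88.9
    map_between_sd: float = 15.0
    map_walk_sd: float = 1.2
    device_noise_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not self.rounds or any(r <= 0 for r in self.rounds):
            raise ValueError("round targets must be positive")
        if self.ppg_sample_period_s <= 0 or self.acquisition_window_s <= 0:
            raise ValueError("PPG timing parameters must be positive")
        if self.device_noise_sd < 0:
            raise ValueError("device_noise_sd must be nonnegative")

    @property
    def records_per_participant(self) -> int:
        return int(sum(self.rounds))

    @property
    def raw_samples_per_record(self) -> int:
        return int(self.acquisition_window_s // self.ppg_sample_period_s)


def simulate_ppg_session(
    spec: ProtocolSpec,
    truth: GroundTruthMap,
    participant_index: int = 0,
    structure: BPStructure | None = None,
) -> list[PairedObservation]:
    """One participant's session of paired PPG / reference BP records.

    The participant's true MAP follows a slow random walk around an
    individual baseline across the session's rounds. Each record averages
    floor(window / period) raw light-absorption samples g(MAP) + noise after
    discarding nonpositive samples (a record whose samples are all
    nonpositive is regenerated); the reference SBP/DBP carry device noise,
    and the paired MAP is Eq 2 applied to the recorded values.
    """
    if structure is None:
        structure = bp_structure()
    rng = np.random.default_rng([spec.seed, participant_index])
    n_raw = spec.raw_samples_per_record
    base = rng.normal(spec.map_mean, spec.map_between_sd)
    map_true = base
    records: list[PairedObservation] = []
    for target in spec.rounds:
        for _ in range(target):
            map_true += rng.normal(0.0, spec.map_walk_sd)
            map_now = min(max(map_true, 55.0), 140.0)
            dbp_true = float(structure.dbp_given_map(map_now))
            dbp_true = min(dbp_true, map_now - MIN_PULSE_PRESSURE / 3.0)
            sbp_true = 3.0 * map_now - 2.0 * dbp_true
            # reference cuff reading with device noise; SBP > DBP enforced
            for _attempt in range(100):
                sbp_ref = sbp_true + rng.normal(0.0, spec.device_noise_sd)
                dbp_ref = dbp_true + rng.normal(0.0, spec.device_noise_sd)
                if sbp_ref > dbp_ref > 0:
                    break
            else:  # pragma: no cover - unreachable at realistic pressures
                raise RuntimeError("could not draw an ordered reference reading")
            ppg = _acquire_ppg(rng, truth, map_now, n_raw)
            records.append(
                PairedObservation(
                    ppg=ppg, sbp=sbp_ref, dbp=dbp_ref,
                    map=compute_map(sbp_ref, dbp_ref),
                )
            )
    return records


def _acquire_ppg(
    rng: np.random.Generator, truth: GroundTruthMap, map_now: float, n_raw: int
) -> float:
    """Average the positive raw samples; regenerate if none are positive."""
    level = float(truth.mean_response(map_now))
    for _attempt in range(100):
        raw = level + rng.normal(0.0, truth.noise_sd, n_raw)
        positive = raw[raw > 0]
        if positive.size:
            return float(positive.mean())
    raise RuntimeError(
        "PPG acquisition produced no positive samples in 100 attempts; "
        "the ground-truth calibration is implausible"
    )


def simulate_protocol(
    spec: ProtocolSpec,
    truth: GroundTruthMap,
    structure: BPStructure | None = None,
) -> pd.DataFrame:
    """All participants' sessions as one paired table.

    Columns: participant, record (within-participant index), round, ppg,
    sbp, dbp, map. Round boundaries follow the spec's valid-record targets.
    """
    round_of = [
        r for r, target in enumerate(spec.rounds) for _ in range(target)
    ]
    rows = []
    for p in range(spec.n_participants):
        session = simulate_ppg_session(spec, truth, p, structure)
        for k, obs in enumerate(session):
            rows.append(
                (f"P{p}", k, round_of[k], obs.ppg, obs.sbp, obs.dbp, obs.map)
            )
    return pd.DataFrame(
        rows, columns=["participant", "record", "round", "ppg", "sbp", "dbp", "map"]
    )


def write_paired(frame: pd.DataFrame, path, seed: int | None = None) -> None:
    """Write a paired PPG/BP table as CSV with the seed in a header comment."""
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        frame.to_csv(fh, index=False)


def read_paired(path) -> pd.DataFrame:
    frame = pd.read_csv(path, comment="#")
    missing = {"ppg", "sbp", "dbp", "map"} - set(frame.columns)
    if missing:
        raise ValueError(f"paired table missing columns: {sorted(missing)}")
    return frame
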
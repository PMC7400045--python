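"""Device-validation statistics for BP prediction.

Implements the full protocol used to judge a cuffless monitor against a
reference device: mean error and SD of the differences, Pearson and
Spearman correlations, percentage accuracy, cumulative percentages of
absolute errors within 5/10/15 mmHg, the AAMI pass/fail criterion
(|ME| <= 5 mmHg and SD <= 8 mmHg), the BHS A-D accuracy grade, and
Bland-Altman limits of agreement.

Sign convention throughout: differences are reference - predicted, so a
negative mean error means the monitor over-estimates on average. All
threshold comparisons are inclusive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ErrorSummary",
    "ValidationReport",
    "error_summary",
    "percentage_accuracy",
    "cumulative_within",
    "aami_check",
    "bhs_grade",
    "bland_altman",
    "correlations",
    "evaluate_predictions",
    "per_participant_report",
    "BHS_THRESHOLDS",
    "AAMI_ME_LIMIT",
    "AAMI_SD_LIMIT",
]

AAMI_ME_LIMIT = 5.0
AAMI_SD_LIMIT = 8.0

#: BHS grading table: cumulative % of absolute errors within 5/10/15 mmHg
#: required for each grade; all three must be met (inclusive). Anything
#: below grade C is D.
BHS_THRESHOLDS: dict[str, tuple[float, float, float]] = {
    "A": (60.0, 85.0, 95.0),
    "B": (50.0, 75.0, 90.0),
    "C": (40.0, 65.0, 85.0),
}


def _paired(reference, predicted, min_n: int = 2) -> tuple[np.ndarray, np.ndarray]:
    ref = np.asarray(reference, float).ravel()
    pred = np.asarray(predicted, float).ravel()
    if ref.size != pred.size:
        raise ValueError(f"length mismatch: {ref.size} reference vs {pred.size} predicted")
    if ref.size < min_n:
        raise ValueError(f"need at least {min_n} paired values, got {ref.size}")
    if not (np.all(np.isfinite(ref)) and np.all(np.isfinite(pred))):
        raise ValueError("paired series must be finite")
    return ref, pred


@dataclass(frozen=True)
class ErrorSummary:
    """Mean error (reference - predicted), its sample SD, and the count."""

    me: float
    sd: float
    n: int


def error_summary(reference, predicted) -> ErrorSummary:
    ref, pred = _paired(reference, predicted)
    d = ref - pred
    return ErrorSummary(float(d.mean()), float(d.std(ddof=1)), int(d.size))


def percentage_accuracy(reference, predicted) -> float:
    """Mean of (1 - |ref - pred| / ref) * 100 over all pairs.

    At most 100 (equality iff prediction is perfect); can go negative when
    an error exceeds its reference value. Requires strictly positive
    references.
    """
    ref, pred = _paired(reference, predicted, min_n=1)
    if np.any(ref <= 0):
        raise ValueError("percentage accuracy requires positive reference values")
    return float(np.mean((1.0 - np.abs(ref - pred) / ref) * 100.0))


def cumulative_within(
    reference, predicted, thresholds=(5.0, 10.0, 15.0)
) -> tuple[float, ...]:
    """Percentage of absolute differences within each threshold (inclusive)."""
    ref, pred = _paired(reference, predicted, min_n=1)
    err = np.abs(ref - pred)
    return tuple(float(np.mean(err <= t) * 100.0) for t in thresholds)


def aami_check(summary: ErrorSummary) -> tuple[bool, list[str]]:
    """AAMI verdict: |ME| <= 5 mmHg and SD <= 8 mmHg (inclusive bounds).

    Returns (passed, reasons); reasons name any violated bound.
    """
    reasons = []
    if abs(summary.me) > AAMI_ME_LIMIT:
        reasons.append(
            f"|mean error| {abs(summary.me):.2f} mmHg exceeds {AAMI_ME_LIMIT} mmHg"
        )
    if summary.sd > AAMI_SD_LIMIT:
        reasons.append(f"error SD {summary.sd:.2f} mmHg exceeds {AAMI_SD_LIMIT} mmHg")
    return (not reasons, reasons)


def bhs_grade(cum5: float, cum10: float, cum15: float) -> str:
    """BHS accuracy grade from the cumulative 5/10/15 mmHg percentages."""
    for p in (cum5, cum10, cum15):
        if not 0.0 <= p <= 100.0:
            raise ValueError("cumulative percentages must lie in [0, 100]")
    if not cum5 <= cum10 <= cum15:
        raise ValueError("cumulative percentages must be nondecreasing in the threshold")
    for grade in ("A", "B", "C"):
        t5, t10, t15 = BHS_THRESHOLDS[grade]
        if cum5 >= t5 and cum10 >= t10 and cum15 >= t15:
            return grade
    return "D"


def bland_altman(reference, predicted, multiplier: float = 1.96):
    """Bland-Altman agreement: bias, limits of agreement, and plot points.

    Differences are reference - predicted; limits are bias +/- 1.96*SD by
    default. Returns (bias, loa_lower, loa_upper, points) where points is a
    DataFrame of (mean, difference) pairs for plotting.
    """
    ref, pred = _paired(reference, predicted)
    d = ref - pred
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    points = pd.DataFrame({"mean": (ref + pred) / 2.0, "difference": d})
    return bias, bias - multiplier * sd, bias + multiplier * sd, points


def correlations(reference, predicted) -> tuple[float, float]:
    """(Pearson, Spearman) correlation; Spearman uses average ranks for ties."""
    ref, pred = _paired(reference, predicted, min_n=3)
    if np.std(ref) == 0 or np.std(pred) == 0:
        raise ValueError("correlation undefined for zero-variance series")
    pearson = float(stats.pearsonr(ref, pred).statistic)
    spearman = float(stats.spearmanr(ref, pred).statistic)
    return pearson, spearman


# ---------------------------------------------------------------------------
# full report


@dataclass
class QuantityReport:
    """All validation metrics for one BP quantity (SBP or DBP)."""

    summary: ErrorSummary
    pearson: float
    spearman: float
    accuracy_pct: float
    cum5: float
    cum10: float
    cum15: float
    aami_pass: bool
    aami_reasons: list[str]
    bhs: str
    ba_bias: float
    ba_lower: float
    ba_upper: float
    ba_points: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "n": self.summary.n,
            "mean_error_mmHg": self.summary.me,
            "error_sd_mmHg": self.summary.sd,
            "pearson": self.pearson,
            "spearman": self.spearman,
            "accuracy_pct": self.accuracy_pct,
            "cumulative_pct_within": {"5": self.cum5, "10": self.cum10, "15": self.cum15},
            "aami_pass": self.aami_pass,
            "aami_reasons": self.aami_reasons,
            "bhs_grade": self.bhs,
            "bland_altman": {
                "bias": self.ba_bias,
                "loa_lower": self.ba_lower,
                "loa_upper": self.ba_upper,
            },
        }


def evaluate_quantity(reference, predicted) -> QuantityReport:
    summary = error_summary(reference, predicted)
    pearson, spearman = correlations(reference, predicted)
    cum5, cum10, cum15 = cumulative_within(reference, predicted)
    passed, reasons = aami_check(summary)
    bias, lower, upper, points = bland_altman(reference, predicted)
    return QuantityReport(
        summary=summary,
        pearson=pearson,
        spearman=spearman,
        accuracy_pct=percentage_accuracy(reference, predicted),
        cum5=cum5,
        cum10=cum10,
        cum15=cum15,
        aami_pass=passed,
        aami_reasons=reasons,
        bhs=bhs_grade(cum5, cum10, cum15),
        ba_bias=bias,
        ba_lower=lower,
        ba_upper=upper,
        ba_points=points,
    )


@dataclass
class ValidationReport:
    """The full metric bundle for SBP and DBP predictions."""

    sbp: QuantityReport
    dbp: QuantityReport
    label: str = ""

    def to_dict(self) -> dict:
        return {"label": self.label, "sbp": self.sbp.to_dict(), "dbp": self.dbp.to_dict()}

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_markdown(self) -> str:
        """Render the report as a Markdown table (one decimal for pressures)."""
        lines = [
            f"### Validation report{': ' + self.label if self.label else ''}",
            "",
            "| BP estimate | Error bias (mmHg), mean (SD) | Accuracy (%) | Pearson | Spearman "
            "| <=5 mmHg (%) | <=10 mmHg (%) | <=15 mmHg (%) | AAMI | BHS |",
            "|---|---|---|---|---|---|---|---|---|---|",
        ]
        for name, q in (("SBP", self.sbp), ("DBP", self.dbp)):
            lines.append(
                f"| {name} | {q.summary.me:.2f} ({q.summary.sd:.2f}) "
                f"| {q.accuracy_pct:.2f} | {q.pearson:.2f} | {q.spearman:.2f} "
                f"| {q.cum5:.2f} | {q.cum10:.2f} | {q.cum15:.2f} "
                f"| {'pass' if q.aami_pass else 'fail'} | {q.bhs} |"
            )
        return "\n".join(lines) + "\n"


def evaluate_predictions(
    sbp_ref, sbp_pred, dbp_ref, dbp_pred, label: str = ""
) -> ValidationReport:
    """Assemble the full validation report for paired SBP/DBP predictions."""
    return ValidationReport(
        sbp=evaluate_quantity(sbp_ref, sbp_pred),
        dbp=evaluate_quantity(dbp_ref, dbp_pred),
        label=label,
    )


def per_participant_report(frame: pd.DataFrame) -> pd.DataFrame:
    """Per-participant error summaries and accuracy.

    Expects columns participant, sbp_ref, sbp_pred, dbp_ref, dbp_pred.
    Groups with fewer than two records are excluded (a warning row count is
    implicit in the output's n column).
    """
    required = {"participant", "sbp_ref", "sbp_pred", "dbp_ref", "dbp_pred"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"per-participant table missing columns: {sorted(missing)}")
    rows = []
    for pid, grp in frame.groupby("participant", sort=True):
        if len(grp) < 2:
            continue
        s = error_summary(grp.sbp_ref, grp.sbp_pred)
        d = error_summary(grp.dbp_ref, grp.dbp_pred)
        rows.append(
            {
                "participant": pid,
                "n": s.n,
                "sbp_me": s.me,
                "sbp_sd": s.sd,
                "dbp_me": d.me,
                "dbp_sd": d.sd,
                "sbp_accuracy_pct": percentage_accuracy(grp.sbp_ref, grp.sbp_pred),
                "dbp_accuracy_pct": percentage_accuracy(grp.dbp_ref, grp.dbp_pred),
            }
        )
    if not rows:
        raise ValueError("no participant has at least two records")
    return pd.DataFrame(rows)
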
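"""Tumor response classification and discrimination statistics.

Implements volumetric response calls adapted from the iRANO criteria —
progressive disease (PD) at a volume change >= +40% from baseline, partial
response (PR) at <= -65%, stable disease (SD) in the open interval between —
plus empirical ROC analysis with AUC (rank statistic / trapezoid rule,
Hanley-McNeil CI), Wilson score intervals for sensitivity and specificity,
Youden-index cutoff selection, and descriptive longitudinal summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "VolumeTrajectory",
    "ResponseCall",
    "RocResult",
    "classify_response",
    "classify_cohort",
    "cohort_response_summary",
    "roc_analysis",
    "youden_cutoff",
    "longitudinal_summary",
    "PD_THRESHOLD_PERCENT",
    "PR_THRESHOLD_PERCENT",
]

#: Volume-change thresholds (percent of baseline), boundary-inclusive.
PD_THRESHOLD_PERCENT = 40.0
PR_THRESHOLD_PERCENT = -65.0


class ClassificationError(ValueError):
    """A trajectory cannot be classified (e.g. a required week is missing)."""


@dataclass
class VolumeTrajectory:
    """Per-subject longitudinal tumor volumes (mm^3) keyed by week."""

    subject_id: str
    group: str
    volumes: Dict[int, float]

    def __post_init__(self) -> None:
        self.volumes = {int(w): float(v) for w, v in sorted(self.volumes.items())}
        for w, v in self.volumes.items():
            if v < 0:
                raise ValueError(f"{self.subject_id}: negative volume at week {w}")

    @property
    def weeks(self) -> List[int]:
        return sorted(self.volumes)

    def missing_weeks(self, expected: Iterable[int] = (2, 3, 4)) -> List[int]:
        return sorted(set(expected) - set(self.volumes))

    @property
    def complete(self) -> bool:
        return not self.missing_weeks()


@dataclass
class ResponseCall:
    """PD/SD/PR call with the underlying percent volume change."""

    subject_id: str
    group: str
    percent_change: float
    category: str
    baseline_week: int
    end_week: int


def classify_response(
    traj: VolumeTrajectory,
    baseline_week: int = 2,
    end_week: int = 4,
    pd_threshold: float = PD_THRESHOLD_PERCENT,
    pr_threshold: float = PR_THRESHOLD_PERCENT,
) -> ResponseCall:
    """Volumetric response call from two time points.

    percent change = 100 (V_end - V_base) / V_base; PD iff >= +40 (inclusive),
    PR iff <= -65 (inclusive), SD otherwise.  A missing week raises
    :class:`ClassificationError` so the subject is flagged, never silently
    dropped.
    """
    for w in (baseline_week, end_week):
        if w not in traj.volumes:
            raise ClassificationError(f"{traj.subject_id}: week {w} missing")
    v0 = traj.volumes[baseline_week]
    v1 = traj.volumes[end_week]
    if v0 <= 0:
        raise ClassificationError(f"{traj.subject_id}: non-positive baseline volume")
    pct = 100.0 * (v1 - v0) / v0
    if pct >= pd_threshold:
        cat = "PD"
    elif pct <= pr_threshold:
        cat = "PR"
    else:
        cat = "SD"
    return ResponseCall(
        subject_id=traj.subject_id,
        group=traj.group,
        percent_change=pct,
        category=cat,
        baseline_week=baseline_week,
        end_week=end_week,
    )


def classify_cohort(
    trajectories: Sequence[VolumeTrajectory],
    baseline_week: int = 2,
    end_week: int = 4,
) -> Tuple[List[ResponseCall], List[str]]:
    """Classify every trajectory; returns (calls, flagged subject ids)."""
    calls: List[ResponseCall] = []
    flagged: List[str] = []
    for t in trajectories:
        try:
            calls.append(classify_response(t, baseline_week, end_week))
        except ClassificationError:
            flagged.append(t.subject_id)
    return calls, flagged


def cohort_response_summary(calls: Sequence[ResponseCall], decimals: int = 0) -> pd.DataFrame:
    """Per-group PD/SD/PR counts and percentages.

    Percentages use round-half-to-even at ``decimals`` places (so 5/9, 2/9,
    2/9 summarize to 56/22/22%).  Empty input raises; groups are rows.
    """
    if not calls:
        raise ValueError("no response calls to summarize")
    rows = []
    df = pd.DataFrame(
        [{"group": c.group, "category": c.category} for c in calls]
    )
    for group, sub in df.groupby("group", sort=True):
        n = len(sub)
        row: Dict[str, object] = {"group": group, "n": n}
        for cat in ("PD", "SD", "PR"):
            k = int((sub["category"] == cat).sum())
            row[f"{cat}_count"] = k
            row[f"{cat}_percent"] = round(100.0 * k / n, decimals)
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------


@dataclass
class RocResult:
    """Empirical ROC of one biomarker.

    ``table`` has one row per candidate cutoff (midpoints between adjacent
    observed values) with sensitivity/specificity, their Wilson 95% CIs and
    the Youden index; the optimum row is summarized in the criterion fields.
    ``direction`` is "<" when positives lie below the cutoff.
    """

    name: str
    direction: str
    auc: float
    auc_ci: Tuple[float, float]
    table: pd.DataFrame
    cutoff: float
    criterion: str
    youden: float
    sensitivity: float
    sensitivity_ci: Tuple[float, float]
    specificity: float
    specificity_ci: Tuple[float, float]
    n_positive: int
    n_negative: int


def _auc_rank(values: np.ndarray, positive: np.ndarray) -> float:
    """Tie-corrected rank AUC: P(value_pos > value_neg) + 0.5 P(tie)."""
    ranks = sstats.rankdata(values)
    n_pos = int(positive.sum())
    n_neg = int((~positive).sum())
    u = ranks[positive].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _hanley_mcneil_ci(auc: float, n_pos: int, n_neg: int, alpha: float = 0.05) -> Tuple[float, float]:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2) + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    se = np.sqrt(max(var, 0.0))
    z = sstats.norm.ppf(1 - alpha / 2)
    return (float(np.clip(auc - z * se, 0, 1)), float(np.clip(auc + z * se, 0, 1)))


def roc_analysis(
    values,
    labels,
    positive_label=None,
    direction: str = "auto",
    alpha: float = 0.05,
    name: str = "biomarker",
) -> RocResult:
    """Empirical ROC analysis of a per-subject biomarker.

    AUC is the two-sample rank statistic with tie correction (identical to
    the trapezoid rule over the empirical ROC), with a Hanley-McNeil 95% CI.
    Candidate cutoffs sit at midpoints between adjacent observed values;
    sensitivity and specificity carry two-sided Wilson score intervals.  The
    optimal criterion maximizes the Youden index (ties broken toward higher
    sensitivity, then the smaller absolute cutoff).  ``direction="auto"``
    orients the test so AUC >= 0.5; "greater"/"less" fix it.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.ndim != 1 or values.shape != labels.shape:
        raise ValueError("values and labels must be 1-D and equally long")
    if np.any(~np.isfinite(values)):
        raise ValueError("biomarker values must be finite (no NaNs)")
    if positive_label is None:
        uniq = pd.unique(labels)
        if len(uniq) != 2:
            raise ValueError("labels must contain exactly two classes")
        positive_label = uniq[0] if uniq[0] is True else (True if True in list(uniq) else sorted(uniq.tolist())[-1])
    positive = labels == positive_label
    n_pos = int(positive.sum())
    n_neg = int((~positive).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    auc_gt = _auc_rank(values, positive)
    if direction == "auto":
        use_less = auc_gt < 0.5
    elif direction in ("greater", ">"):
        use_less = False
    elif direction in ("less", "<"):
        use_less = True
    else:
        raise ValueError("direction must be 'auto', 'greater' or 'less'")
    auc = 1.0 - auc_gt if use_less else auc_gt

    uniq = np.unique(values)
    if uniq.size >= 2:
        cutoffs = (uniq[:-1] + uniq[1:]) / 2.0
    else:
        cutoffs = np.array([uniq[0]])
    rows = []
    for c in cutoffs:
        if use_less:
            tp = int((values[positive] < c).sum())
            tn = int((values[~positive] > c).sum())
        else:
            tp = int((values[positive] > c).sum())
            tn = int((values[~positive] < c).sum())
        sens = tp / n_pos
        spec = tn / n_neg
        s_lo, s_hi = proportion_confint(tp, n_pos, alpha=alpha, method="wilson")
        p_lo, p_hi = proportion_confint(tn, n_neg, alpha=alpha, method="wilson")
        rows.append(
            {
                "cutoff": float(c),
                "sensitivity": sens,
                "sens_ci_low": float(s_lo),
                "sens_ci_high": float(s_hi),
                "specificity": spec,
                "spec_ci_low": float(p_lo),
                "spec_ci_high": float(p_hi),
                "youden": sens + spec - 1.0,
            }
        )
    table = pd.DataFrame(rows)

    best = _select_youden_row(table)
    sign = "<" if use_less else ">"
    return RocResult(
        name=name,
        direction=sign,
        auc=auc,
        auc_ci=_hanley_mcneil_ci(auc, n_pos, n_neg, alpha),
        table=table,
        cutoff=float(best["cutoff"]),
        criterion=f"{sign} {best['cutoff']:g}",
        youden=float(best["youden"]),
        sensitivity=float(best["sensitivity"]),
        sensitivity_ci=(float(best["sens_ci_low"]), float(best["sens_ci_high"])),
        specificity=float(best["specificity"]),
        specificity_ci=(float(best["spec_ci_low"]), float(best["spec_ci_high"])),
        n_positive=n_pos,
        n_negative=n_neg,
    )


def _select_youden_row(table: pd.DataFrame) -> pd.Series:
    """Max-Youden row; ties -> higher sensitivity, then smaller |cutoff|."""
    order = table.sort_values(
        by=["youden", "sensitivity", "cutoff"],
        key=lambda col: col.abs() if col.name == "cutoff" else col,
        ascending=[False, False, True],
    )
    return order.iloc[0]


def youden_cutoff(roc: RocResult) -> Tuple[str, float, float]:
    """Optimal criterion from an ROC: (direction, cutoff, Youden index)."""
    best = _select_youden_row(roc.table)
    return roc.direction, float(best["cutoff"]), float(best["youden"])


def longitudinal_summary(cohort: pd.DataFrame, parameters: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Per-group, per-week mean +/- SD of longitudinal parameters.

    ``cohort`` is the tidy table (columns subject_id, group, week, plus
    parameter columns).  SD uses ddof=1, reported as 0 with an ``n`` column of
    1 for singleton cells.  Descriptive only — no inferential tests.
    """
    if parameters is None:
        parameters = [
            c for c in cohort.columns if c not in ("subject_id", "group", "week")
        ]
    rows = []
    for (group, week), sub in cohort.groupby(["group", "week"], sort=True):
        row: Dict[str, object] = {"group": group, "week": week, "n": len(sub)}
        for p in parameters:
            vals = sub[p].dropna().to_numpy(dtype=float)
            row[f"{p}_mean"] = vals.mean() if vals.size else np.nan
            row[f"{p}_sd"] = vals.std(ddof=1) if vals.size > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows).set_index(["group", "week"])
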
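"""Control/impact day classification and estimation metrics.

Every antibiotic day plays two roles across the two scenarios: each treated
day is a stop-impact and a continue-control day; the cessation day (first
antibiotic-free day, when it happens in-ICU) is a stop-control and a
continue-impact day.  On control days the factual outcome is known, so the
estimate can be scored; on impact days the estimate quantifies the
unobserved alternative.

The mean delta and MAPE/MAE statistics average within each stay first and
then across stays; RMSE is pooled over all qualifying days.  Significance of
label-vs-estimate differences uses the two-sided Wilcoxon rank-sum
(Mann-Whitney U) test; mortality estimates are additionally scored with the
AUROC/accuracy/precision/recall/specificity/F1/AUPRC family with percentile
bootstrap confidence intervals.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.metrics import average_precision_score, roc_auc_score

from .preprocess import StayTimeline, TreatmentCourse

logger = logging.getLogger(__name__)

__all__ = [
    "classify_day",
    "add_day_roles",
    "mean_delta",
    "error_metrics",
    "rank_sum_test",
    "classification_report",
    "evaluate_estimates",
    "whatif_stop_after",
]


def classify_day(course: TreatmentCourse, day: int, scenario: str, n_days: int | None = None) -> str:
    """Role of (day, scenario): 'control', 'impact' or 'not_applicable'.

    Treatment days of the initial course are continue-control and
    stop-impact; the in-stay cessation day is stop-control and
    continue-impact.  Other days are not antibiotic days.
    """
    if scenario not in ("stop", "continue"):
        raise ValueError(f"unknown scenario {scenario!r}")
    m = course.initial_course_length
    first = course.first_abx_day
    stop_day = course.stop_day
    if first is not None and first <= day <= first + m - 1:
        return "impact" if scenario == "stop" else "control"
    if stop_day is not None and day == stop_day and (n_days is None or day <= n_days):
        return "control" if scenario == "stop" else "impact"
    return "not_applicable"


def add_day_roles(estimates: pd.DataFrame, courses: dict[int, TreatmentCourse]) -> pd.DataFrame:
    """Attach the control/impact role of each estimate row."""
    roles = [
        classify_day(courses[sid], int(day), scen)
        for sid, day, scen in zip(estimates["stay_id"], estimates["day"], estimates["scenario"])
    ]
    return estimates.assign(role=roles)


def _stay_first(df: pd.DataFrame, col: str) -> tuple[float, pd.Series]:
    per_stay = df.groupby("stay_id")[col].mean()
    return float(per_stay.mean()), per_stay


def mean_delta(df: pd.DataFrame) -> tuple[float, pd.Series]:
    """Stay-first mean of (label - estimate) over qualifying days.

    ``df`` needs columns stay_id, y, estimate.  Positive values mean the true
    label exceeds the estimate.  Returns (mu_delta, per-stay deltas); an
    empty frame yields (nan, empty).
    """
    if len(df) == 0:
        return float("nan"), pd.Series(dtype=float)
    work = df.assign(_delta=df["y"] - df["estimate"])
    mu, per_stay = _stay_first(work, "_delta")
    return mu, per_stay


def error_metrics(df: pd.DataFrame) -> dict[str, float]:
    """MAPE and MAE (stay-first averaging) and pooled-day RMSE.

    Days with a zero label are excluded from MAPE with a logged count.
    """
    if len(df) == 0:
        return {"mape": float("nan"), "mae": float("nan"), "rmse": float("nan")}
    err = df["y"] - df["estimate"]
    work = df.assign(_abs=err.abs())
    mae, _ = _stay_first(work, "_abs")
    nz = df["y"] != 0
    if (~nz).sum():
        logger.info("MAPE: excluded %d zero-label days", int((~nz).sum()))
    if nz.any():
        wnz = df[nz].assign(_ape=(err[nz] / df["y"][nz]).abs())
        mape, _ = _stay_first(wnz, "_ape")
    else:
        mape = float("nan")
    rmse = float(np.sqrt(np.mean(err.to_numpy() ** 2)))
    return {"mape": float(mape), "mae": float(mae), "rmse": rmse}


def rank_sum_test(x, y, alpha: float = 0.05) -> dict:
    """Two-sided Mann-Whitney U between two samples of day values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        return {"U": float("nan"), "p_value": float("nan"), "significant": False, "defined": False}
    res = mannwhitneyu(x, y, alternative="two-sided")
    return {
        "U": float(res.statistic),
        "p_value": float(res.pvalue),
        "significant": bool(res.pvalue < alpha),
        "defined": True,
    }


def classification_report(
    labels,
    probabilities,
    *,
    n_boot: int = 1000,
    seed: int = 0,
    threshold: float = 0.5,
    boot_size: int | None = None,
) -> dict:
    """Mortality metric family with percentile-bootstrap 95% CIs.

    ``boot_size`` defaults to the sample size.  AUROC/AUPRC are flagged
    undefined for single-class labels.
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if y.size != p.size or y.size == 0:
        raise ValueError("labels and probabilities must be non-empty and aligned")
    rng = np.random.default_rng(seed)
    size = boot_size or y.size

    def _metrics(yb, pb):
        out = {}
        two_class = len(np.unique(yb)) == 2
        out["auroc"] = float(roc_auc_score(yb, pb)) if two_class else float("nan")
        out["auprc"] = float(average_precision_score(yb, pb)) if two_class else float("nan")
        pred = (pb >= threshold).astype(int)
        tp = int(np.sum((pred == 1) & (yb == 1)))
        tn = int(np.sum((pred == 0) & (yb == 0)))
        fp = int(np.sum((pred == 1) & (yb == 0)))
        fn = int(np.sum((pred == 0) & (yb == 1)))
        out["accuracy"] = (tp + tn) / yb.size
        out["precision"] = tp / (tp + fp) if tp + fp else float("nan")
        out["recall"] = tp / (tp + fn) if tp + fn else float("nan")
        out["specificity"] = tn / (tn + fp) if tn + fp else float("nan")
        pr, rc = out["precision"], out["recall"]
        out["f1"] = 2 * pr * rc / (pr + rc) if pr + rc and np.isfinite(pr + rc) and (pr + rc) > 0 else float("nan")
        return out

    point = _metrics(y, p)
    boots: dict[str, list[float]] = {k: [] for k in point}
    for _ in range(n_boot):
        idx = rng.integers(0, y.size, size=size)
        for k, v in _metrics(y[idx], p[idx]).items():
            boots[k].append(v)
    report = {}
    for k, v in point.items():
        bs = np.asarray(boots[k], dtype=float)
        bs = bs[np.isfinite(bs)]
        lo, hi = (np.percentile(bs, [2.5, 97.5]) if bs.size else (float("nan"), float("nan")))
        report[k] = {"value": v, "ci_low": float(lo), "ci_high": float(hi)}
    report["n"] = int(y.size)
    report["defined"] = len(np.unique(y)) == 2
    return report


def evaluate_estimates(
    estimates: pd.DataFrame,
    labels: pd.DataFrame,
    courses: dict[int, TreatmentCourse],
    *,
    alpha: float = 0.05,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Per (scenario x role) metric blocks for both outcome types.

    ``estimates`` is the table from the synthetic-control step; ``labels``
    carries stay_id, los_days, mortality.  Control blocks score estimation
    error against the known outcome; impact blocks quantify the estimated
    effect of the unobserved action (delta = label - estimate).
    """
    lab = labels.set_index("stay_id")
    est = add_day_roles(estimates[~estimates["no_estimate"]], courses)
    report: dict = {}
    for outcome_type, grp_o in est.groupby("outcome_type"):
        ycol = "los_days" if outcome_type == "los" else "mortality"
        for (scenario, role), grp in grp_o.groupby(["scenario", "role"]):
            if role == "not_applicable":
                continue
            df = grp.assign(y=grp["stay_id"].map(lab[ycol]).astype(float))
            mu, per_stay = mean_delta(df)
            block = {
                "n_stays": int(df["stay_id"].nunique()),
                "n_days": int(len(df)),
                "mean_delta": mu,
                **error_metrics(df),
                "rank_sum": rank_sum_test(df["y"], df["estimate"], alpha=alpha),
            }
            if outcome_type == "mortality":
                stay_level = df.groupby("stay_id").agg(y=("y", "first"), p=("estimate", "mean"))
                try:
                    block["classification"] = classification_report(
                        df["y"].astype(int), df["estimate"], n_boot=n_boot, seed=seed
                    )
                except ValueError:
                    block["classification"] = None
                block["n_positive"] = int(stay_level["y"].sum())
            report[f"{outcome_type}/{scenario}/{role}"] = block
    return report


def report_to_frame(report: dict) -> pd.DataFrame:
    """Flatten an evaluation report to one row per scenario x role block."""
    rows = []
    for key, block in report.items():
        outcome_type, scenario, role = key.split("/")
        row = {
            "outcome_type": outcome_type,
            "scenario": scenario,
            "role": role,
            "n_stays": block["n_stays"],
            "n_days": block["n_days"],
            "mean_delta": block["mean_delta"],
            "mape": block["mape"],
            "mae": block["mae"],
            "rmse": block["rmse"],
            "p_value": block["rank_sum"]["p_value"],
        }
        cls = block.get("classification")
        if cls:
            for m in ("auroc", "auprc", "accuracy", "precision", "recall", "specificity", "f1"):
                row[m] = cls[m]["value"]
        rows.append(row)
    return pd.DataFrame(rows)


def whatif_stop_after(
    estimates: pd.DataFrame,
    labels: pd.DataFrame,
    courses: dict[int, TreatmentCourse],
    cutoff: int,
    *,
    course_filter: str = "longer",
    alpha: float = 0.05,
) -> dict:
    """What if long-treated patients had stopped after ``cutoff`` days?

    Selects stays with an initial course strictly longer than ``cutoff``
    (``course_filter='longer'``) or exactly ``cutoff`` days
    (``course_filter='equal'``, the shorter-course query) and compares their
    realised LOS (the factual "continue" arm) to the stop-scenario estimate
    at day cutoff+1 — the first hypothetical antibiotic-free day.
    """
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    if course_filter == "longer":
        sids = [s for s, c in courses.items() if c.initial_course_length > cutoff]
    elif course_filter == "equal":
        sids = [s for s, c in courses.items() if c.initial_course_length == cutoff]
    else:
        raise ValueError("course_filter must be 'longer' or 'equal'")
    day = cutoff + 1
    sel = estimates[
        (estimates["scenario"] == "stop")
        & (estimates["day"] == day)
        & (estimates["outcome_type"] == "los")
        & (~estimates["no_estimate"])
        & (estimates["stay_id"].isin(sids))
    ]
    if len(sel) == 0:
        return {"n_stays": 0, "defined": False}
    lab = labels.set_index("stay_id")
    df = sel.assign(y=sel["stay_id"].map(lab["los_days"]).astype(float))
    mu, _ = mean_delta(df)
    out = {
        "n_stays": int(df["stay_id"].nunique()),
        "defined": True,
        "query_day": day,
        "mean_delta": mu,
        **error_metrics(df),
        "rank_sum": rank_sum_test(df["y"], df["estimate"], alpha=alpha),
    }
    return out
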
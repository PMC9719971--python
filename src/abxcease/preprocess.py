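"""Long-format EHR events -> regular per-day stay timelines.

Implements daily aggregation, treatment-course derivation, cohort filtering,
train-statistics normalisation with forward fill and missing-indicator
channels, a stay-level train/validation/test split and minority-class
oversampling for the mortality task.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "StayTimeline",
    "TreatmentCourse",
    "SplitSpec",
    "FeatureNormalizer",
    "aggregate_daily",
    "compute_treatment_course",
    "filter_cohort",
    "split_by_stay",
    "oversample_positive_mortality",
    "build_timelines",
]

AGE_VARIABLE = "age"


@dataclass
class TreatmentCourse:
    first_abx_day: int | None
    initial_course_length: int
    stop_day: int | None  # first antibiotic-free day after treatment, in-stay
    retreatment: bool


@dataclass
class StayTimeline:
    """One ICU stay on a contiguous 1-based day grid.

    ``features`` holds the (possibly normalised) day x feature matrix with
    missing cells imputed; ``missing_mask`` is 1 where the raw cell was
    unobserved.  Outcome labels are static over the stay.
    """

    stay_id: int
    features: np.ndarray  # (T, F) float
    missing_mask: np.ndarray  # (T, F) uint8
    feature_names: list[str]
    abx_status: np.ndarray  # (T,) int
    cum_treatment_len: np.ndarray  # (T,) int
    course: TreatmentCourse
    age_at_admission: float
    los_label: float
    mortality_label: int
    normalised: bool = False

    @property
    def n_days(self) -> int:
        return self.features.shape[0]

    @property
    def days(self) -> np.ndarray:
        return np.arange(1, self.n_days + 1)

    def antibiotic_days(self) -> np.ndarray:
        """Treatment days plus the in-stay cessation day, if any."""
        days = list(np.nonzero(self.abx_status)[0] + 1)
        if self.course.stop_day is not None and self.course.stop_day <= self.n_days:
            days.append(self.course.stop_day)
        return np.array(sorted(set(days)), dtype=int)


@dataclass(frozen=True)
class SplitSpec:
    train: float = 0.70
    val: float = 0.15
    test: float = 0.15
    seed: int = 0
    oversample_factor: int = 3

    def validate(self) -> None:
        fracs = (self.train, self.val, self.test)
        if any(f < 0 for f in fracs) or abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("split fractions must be non-negative and sum to 1")
        if self.oversample_factor < 0:
            raise ValueError("oversample_factor must be >= 0")


def aggregate_daily(events: pd.DataFrame, *, agg: str = "mean") -> dict[int, pd.DataFrame]:
    """Collapse long-format events to one row per (stay, day).

    Multiple same-day observations of a variable collapse to their mean (or
    ``median`` via ``agg``).  The day grid of each stay runs contiguously from
    1 to its maximum observed day; absent cells are NaN (missing).
    """
    if agg not in ("mean", "median"):
        raise ValueError("agg must be 'mean' or 'median'")
    out: dict[int, pd.DataFrame] = {}
    if len(events) == 0:
        return out
    required = {"stay_id", "day", "variable", "value"}
    missing_cols = required - set(events.columns)
    if missing_cols:
        raise ValueError(f"events table lacks columns: {sorted(missing_cols)}")
    values = pd.to_numeric(events["value"], errors="coerce")
    bad = values.isna() & events["value"].notna()
    if bad.any():
        row = events[bad].iloc[0]
        raise ValueError(
            "non-numeric value for variable "
            f"{row['variable']!r} at (stay={row['stay_id']}, day={row['day']}): {row['value']!r}"
        )
    ev = events.assign(value=values)
    all_vars = sorted(ev["variable"].astype(str).unique())
    for sid, grp in ev.groupby("stay_id", sort=True):
        wide = grp.pivot_table(index="day", columns="variable", values="value", aggfunc=agg)
        wide = wide.reindex(index=np.arange(1, int(grp["day"].max()) + 1), columns=all_vars)
        wide.columns.name = None
        out[int(sid)] = wide
    return out


def compute_treatment_course(abx_flags: Sequence[int] | np.ndarray) -> tuple[np.ndarray, TreatmentCourse]:
    """Cumulative consecutive-treatment counter and derived course facts.

    ``cum[t] = cum[t-1] + 1`` inside a run of treated days, resets to 0 on
    untreated days.  ``stop_day`` is the first antibiotic-free day following a
    treated day; ``retreatment`` is true when a new run starts after a gap.
    """
    flags = np.asarray(abx_flags, dtype=int)
    if flags.ndim != 1:
        raise ValueError("abx_flags must be one-dimensional")
    cum = np.zeros_like(flags)
    run = 0
    for t, f in enumerate(flags):
        run = run + 1 if f else 0
        cum[t] = run

    treated = np.nonzero(flags)[0]
    if treated.size == 0:
        return cum, TreatmentCourse(None, 0, None, False)
    first = int(treated[0])
    length = 1
    while first + length < flags.size and flags[first + length]:
        length += 1
    stop_idx = None
    for t in range(1, flags.size):
        if flags[t] == 0 and flags[t - 1] == 1:
            stop_idx = t
            break
    runs_started = int(np.sum((flags[1:] == 1) & (flags[:-1] == 0))) + int(flags[0] == 1)
    return cum, TreatmentCourse(
        first_abx_day=first + 1,
        initial_course_length=length,
        stop_day=None if stop_idx is None else stop_idx + 1,
        retreatment=runs_started > 1,
    )


def filter_cohort(
    timelines: Iterable[StayTimeline],
    *,
    min_course: int = 1,
    max_course: int = 21,
    max_daily_missing: float = 0.5,
    missing_rule: str = "any_day",
) -> tuple[list[StayTimeline], dict[str, int]]:
    """Retain stays with an initial antibiotic course in [min, max] days whose
    per-day missing-value fraction never exceeds ``max_daily_missing``.

    A stay violating several rules is counted once, under the first rule.
    ``missing_rule='mean'`` relaxes the per-day check to the stay mean.
    """
    kept: list[StayTimeline] = []
    removed = {"course_length": 0, "daily_missingness": 0}
    for tl in timelines:
        if not min_course <= tl.course.initial_course_length <= max_course:
            removed["course_length"] += 1
            continue
        daily_missing = tl.missing_mask.mean(axis=1)
        excess = (
            (daily_missing > max_daily_missing).any()
            if missing_rule == "any_day"
            else daily_missing.mean() > max_daily_missing
        )
        if excess:
            removed["daily_missingness"] += 1
            continue
        kept.append(tl)
    logger.info(
        "cohort filter: kept %d stays, removed %d (course length) + %d (daily missingness)",
        len(kept), removed["course_length"], removed["daily_missingness"],
    )
    return kept, removed


def split_by_stay(stay_ids: Sequence[int], spec: SplitSpec) -> dict[str, list[int]]:
    """Seeded stay-level partition with largest-remainder rounding.

    Remainder ties break by set order (train, val, test); stay assignment is by
    a seeded permutation of the sorted ids, so identical specs give identical
    partitions.
    """
    spec.validate()
    ids = sorted(int(s) for s in stay_ids)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate stay_ids")
    n = len(ids)
    if n < 3:
        raise ValueError("need at least 3 stays to split")
    fracs = {"train": spec.train, "val": spec.val, "test": spec.test}
    quotas = {k: f * n for k, f in fracs.items()}
    sizes = {k: int(np.floor(q)) for k, q in quotas.items()}
    leftover = n - sum(sizes.values())
    for k in sorted(fracs, key=lambda k: (-(quotas[k] - sizes[k]), ["train", "val", "test"].index(k))):
        if leftover == 0:
            break
        sizes[k] += 1
        leftover -= 1
    perm = np.random.default_rng(spec.seed).permutation(n)
    shuffled = [ids[i] for i in perm]
    out, pos = {}, 0
    for k in ("train", "val", "test"):
        out[k] = sorted(shuffled[pos : pos + sizes[k]])
        pos += sizes[k]
    return out


def oversample_positive_mortality(
    mortality_labels: Sequence[int], factor: int = 3
) -> np.ndarray:
    """Sampling index with each positive-mortality stay appearing 1 + factor
    times (data is never copied, only the index).  Factor 0 is the identity."""
    if factor < 0:
        raise ValueError("factor must be >= 0")
    y = np.asarray(mortality_labels, dtype=int)
    idx = np.arange(y.size)
    pos = idx[y == 1]
    if pos.size == 0:
        warnings.warn("no positive-mortality stays; oversampling index unchanged")
        return idx
    return np.concatenate([idx, np.tile(pos, factor)])


class FeatureNormalizer:
    """Training-set feature statistics: 1st/99th-percentile clipping bounds,
    z-scoring mean/sd, plus age statistics.  Fit on training stays only and
    frozen for reuse at inference; transform is a pure function of the raw
    timeline.

    Transform order per stay and feature: clip -> forward fill -> z-score;
    leading cells with nothing to fill from become 0 (the training mean) with
    the missing indicator left set.
    """

    def __init__(self, clip_quantiles: tuple[float, float] = (0.01, 0.99)):
        self.clip_quantiles = clip_quantiles

    def fit(self, train_timelines: Sequence[StayTimeline]) -> "FeatureNormalizer":
        if not train_timelines:
            raise ValueError("cannot fit normaliser on an empty training set")
        names = train_timelines[0].feature_names
        cols = {n: [] for n in names}
        for tl in train_timelines:
            if tl.feature_names != names:
                raise ValueError("inconsistent feature ordering across stays")
            obs = tl.missing_mask == 0
            for j, n in enumerate(names):
                vals = tl.features[:, j][obs[:, j]]
                if vals.size:
                    cols[n].append(vals)
        self.feature_names_ = list(names)
        lo, hi, mean, scale = [], [], [], []
        for n in names:
            vals = np.concatenate(cols[n]) if cols[n] else np.array([0.0])
            qlo, qhi = np.quantile(vals, self.clip_quantiles)
            clipped = np.clip(vals, qlo, qhi)
            m, s = float(clipped.mean()), float(clipped.std())
            if s < 1e-12:
                warnings.warn(f"zero-variance training feature {n!r}; scale forced to 1")
                s = 1.0
            lo.append(float(qlo)); hi.append(float(qhi)); mean.append(m); scale.append(s)
        self.clip_lo_ = np.array(lo)
        self.clip_hi_ = np.array(hi)
        self.mean_ = np.array(mean)
        self.scale_ = np.array(scale)
        ages = np.array([tl.age_at_admission for tl in train_timelines], dtype=float)
        ages = ages[np.isfinite(ages)]
        self.age_mean_ = float(ages.mean()) if ages.size else 0.0
        self.age_scale_ = float(ages.std()) if ages.size and ages.std() > 1e-12 else 1.0
        return self

    def transform(self, timelines: Sequence[StayTimeline]) -> list[StayTimeline]:
        out = []
        for tl in timelines:
            if tl.feature_names != self.feature_names_:
                raise ValueError("feature names do not match fitted normaliser")
            x = np.clip(tl.features, self.clip_lo_, self.clip_hi_)
            x = np.where(tl.missing_mask == 1, np.nan, x)
            x = pd.DataFrame(x).ffill().to_numpy()
            z = (x - self.mean_) / self.scale_
            z = np.where(np.isnan(z), 0.0, z)
            out.append(
                StayTimeline(
                    stay_id=tl.stay_id,
                    features=z,
                    missing_mask=tl.missing_mask.copy(),
                    feature_names=list(tl.feature_names),
                    abx_status=tl.abx_status.copy(),
                    cum_treatment_len=tl.cum_treatment_len.copy(),
                    course=tl.course,
                    age_at_admission=tl.age_at_admission,
                    los_label=tl.los_label,
                    mortality_label=tl.mortality_label,
                    normalised=True,
                )
            )
        return out

    def fit_transform(self, train_timelines, all_timelines=None):
        self.fit(train_timelines)
        return self.transform(all_timelines if all_timelines is not None else train_timelines)

    # -- persistence ---------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "clip_quantiles": list(self.clip_quantiles),
            "feature_names": self.feature_names_,
            "clip_lo": self.clip_lo_.tolist(),
            "clip_hi": self.clip_hi_.tolist(),
            "mean": self.mean_.tolist(),
            "scale": self.scale_.tolist(),
            "age_mean": self.age_mean_,
            "age_scale": self.age_scale_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureNormalizer":
        obj = cls(clip_quantiles=tuple(d["clip_quantiles"]))
        obj.feature_names_ = list(d["feature_names"])
        obj.clip_lo_ = np.asarray(d["clip_lo"], dtype=float)
        obj.clip_hi_ = np.asarray(d["clip_hi"], dtype=float)
        obj.mean_ = np.asarray(d["mean"], dtype=float)
        obj.scale_ = np.asarray(d["scale"], dtype=float)
        obj.age_mean_ = float(d["age_mean"])
        obj.age_scale_ = float(d["age_scale"])
        return obj

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "FeatureNormalizer":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def build_timelines(
    events: pd.DataFrame,
    abx: pd.DataFrame,
    labels: pd.DataFrame,
    *,
    agg: str = "mean",
) -> list[StayTimeline]:
    """Assemble raw (un-normalised) StayTimelines from the three input tables.

    The static ``age`` variable, when present, is pulled out of the feature
    matrix into ``age_at_admission``.  The day grid is the union of event and
    administration days, contiguous from day 1.
    """
    daily = aggregate_daily(events, agg=agg)
    lab = labels.set_index("stay_id")
    out: list[StayTimeline] = []
    for sid, grp in abx.groupby("stay_id", sort=True):
        sid = int(sid)
        grp = grp.sort_values("day")
        t_abx = int(grp["day"].max())
        wide = daily.get(sid)
        t_days = max(t_abx, 0 if wide is None else wide.index.max())
        flags = np.zeros(t_days, dtype=int)
        flags[grp["day"].to_numpy() - 1] = grp["on_antibiotics"].to_numpy()
        cum, course = compute_treatment_course(flags)

        if wide is None:
            feature_names: list[str] = []
            feats = np.zeros((t_days, 0))
            mask = np.zeros((t_days, 0), dtype=np.uint8)
            age = np.nan
        else:
            wide = wide.reindex(np.arange(1, t_days + 1))
            age = np.nan
            if AGE_VARIABLE in wide.columns:
                age_col = wide[AGE_VARIABLE].dropna()
                if len(age_col):
                    age = float(age_col.iloc[0])
                wide = wide.drop(columns=[AGE_VARIABLE])
            feature_names = [str(c) for c in wide.columns]
            feats = wide.to_numpy(dtype=float)
            mask = np.isnan(feats).astype(np.uint8)
            feats = np.where(np.isnan(feats), 0.0, feats)

        row = lab.loc[sid]
        out.append(
            StayTimeline(
                stay_id=sid,
                features=feats,
                missing_mask=mask,
                feature_names=feature_names,
                abx_status=flags,
                cum_treatment_len=cum,
                course=course,
                age_at_admission=age,
                los_label=float(row["los_days"]),
                mortality_label=int(row["mortality"]),
                normalised=False,
            )
        )
    return out
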
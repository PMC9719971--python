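"""Synthetic ICU cohort generator with known cessation counterfactuals.

Emulates the statistical structure an antibiotic-cessation outcome estimator
assumes: daily multivariate features driven by a latent severity process,
heavy informative-or-random missingness, an initial intravenous antibiotic
course of 1-21 days whose length is positively rank-correlated with length of
stay (LOS), a ~18-19% stay-level mortality rate, and roughly 40% of stays
ceasing antibiotics before ICU discharge.  The causal effect of cessation
timing on LOS is linear and configurable, so every stop/continue
counterfactual has a closed-form ground truth that downstream estimators can
be scored against.

Scenario convention
-------------------
"Stop on day t" means day t is the first antibiotic-free day: the
counterfactual course length is t-1 and the avoided treatment days relative
to a factual course of m days number m - t + 1.  "Continue on day t" means
antibiotics are administered on day t; on treatment days this is the factual
action, on the cessation day it extends the course by one day.  This matches
the donor-pool definition used by the synthetic-control estimator (a stay
joins the stop pool on its cessation day).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "GroundTruth",
    "CohortData",
    "simulate_cohort",
    "true_counterfactual",
]

MAX_STAY_DAYS = 60


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Defaults are calibrated so that a large cohort reproduces the headline
    structure of a real ICU antibiotic cohort: Spearman(LOS, treatment
    length) ~ 0.72, mean LOS ~ 5.6 d (SD ~ 4.2), mean course ~ 4.4 d
    (SD ~ 3.3), ~42% of stays stopping antibiotics in-ICU and a stay-level
    mortality rate equal to ``mortality_base_rate``.
    """

    n_stays: int = 1000
    n_features: int = 43
    severity_init_mean: float = 2.6
    severity_init_sd: float = 1.9
    severity_decay: float = 0.18
    severity_noise_sd: float = 0.35
    missing_rate: float = 0.3
    informative_missingness: float = 0.0
    abx_stop_threshold: float = 1.0
    policy_jitter_prob: float = 0.25
    min_course_days: int = 1
    max_course_days: int = 21
    cessation_effect_los: float = 0.8
    los_severity_coef: float = 0.37
    los_noise_sd: float = 0.7
    los_noise_scale: float = 2.9
    fast_track_prob: float = 0.58
    mortality_base_rate: float = 0.186
    mortality_severity_coef: float = 1.2
    discharge_margin: float = 0.4
    feature_noise_sd: float = 0.4
    prognosis_obs_coef: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_stays < 1:
            raise ValueError("n_stays must be >= 1")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        for name in ("mortality_base_rate",):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.severity_decay < 1.0:
            raise ValueError("severity_decay must lie in (0, 1)")
        if self.severity_init_mean <= 0 or self.severity_init_sd <= 0:
            raise ValueError("severity_init_mean and severity_init_sd must be positive")
        if self.severity_noise_sd < 0:
            raise ValueError("severity_noise_sd must be non-negative")
        if not 1 <= self.min_course_days <= self.max_course_days:
            raise ValueError("require 1 <= min_course_days <= max_course_days")
        if self.abx_stop_threshold <= 0:
            raise ValueError("abx_stop_threshold must be positive")
        if self.discharge_margin < 0:
            raise ValueError("discharge_margin must be non-negative")


@dataclass
class GroundTruth:
    """Per-stay causal bookkeeping hidden from the estimator.

    ``cf`` holds one row per antibiotic day of every stay with the true
    counterfactual LOS under stopping and continuing on that day.  The
    counterfactual of the factually-taken action equals the realised outcome
    and no counterfactual LOS falls below the day index being queried.
    """

    stays: pd.DataFrame  # stay_id, treatment_len, los_days, mortality, stopped_in_icu, severity_init
    cf: pd.DataFrame  # stay_id, day, cf_stop_los, cf_continue_los
    severity: dict[int, np.ndarray]
    config: SimConfig = field(repr=False)


@dataclass
class CohortData:
    events: pd.DataFrame  # stay_id, day, variable, value (long format; missing cells absent)
    abx: pd.DataFrame  # stay_id, day, on_antibiotics
    labels: pd.DataFrame  # stay_id, los_days, mortality
    ground_truth: GroundTruth

    def write(self, outdir, fmt: Literal["csv", "parquet"] = "csv") -> dict[str, str]:
        """Write the four tables; ground truth goes to a separate file that the
        estimator pipeline never reads."""
        import os

        os.makedirs(outdir, exist_ok=True)
        paths = {}
        tables = {
            "events": self.events,
            "abx": self.abx,
            "labels": self.labels,
            "ground_truth_stays": self.ground_truth.stays,
            "ground_truth_cf": self.ground_truth.cf,
        }
        for name, df in tables.items():
            path = os.path.join(outdir, f"{name}.{fmt}")
            if fmt == "parquet":
                df.to_parquet(path, index=False)
            else:
                # %.17g keeps doubles bit-exact through a CSV round trip
                df.to_csv(path, index=False, float_format="%.17g")
            paths[name] = path
        return paths


def _solve_mortality_intercept(z: np.ndarray, coef: float, target: float) -> float:
    """Bisect the logistic intercept so the cohort-mean death probability hits
    the configured rate regardless of the severity distribution drawn."""
    if target <= 0.0:
        return -np.inf
    if target >= 1.0:
        return np.inf
    lo, hi = -30.0, 30.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        p = 1.0 / (1.0 + np.exp(-(mid + coef * z)))
        if p.mean() > target:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def simulate_cohort(config: SimConfig) -> CohortData:
    """Generate one cohort.  Bit-identical output for identical config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_stays

    # Initial severity: lognormal moment-matched to the configured mean/sd so
    # the right tail produces the long courses and long stays real cohorts show.
    m0, s0 = config.severity_init_mean, config.severity_init_sd
    sig2 = np.log1p((s0 / m0) ** 2)
    mu = np.log(m0) - 0.5 * sig2
    s_init = rng.lognormal(mean=mu, sigma=np.sqrt(sig2), size=n)

    # Severity trajectories: geometric recovery plus noise, floored at zero.
    sev = np.zeros((n, MAX_STAY_DAYS))
    sev[:, 0] = s_init
    noise = rng.normal(0.0, config.severity_noise_sd, size=(n, MAX_STAY_DAYS - 1))
    for t in range(1, MAX_STAY_DAYS):
        sev[:, t] = np.maximum(0.0, (1.0 - config.severity_decay) * sev[:, t - 1] + noise[:, t - 1])

    # Planned course: treat daily until severity first drops below threshold,
    # plus or minus one day of prescriber variability.  The jitter keeps the
    # stop/continue populations overlapping in severity at every day, which
    # real prescribing habit noise provides and a matching estimator needs.
    below = sev < config.abx_stop_threshold
    first_below = np.where(below.any(axis=1), below.argmax(axis=1), MAX_STAY_DAYS)
    jitter_draw = rng.random(n)
    jitter = np.where(
        jitter_draw < config.policy_jitter_prob,
        -1,
        np.where(jitter_draw < 2 * config.policy_jitter_prob, 1, 0),
    )
    planned = np.clip(first_below + jitter, config.min_course_days, config.max_course_days)

    # Baseline LOS (course-free recovery time), two discharge regimes.
    # Fast-track stays step down from the ICU as soon as they stabilise, i.e.
    # at or just after the end of their antibiotic course (they usually leave
    # while still on antibiotics).  Complicated stays have a severity-linked
    # recovery baseline plus an independent heavy-tailed tail that
    # decorrelates LOS from the course length.
    e = config.cessation_effect_los
    is_fast = rng.random(n) < config.fast_track_prob
    slack = np.maximum(0.05, (1.0 - e) * planned)
    base_fast = rng.random(n) * slack
    base_slow = (
        config.discharge_margin
        + config.los_severity_coef * s_init
        + rng.lognormal(mean=np.log(config.los_noise_scale), sigma=config.los_noise_sd, size=n)
    )
    los_base = np.where(is_fast, base_fast, base_slow)

    # Realised course may be truncated by discharge; LOS depends on the
    # realised course, so iterate the (monotone, contracting) fixed point.
    course = planned.astype(float)
    for _ in range(30):
        los = np.maximum(1.0, los_base + e * course)
        t_days = np.ceil(los - 1e-9)
        new_course = np.minimum(planned, t_days)
        if np.array_equal(new_course, course):
            break
        course = new_course
    course = course.astype(int)
    los = np.minimum(np.maximum(1.0, los_base + e * course), float(MAX_STAY_DAYS))
    t_days = np.ceil(los - 1e-9).astype(int)
    t_days = np.maximum(t_days, course)
    stopped = course < t_days  # an in-ICU antibiotic-free day exists

    # Mortality: logistic in standardised initial severity, intercept solved so
    # the realised rate matches the configured rate in expectation.
    z = (s_init - s_init.mean()) / max(s_init.std(), 1e-9)
    icpt = _solve_mortality_intercept(z, config.mortality_severity_coef, config.mortality_base_rate)
    with np.errstate(over="ignore"):
        p_death = 1.0 / (1.0 + np.exp(-(icpt + config.mortality_severity_coef * z)))
    mortality = (rng.random(n) < p_death).astype(int)

    # Feature readouts of latent severity: linear plus saturating components
    # with per-feature coefficients; one static age feature.
    # A per-stay recovery-prognosis signal (standardised baseline recovery
    # time) is also read out by the features, the way frailty and
    # complication markers are visible in real labs/vitals.  Without it the
    # post-course tail would be latent and donor pools selected on it, which
    # no state-matching estimator could adjust for.
    # Feature semantics (which variable reads out what, how strongly) are a
    # fixed property of the data-generating process, shared across seeds the
    # way lab panels mean the same thing in every cohort; the config seed
    # only drives patient-level sampling.
    n_dyn = max(config.n_features - 1, 1)
    feat_rng = np.random.default_rng(971203 + n_dyn)
    coef_lin = feat_rng.normal(0.0, 1.0, size=n_dyn)
    coef_sat = feat_rng.normal(0.0, 1.0, size=n_dyn)
    coef_prog = feat_rng.normal(0.0, config.prognosis_obs_coef, size=n_dyn)
    offset = feat_rng.normal(0.0, 1.0, size=n_dyn)
    prognosis = (los_base - los_base.mean()) / max(los_base.std(), 1e-9)
    age = np.round(rng.uniform(40.0, 90.0, size=n), 1)

    stay_ids = np.arange(1, n + 1)
    ev_stay, ev_day, ev_var, ev_val = [], [], [], []
    abx_stay, abx_day, abx_flag = [], [], []
    cf_stay, cf_day, cf_stop, cf_cont = [], [], [], []
    severity_map: dict[int, np.ndarray] = {}

    feat_names = [f"f{j:02d}" for j in range(n_dyn)]
    for i in range(n):
        sid = int(stay_ids[i])
        ti = int(t_days[i])
        m = int(course[i])
        s = sev[i, :ti]
        severity_map[sid] = s.copy()

        vals = (
            offset[None, :]
            + coef_lin[None, :] * s[:, None]
            + coef_sat[None, :] * np.tanh(s[:, None])
            + coef_prog[None, :] * prognosis[i]
            + rng.normal(0.0, config.feature_noise_sd, size=(ti, n_dyn))
        )
        if config.missing_rate > 0.0 or config.informative_missingness != 0.0:
            rate = config.missing_rate
            if config.informative_missingness != 0.0:
                zs = (s - s.mean()) / (s.std() + 1e-9) if ti > 1 else np.zeros(ti)
                rate = np.clip(rate * (1.0 + config.informative_missingness * zs), 0.0, 0.95)[:, None]
            observed = rng.random((ti, n_dyn)) >= rate
        else:
            observed = np.ones((ti, n_dyn), dtype=bool)

        days_grid = np.arange(1, ti + 1)
        obs_d, obs_f = np.nonzero(observed)
        ev_stay.append(np.full(obs_d.size + ti, sid))
        ev_day.append(np.concatenate([days_grid[obs_d], days_grid]))
        ev_var.append(np.concatenate([np.asarray(feat_names, dtype=object)[obs_f],
                                      np.full(ti, "age", dtype=object)]))
        ev_val.append(np.concatenate([vals[obs_d, obs_f], np.full(ti, age[i])]))

        abx_stay.append(np.full(ti, sid))
        abx_day.append(days_grid)
        abx_flag.append((days_grid <= m).astype(int))

        # Ground truth on every antibiotic day: treated days 1..m plus the
        # cessation day m+1 when it falls inside the stay.
        n_abx = m + (1 if stopped[i] else 0)
        days_abx = np.arange(1, n_abx + 1)
        realised = float(los[i])
        stop_cf = np.maximum(days_abx.astype(float), realised - e * (m - (days_abx - 1)))
        cont_cf = np.full(n_abx, realised)
        if stopped[i]:
            stop_cf[m] = realised  # day m+1: stop is the factual action
            cont_cf[m] = realised + e  # one extra treated day
        cf_stay.append(np.full(n_abx, sid))
        cf_day.append(days_abx)
        cf_stop.append(stop_cf)
        cf_cont.append(cont_cf)

    events = pd.DataFrame(
        {
            "stay_id": np.concatenate(ev_stay).astype(int),
            "day": np.concatenate(ev_day).astype(int),
            "variable": np.concatenate(ev_var),
            "value": np.concatenate(ev_val).astype(float),
        }
    )
    abx = pd.DataFrame(
        {
            "stay_id": np.concatenate(abx_stay).astype(int),
            "day": np.concatenate(abx_day).astype(int),
            "on_antibiotics": np.concatenate(abx_flag).astype(int),
        }
    )
    labels = pd.DataFrame(
        {"stay_id": stay_ids, "los_days": los, "mortality": mortality}
    )
    gt_stays = pd.DataFrame(
        {
            "stay_id": stay_ids,
            "treatment_len": course,
            "los_days": los,
            "mortality": mortality,
            "stopped_in_icu": stopped.astype(bool),
            "severity_init": s_init,
            "planned_course": planned,
        }
    )
    cf = pd.DataFrame(
        {
            "stay_id": np.concatenate(cf_stay).astype(int),
            "day": np.concatenate(cf_day).astype(int),
            "cf_stop_los": np.concatenate(cf_stop).astype(float),
            "cf_continue_los": np.concatenate(cf_cont).astype(float),
        }
    )
    gt = GroundTruth(stays=gt_stays, cf=cf, severity=severity_map, config=config)
    return CohortData(events=events, abx=abx, labels=labels, ground_truth=gt)


def true_counterfactual(
    gt: GroundTruth, stay_id: int, day: int, scenario: Literal["stop", "continue"]
) -> float:
    """Oracle LOS for taking ``scenario`` on ``day`` of ``stay_id``.

    Only antibiotic days (treatment days plus the in-ICU cessation day) are
    queryable; anything else raises ``KeyError``.
    """
    if scenario not in ("stop", "continue"):
        raise ValueError(f"scenario must be 'stop' or 'continue', got {scenario!r}")
    rows = gt.cf[(gt.cf["stay_id"] == stay_id) & (gt.cf["day"] == day)]
    if rows.empty:
        raise KeyError(
            f"(stay={stay_id}, day={day}) is not an antibiotic day of this cohort"
        )
    col = "cf_stop_los" if scenario == "stop" else "cf_continue_los"
    return float(rows.iloc[0][col])


def config_with(config: SimConfig, **overrides) -> SimConfig:
    """Return a copy of ``config`` with fields replaced."""
    return dataclasses.replace(config, **overrides)
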
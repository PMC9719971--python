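"""Canned study-condition experiments: effect recovery, null calibration and
the pool-segregation ablation.

These are the package's benchmark protocols on the synthetic cohort: cohort
sizes and training lengths are the package's desk-scale study conditions
(documented in the methods note) and every random draw derives from the
caller's seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .autoencoder import SequenceAutoencoder
from .evaluation import add_day_roles, error_metrics, mean_delta, rank_sum_test
from .preprocess import (
    FeatureNormalizer,
    SplitSpec,
    build_timelines,
    filter_cohort,
    split_by_stay,
)
from .simulate import SimConfig, simulate_cohort
from .synthetic_control import estimate_all

logger = logging.getLogger(__name__)

__all__ = ["RecoveryResult", "recovery_experiment", "null_replicate_pvalues", "ablation_comparison"]


def _prepare(config: SimConfig, split_seed: int):
    cohort = simulate_cohort(config)
    raw = build_timelines(cohort.events, cohort.abx, cohort.labels)
    kept, _ = filter_cohort(raw)
    split = split_by_stay([tl.stay_id for tl in kept], SplitSpec(seed=split_seed))
    train_ids = set(split["train"])
    norm = FeatureNormalizer().fit([tl for tl in kept if tl.stay_id in train_ids])
    processed = norm.transform(kept)
    by_id = {tl.stay_id: tl for tl in processed}
    parts = {k: [by_id[s] for s in ids] for k, ids in split.items()}
    return cohort, processed, parts


def _train_los(parts, epochs: int, seed: int) -> SequenceAutoencoder:
    model = SequenceAutoencoder(task="los", epochs=epochs, seed=seed)
    model.fit(parts["train"], validation_data=parts["val"])
    return model


def _los_estimates(model, processed, k, ridge_lambda, segregate=True):
    emb = model.transform(processed)
    est = estimate_all(emb, k=k, ridge_lambda=ridge_lambda, outcome="los", segregate=segregate)
    courses = {tl.stay_id: tl.course for tl in processed}
    return add_day_roles(est[~est["no_estimate"]], courses)


@dataclass
class RecoveryResult:
    effect: float
    los_sd: float
    stop_control_mu: float
    continue_control_mu: float
    stop_impact_mu: float
    stop_impact_p: float
    true_mean_effect: float
    n_stays: int

    @property
    def relative_error(self) -> float:
        if self.true_mean_effect == 0:
            return float("nan")
        return abs(self.stop_impact_mu - self.true_mean_effect) / abs(self.true_mean_effect)


def recovery_experiment(
    effect: float,
    *,
    n_stays: int = 2000,
    seed: int = 1,
    epochs: int = 20,
    k: int = 10,
    ridge_lambda: float = 1.0,
) -> RecoveryResult:
    """Train on one simulated cohort with a known cessation effect and score
    control-day calibration plus stop-impact effect recovery against the
    simulator's counterfactual ground truth."""
    cohort, processed, parts = _prepare(
        SimConfig(n_stays=n_stays, seed=seed, cessation_effect_los=effect), split_seed=seed
    )
    model = _train_los(parts, epochs, seed)
    est = _los_estimates(model, processed, k, ridge_lambda)
    labels = cohort.labels.set_index("stay_id")["los_days"]
    est = est.assign(y=est["stay_id"].map(labels).astype(float))

    def block(scenario, role):
        return est[(est["scenario"] == scenario) & (est["role"] == role)]

    stop_ctrl, _ = mean_delta(block("stop", "control"))
    cont_ctrl, _ = mean_delta(block("continue", "control"))
    si = block("stop", "impact")
    stop_imp, _ = mean_delta(si)
    p = rank_sum_test(si["y"], si["estimate"])["p_value"]

    cf = cohort.ground_truth.cf.set_index(["stay_id", "day"])["cf_stop_los"]
    truth_days = si["y"].to_numpy() - np.array(
        [cf[(s, d)] for s, d in zip(si["stay_id"], si["day"])]
    )
    truth_mu, _ = mean_delta(si.assign(y=truth_days, estimate=0.0))
    return RecoveryResult(
        effect=effect,
        los_sd=float(cohort.ground_truth.stays["los_days"].std()),
        stop_control_mu=stop_ctrl,
        continue_control_mu=cont_ctrl,
        stop_impact_mu=stop_imp,
        stop_impact_p=float(p),
        true_mean_effect=float(truth_mu),
        n_stays=n_stays,
    )


def null_replicate_pvalues(
    *,
    n_replicates: int = 20,
    n_stays: int = 1000,
    epochs: int = 15,
    base_seed: int = 200,
    k: int = 10,
    ridge_lambda: float = 1.0,
) -> list[float]:
    """Stop-impact rank-sum p-values across replicate null cohorts
    (cessation effect 0), with the encoder retrained per replicate."""
    ps = []
    for i in range(n_replicates):
        seed = base_seed + i
        cohort, processed, parts = _prepare(
            SimConfig(n_stays=n_stays, seed=seed, cessation_effect_los=0.0), split_seed=seed
        )
        model = _train_los(parts, epochs, seed)
        est = _los_estimates(model, processed, k, ridge_lambda)
        si = est[(est["scenario"] == "stop") & (est["role"] == "impact")]
        y = si["stay_id"].map(cohort.labels.set_index("stay_id")["los_days"]).astype(float)
        ps.append(rank_sum_test(y, si["estimate"])["p_value"])
        logger.info("null replicate %d/%d: p=%.4f", i + 1, n_replicates, ps[-1])
    return ps


def ablation_comparison(
    seeds,
    *,
    n_stays: int = 1000,
    epochs: int = 15,
    k: int = 10,
    ridge_lambda: float = 1.0,
) -> list[tuple[float, float]]:
    """Control-day LOS RMSE with segregated vs merged donor pools, per seed.
    Merging across days and treatment status should degrade (raise) it."""
    out = []
    for seed in seeds:
        cohort, processed, parts = _prepare(SimConfig(n_stays=n_stays, seed=seed), split_seed=seed)
        model = _train_los(parts, epochs, seed)
        labels = cohort.labels.set_index("stay_id")["los_days"]
        rmses = {}
        for seg in (True, False):
            est = _los_estimates(model, processed, k, ridge_lambda, segregate=seg)
            ctrl = est[est["role"] == "control"]
            rmses[seg] = error_metrics(ctrl.assign(y=ctrl["stay_id"].map(labels).astype(float)))["rmse"]
        out.append((rmses[True], rmses[False]))
        logger.info("ablation seed %s: segregated %.3f merged %.3f", seed, rmses[True], rmses[False])
    return out
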
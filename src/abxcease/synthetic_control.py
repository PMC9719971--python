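"""Donor pools, ridge weighting and counterfactual outcome estimation.

For each day t the embedding space is partitioned into a "continue" pool
(patient-days still receiving antibiotics on day t) and a "stop" pool
(patients whose first antibiotic-free day is t).  For a subject-day the k
nearest donors (Euclidean distance) are drawn from each pool, ridge weights

    Loss = sum_d (z_d - sum_j x_{j,d} w_j)^2 + lambda * sum_j w_j^2

are solved in closed form, and the stop/continue counterfactual outcome is
the weighted average of the donor outcome labels.  The subject's own
stay-days are never donors.  Disabling segregation merges every pool into
one (the temporal-ablation mode).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator

__all__ = [
    "SyntheticControlEstimator",
    "ridge_weights",
    "select_donors",
    "estimate_outcome",
    "build_donor_index",
]


def ridge_weights(z: np.ndarray, X: np.ndarray, ridge_lambda: float = 1.0) -> np.ndarray:
    """Closed-form minimiser w* = (X'X + lambda I)^-1 X'z of the donor loss.

    ``X`` has one donor embedding per column (D x k).
    """
    if ridge_lambda < 0:
        raise ValueError("ridge_lambda must be non-negative")
    z = np.asarray(z, dtype=float)
    X = np.asarray(X, dtype=float)
    if not (np.isfinite(z).all() and np.isfinite(X).all()):
        raise ValueError("non-finite entries in embeddings")
    k = X.shape[1]
    A = X.T @ X + ridge_lambda * np.eye(k)
    try:
        return np.linalg.solve(A, X.T @ z)
    except np.linalg.LinAlgError:  # lambda == 0 with rank-deficient donors
        return np.linalg.lstsq(A, X.T @ z, rcond=None)[0]


def select_donors(
    subject_z: np.ndarray,
    pool_Z: np.ndarray,
    pool_keys: np.ndarray,
    k: int,
) -> np.ndarray:
    """Indices of the k nearest pool members by Euclidean distance.

    ``pool_keys`` is an (n, 2) array of (stay_id, day) used to break distance
    ties deterministically (ascending stay_id, then day).  If the pool is
    smaller than k the whole pool is returned in order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if pool_Z.shape[0] == 0:
        return np.array([], dtype=int)
    d = np.linalg.norm(pool_Z - subject_z[None, :], axis=1)
    order = np.lexsort((pool_keys[:, 1], pool_keys[:, 0], d))
    return order[:k]


def estimate_outcome(
    w: np.ndarray, donor_labels: np.ndarray, *, normalize: bool = True
) -> tuple[float, np.ndarray]:
    """Weighted average of donor labels; weights renormalised to sum to 1 by
    default so the estimate stays within the donor label range.  A zero (or
    near-zero) weight sum falls back to uniform weights."""
    w = np.asarray(w, dtype=float)
    y = np.asarray(donor_labels, dtype=float)
    if w.size == 0 or w.size != y.size:
        raise ValueError("weights and donor labels must align and be non-empty")
    if normalize:
        s = w.sum()
        if abs(s) < 1e-12:
            import logging

            logging.getLogger(__name__).warning("zero ridge-weight sum; falling back to uniform weights")
            wn = np.full_like(w, 1.0 / w.size)
        else:
            wn = w / s
    else:
        wn = w
    return float(wn @ y), wn


def build_donor_index(embeddings: pd.DataFrame, *, segregate: bool = True) -> dict:
    """Partition day-embeddings into per-(day, scenario) donor pools.

    ``embeddings`` needs columns stay_id, day, abx_status, is_stop_day and
    z-columns.  Continue pool at day t: rows on antibiotics on day t.  Stop
    pool at day t: rows whose stay ceases antibiotics on day t.  With
    ``segregate=False`` a single merged pool (all antibiotic-day rows) backs
    both scenarios on every day.
    """
    zcols = [c for c in embeddings.columns if c.startswith("z") and c[1:].isdigit()]
    abx_rows = embeddings[(embeddings["abx_status"] == 1) | embeddings["is_stop_day"]]
    pools: dict = {"zcols": zcols, "segregate": segregate}
    if not segregate:
        pools["merged"] = _pool_arrays(abx_rows, zcols)
        return pools
    for day, grp in abx_rows.groupby("day"):
        cont = grp[grp["abx_status"] == 1]
        stop = grp[grp["is_stop_day"]]
        if len(cont):
            pools[(int(day), "continue")] = _pool_arrays(cont, zcols)
        if len(stop):
            pools[(int(day), "stop")] = _pool_arrays(stop, zcols)
    return pools


def _pool_arrays(df: pd.DataFrame, zcols: list[str]) -> dict:
    return {
        "Z": df[zcols].to_numpy(dtype=float),
        "keys": df[["stay_id", "day"]].to_numpy(dtype=int),
        "los": df["los_label"].to_numpy(dtype=float),
        "mortality": df["mortality_label"].to_numpy(dtype=float),
    }


class SyntheticControlEstimator(BaseEstimator):
    """Stop/continue counterfactual outcomes via embedding-space synthetic
    controls.

    Parameters
    ----------
    k : donors per estimate (default 10).
    ridge_lambda : L2 penalty of the weight solve (the loss carries a unit
        penalty; default 1.0).
    normalize_weights : renormalise ridge weights to sum to one before
        averaging donor labels (raw weights are always recorded).
    segregate : partition pools by day and treatment status; False merges
        everything (ablation).
    outcome : 'los', 'mortality', or 'both'.
    """

    def __init__(
        self,
        k: int = 10,
        ridge_lambda: float = 1.0,
        normalize_weights: bool = True,
        segregate: bool = True,
        outcome: str = "los",
    ):
        self.k = k
        self.ridge_lambda = ridge_lambda
        self.normalize_weights = normalize_weights
        self.segregate = segregate
        self.outcome = outcome

    def fit(self, donor_embeddings: pd.DataFrame, y=None):
        """Index the donor population (a per-day embedding table from
        :meth:`SequenceAutoencoder.transform`)."""
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.outcome not in ("los", "mortality", "both"):
            raise ValueError("outcome must be 'los', 'mortality' or 'both'")
        self.pools_ = build_donor_index(donor_embeddings, segregate=self.segregate)
        self.zcols_ = self.pools_["zcols"]
        return self

    def _pool_for(self, day: int, scenario: str):
        if not self.pools_["segregate"]:
            return self.pools_.get("merged")
        return self.pools_.get((int(day), scenario))

    def predict(self, subject_embeddings: pd.DataFrame) -> pd.DataFrame:
        """Estimate stop and continue outcomes for every antibiotic day.

        Returns one row per (stay, day, scenario, outcome_type).  Rows whose
        donor pool is empty after self-exclusion are flagged
        ``no_estimate`` rather than raising.
        """
        if not hasattr(self, "pools_"):
            raise RuntimeError("estimator is not fitted")
        outcomes = ["los", "mortality"] if self.outcome == "both" else [self.outcome]
        rows = []
        subj = subject_embeddings[
            (subject_embeddings["abx_status"] == 1) | subject_embeddings["is_stop_day"]
        ]
        for day, grp in subj.groupby("day", sort=True):
            Zq = grp[self.zcols_].to_numpy(dtype=float)
            sids = grp["stay_id"].to_numpy()
            for scenario in ("stop", "continue"):
                pool = self._pool_for(int(day), scenario)
                for qi in range(len(grp)):
                    rows.extend(
                        self._estimate_one(
                            Zq[qi], int(sids[qi]), int(day), scenario, pool, outcomes
                        )
                    )
        df = pd.DataFrame(
            rows,
            columns=[
                "stay_id", "day", "scenario", "outcome_type", "estimate",
                "n_donors_available", "donor_ids", "raw_weights", "no_estimate",
            ],
        )
        return df.sort_values(["stay_id", "day", "scenario", "outcome_type"], kind="stable").reset_index(
            drop=True
        )

    def _estimate_one(self, z, stay_id, day, scenario, pool, outcomes):
        if pool is None:
            return [
                (stay_id, day, scenario, oc, np.nan, 0, [], [], True) for oc in outcomes
            ]
        keep = pool["keys"][:, 0] != stay_id  # never one's own donor
        if not keep.any():
            return [
                (stay_id, day, scenario, oc, np.nan, 0, [], [], True) for oc in outcomes
            ]
        Z = pool["Z"][keep]
        keys = pool["keys"][keep]
        idx = select_donors(z, Z, keys, self.k)
        n_avail = int(idx.size)
        w = ridge_weights(z, Z[idx].T, self.ridge_lambda)
        out = []
        for oc in outcomes:
            labels = pool[oc][keep][idx]
            est, _ = estimate_outcome(w, labels, normalize=self.normalize_weights)
            if oc == "mortality":
                est = float(np.clip(est, 0.0, 1.0))
            out.append(
                (
                    stay_id, day, scenario, oc, est, n_avail,
                    [tuple(map(int, keys[j])) for j in idx],
                    [float(v) for v in w], False,
                )
            )
        return out


def estimate_all(
    donor_embeddings: pd.DataFrame,
    subject_embeddings: pd.DataFrame | None = None,
    *,
    k: int = 10,
    ridge_lambda: float = 1.0,
    normalize_weights: bool = True,
    segregate: bool = True,
    outcome: str = "los",
) -> pd.DataFrame:
    """One-shot wrapper: fit on the donor population (defaulting to the full
    dataset, leave-one-out) and estimate for the subjects (defaulting to the
    same population)."""
    est = SyntheticControlEstimator(
        k=k,
        ridge_lambda=ridge_lambda,
        normalize_weights=normalize_weights,
        segregate=segregate,
        outcome=outcome,
    ).fit(donor_embeddings)
    return est.predict(subject_embeddings if subject_embeddings is not None else donor_embeddings)
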
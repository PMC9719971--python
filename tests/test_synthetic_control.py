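import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from abxcease.synthetic_control import (
    SyntheticControlEstimator,
    build_donor_index,
    estimate_outcome,
    ridge_weights,
    select_donors,
)


def _embedding_frame(rows):
    """rows: (stay_id, day, abx, is_stop, label, z...)"""
    recs = []
    for stay_id, day, abx, stop, label, z in rows:
        rec = {"stay_id": stay_id, "day": day, "abx_status": abx, "is_stop_day": stop,
               "los_label": label, "mortality_label": 0}
        for j, v in enumerate(z):
            rec[f"z{j}"] = v
        recs.append(rec)
    return pd.DataFrame(recs)


# ------------------------------------------------------------- ridge weights
def test_ridge_single_donor_closed_form():
    w = ridge_weights(np.array([1.0, 0.0]), np.array([[1.0], [0.0]]), 1.0)
    assert w[0] == pytest.approx(0.5)  # x'z / (x'x + lambda)


def test_ridge_orthonormal_interpolation_limit():
    X = np.eye(3)
    z = X.sum(axis=1)
    np.testing.assert_allclose(ridge_weights(z, X, 0.0), np.ones(3), atol=1e-12)


def test_ridge_matches_numerical_minimiser():
    rng = np.random.default_rng(1)
    z = rng.normal(size=4)
    X = rng.normal(size=(4, 6))

    def loss(w):
        return np.sum((z - X @ w) ** 2) + np.sum(w**2)

    res = minimize(loss, np.zeros(6), method="L-BFGS-B", tol=1e-14)
    np.testing.assert_allclose(ridge_weights(z, X, 1.0), res.x, atol=1e-6)


def test_ridge_validates_inputs():
    with pytest.raises(ValueError):
        ridge_weights(np.array([1.0]), np.array([[1.0]]), -0.5)
    with pytest.raises(ValueError):
        ridge_weights(np.array([np.nan]), np.array([[1.0]]), 1.0)


# ------------------------------------------------------------ donor selection
def test_select_whole_pool_when_k_equals_size():
    rng = np.random.default_rng(0)
    Z = rng.normal(size=(10, 3))
    keys = np.column_stack([np.arange(10), np.ones(10, dtype=int)])
    idx = select_donors(rng.normal(size=3), Z, keys, 10)
    assert sorted(idx) == list(range(10))


def test_coincident_donor_ranks_first_and_ties_break_by_stay_id():
    z = np.array([1.0, 1.0])
    Z = np.array([[0.0, 0.0], [1.0, 1.0], [1.0, 1.0], [2.0, 2.0]])
    keys = np.array([[5, 1], [9, 1], [3, 1], [7, 1]])
    idx = select_donors(z, Z, keys, 2)
    assert keys[idx[0]].tolist() == [3, 1]  # zero distance, smaller stay_id first
    assert keys[idx[1]].tolist() == [9, 1]


def test_knn_matches_exhaustive_sort():
    rng = np.random.default_rng(3)
    Z = rng.normal(size=(25, 3))
    keys = np.column_stack([rng.permutation(25), np.full(25, 2)])
    z = rng.normal(size=3)
    idx = select_donors(z, Z, keys, 5)
    d = np.linalg.norm(Z - z, axis=1)
    brute = sorted(range(25), key=lambda i: (d[i], keys[i, 0], keys[i, 1]))[:5]
    assert idx.tolist() == brute


# ------------------------------------------------------------------ averaging
def test_constant_donor_labels_give_that_label():
    est, _ = estimate_outcome(np.array([0.2, -3.0, 7.0]), np.full(3, 4.5))
    assert est == pytest.approx(4.5)


def test_weighted_average_hand_example():
    est, wn = estimate_outcome(np.array([1.0, 3.0]), np.array([2.0, 6.0]))
    assert est == pytest.approx(5.0)
    np.testing.assert_allclose(wn, [0.25, 0.75])


def test_single_donor_returns_its_label():
    est, _ = estimate_outcome(np.array([0.37]), np.array([8.0]))
    assert est == pytest.approx(8.0)


def test_zero_weight_sum_falls_back_to_uniform():
    est, wn = estimate_outcome(np.array([1.0, -1.0]), np.array([2.0, 6.0]))
    assert est == pytest.approx(4.0)
    np.testing.assert_allclose(wn, [0.5, 0.5])


# ------------------------------------------------------------- donor indexing
def test_stay_membership_across_pools():
    # stay 1: treated days 1-3, stops day 4; stay 2 discharged on antibiotics
    rows = []
    for d in (1, 2, 3):
        rows.append((1, d, 1, False, 6.0, [0.1 * d, 0.0]))
    rows.append((1, 4, 0, True, 6.0, [0.4, 0.0]))
    for d in (1, 2):
        rows.append((2, d, 1, False, 3.0, [0.0, 0.2 * d]))
    pools = build_donor_index(_embedding_frame(rows))
    for d in (1, 2, 3):
        assert 1 in pools[(d, "continue")]["keys"][:, 0]
    assert pools[(4, "stop")]["keys"][:, 0].tolist() == [1]
    # the never-stopping stay appears in no stop pool
    stop_pools = [k for k in pools if isinstance(k, tuple) and k[1] == "stop"]
    assert all(2 not in pools[k]["keys"][:, 0] for k in stop_pools)


def test_degenerate_cohort_empties_late_continue_pools():
    rows = []
    for sid in (1, 2, 3):
        rows.append((sid, 1, 1, False, 4.0, [float(sid), 0.0]))
        rows.append((sid, 2, 0, True, 4.0, [float(sid), 1.0]))
    pools = build_donor_index(_embedding_frame(rows))
    assert (2, "continue") not in pools
    assert (2, "stop") in pools


# ----------------------------------------------------------------- estimator
def _toy_embeddings(n_stays=30, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for sid in range(1, n_stays + 1):
        m = int(rng.integers(1, 6))
        t_days = m + int(rng.integers(0, 3))
        base = rng.normal(size=2)
        for d in range(1, min(t_days, m) + 1):
            rows.append((sid, d, 1, False, 4.0 + m + base[0], list(base + 0.1 * d)))
        if t_days > m:
            rows.append((sid, m + 1, 0, True, 4.0 + m + base[0], list(base + 0.1 * (m + 1))))
    return _embedding_frame(rows)


def test_estimate_count_matches_antibiotic_days():
    emb = _toy_embeddings()
    est = SyntheticControlEstimator(k=3, outcome="los").fit(emb).predict(emb)
    n_abx_days = len(emb)  # every row is an antibiotic day by construction
    assert len(est) == 2 * n_abx_days
    ok = est[~est["no_estimate"]]
    assert (ok["n_donors_available"] <= 3).all()


def test_donor_order_invariance():
    emb = _toy_embeddings(seed=2)
    est1 = SyntheticControlEstimator(k=5, outcome="los").fit(emb).predict(emb.iloc[:8])
    shuffled = emb.sample(frac=1.0, random_state=4).reset_index(drop=True)
    est2 = SyntheticControlEstimator(k=5, outcome="los").fit(shuffled).predict(emb.iloc[:8])
    merged = est1.merge(est2, on=["stay_id", "day", "scenario", "outcome_type"])
    np.testing.assert_allclose(merged["estimate_x"], merged["estimate_y"], equal_nan=True)


def test_large_lambda_limit():
    """As lambda -> inf, raw weights shrink proportionally to each donor's
    projection on the subject (w_j ~ x_j'z / lambda); with equal projections
    the normalised estimate degenerates to the plain donor mean."""
    rng = np.random.default_rng(3)
    z = rng.normal(size=3)
    X = rng.normal(size=(3, 5))
    w = ridge_weights(z, X, 1e12)
    np.testing.assert_allclose(w / np.abs(w).max(), (X.T @ z) / np.abs(X.T @ z).max(), atol=1e-6)
    # equal-projection donors: uniform weights, estimate = donor mean
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    Xeq = np.column_stack([u + v - (v @ u) * u for v in rng.normal(size=(4, 3)) * 0.1])
    weq = ridge_weights(u, Xeq, 1e12)
    labels = rng.normal(size=4) + 5.0
    est, _ = estimate_outcome(weq, labels)
    assert est == pytest.approx(labels.mean(), rel=1e-6)


def test_k_equal_one_returns_nearest_donor_label():
    emb = _toy_embeddings(seed=5)
    subj = emb.iloc[[0]]
    est = SyntheticControlEstimator(k=1, outcome="los").fit(emb).predict(subj)
    row = est[(est["scenario"] == "continue") & ~est["no_estimate"]].iloc[0]
    donor = row["donor_ids"][0]
    assert row["estimate"] == pytest.approx(
        emb.set_index(["stay_id", "day"]).loc[tuple(donor), "los_label"]
    )


def test_self_exclusion_and_unrelated_stay_removal():
    emb = _toy_embeddings(seed=6)
    subj = emb[emb["stay_id"] == 1]
    est1 = SyntheticControlEstimator(k=3, outcome="los").fit(emb).predict(subj)
    used = {d[0] for row in est1[~est1["no_estimate"]]["donor_ids"] for d in row}
    assert 1 not in used  # never one's own donor
    unrelated = (set(emb["stay_id"]) - used - {1}).pop()
    emb2 = emb[emb["stay_id"] != unrelated]
    est2 = SyntheticControlEstimator(k=3, outcome="los").fit(emb2).predict(subj)
    merged = est1.merge(est2, on=["stay_id", "day", "scenario", "outcome_type"])
    np.testing.assert_allclose(merged["estimate_x"], merged["estimate_y"], equal_nan=True)


def test_ablation_merges_pools_across_days_and_scenarios():
    emb = _toy_embeddings(seed=7)
    sc = SyntheticControlEstimator(k=4, segregate=False, outcome="los").fit(emb)
    est = sc.predict(emb.iloc[[0]])
    stop_row = est[est["scenario"] == "stop"].iloc[0]
    cont_row = est[est["scenario"] == "continue"].iloc[0]
    assert not stop_row["no_estimate"] and not cont_row["no_estimate"]
    assert stop_row["donor_ids"] == cont_row["donor_ids"]  # one merged pool


def test_k_larger_than_pool_saturates():
    emb = _toy_embeddings(n_stays=6, seed=8)
    est = SyntheticControlEstimator(k=50, outcome="los").fit(emb).predict(emb)
    ok = est[~est["no_estimate"]]
    assert (ok["n_donors_available"] < 50).all()


def test_empty_pool_is_flagged_not_raised():
    rows = [(1, 1, 1, False, 5.0, [0.0, 0.0]), (2, 1, 1, False, 6.0, [1.0, 1.0])]
    emb = _embedding_frame(rows)
    est = SyntheticControlEstimator(k=2, outcome="los").fit(emb).predict(emb)
    stop_rows = est[est["scenario"] == "stop"]
    assert stop_rows["no_estimate"].all()
    assert np.isnan(stop_rows["estimate"]).all()


def test_mortality_estimates_clamped_to_unit_interval():
    rng = np.random.default_rng(0)
    rows = []
    for sid in range(1, 12):
        rows.append((sid, 1, 1, False, 5.0, list(rng.normal(size=2))))
    emb = _embedding_frame(rows)
    emb["mortality_label"] = rng.integers(0, 2, size=len(emb))
    est = SyntheticControlEstimator(k=5, outcome="mortality").fit(emb).predict(emb)
    ok = est[~est["no_estimate"]]
    assert ((ok["estimate"] >= 0) & (ok["estimate"] <= 1)).all()
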
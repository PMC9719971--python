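import numpy as np
import pytest

from abxcease.autoencoder import SequenceAutoencoder, build_model_inputs, combined_loss
from abxcease.simulate import SimConfig
from tests.conftest import make_timeline, prepare_cohort


def _split_lists(processed, split):
    by_id = {tl.stay_id: tl for tl in processed}
    return {k: [by_id[s] for s in ids if s in by_id] for k, ids in split.items()}


@pytest.fixture(scope="module")
def tiny_model(small_cohort):
    """A quickly trained LOS model shared by inference-path tests."""
    _, processed, split = small_cohort
    parts = _split_lists(processed, split)
    model = SequenceAutoencoder(
        task="los", embedding_dim=6, hidden_size=10, epochs=3, batch_size=32, seed=0
    )
    model.fit(parts["train"], validation_data=parts["val"])
    return model, parts


# ------------------------------------------------------------- combined loss
def test_combined_loss_hand_example():
    x = np.array([[1.0, 2.0], [3.0, 4.0]])
    x_tilde = np.array([[1.0, 2.0], [3.0, 0.0]])
    total, lr, ls = combined_loss(x, x_tilde, np.ones_like(x), 5.0, 3.0, "los")
    assert lr == pytest.approx(2.0)  # sqrt(16/4)
    assert ls == pytest.approx(2.0)
    assert total == pytest.approx(4.0)


def test_combined_loss_perfect_fit_is_zero():
    x = np.random.default_rng(0).normal(size=(3, 4))
    total, _, _ = combined_loss(x, x, np.ones_like(x), 2.0, 2.0, "los")
    assert total == 0.0


def test_combined_loss_all_missing_keeps_only_supervised_term():
    x = np.ones((2, 2))
    total, lr, ls = combined_loss(x, x + 10, np.zeros_like(x), 1.0, 0.0, "los", (1.0, 2.0))
    assert lr == 0.0
    assert total == pytest.approx(2.0 * 1.0)


def test_combined_loss_mortality_is_bce():
    total, _, ls = combined_loss(
        np.zeros((1, 1)), np.zeros((1, 1)), np.ones((1, 1)), [1.0], [0.5], "mortality"
    )
    assert ls == pytest.approx(-np.log(0.5))


def test_non_finite_loss_aborts():
    with pytest.raises(FloatingPointError):
        combined_loss(np.ones((1, 1)), np.full((1, 1), np.inf), np.ones((1, 1)), 1.0, 1.0, "los")


# ------------------------------------------------------------------ training
def test_gradients_match_finite_differences():
    """Exact BPTT check of the full combined-loss computation graph."""
    tls = [make_timeline(i, [1] * t, n_features=3, los=4.0 + i, mortality=i % 2, seed=3)
           for i, t in [(1, 2), (2, 4), (3, 3)]]
    for tl in tls:
        tl.missing_mask = (np.random.default_rng(tl.stay_id).random(tl.features.shape) < 0.3).astype(np.uint8)
    X, Xtgt, obs, lengths, ylos, ymort = build_model_inputs(tls)
    m = SequenceAutoencoder(task="los", embedding_dim=3, hidden_size=4, num_layers=2, seed=1)
    m._validate()
    m.n_features_ = Xtgt.shape[2]
    m.n_inputs_ = X.shape[2]
    params = m._init_params(np.random.default_rng(2), m.n_inputs_)

    def loss(p):
        tot, *_ = m._batch_step(p, X, Xtgt, obs, lengths, ylos, np.random.default_rng(5))
        return tot

    _, _, _, grads = m._batch_step(params, X, Xtgt, obs, lengths, ylos, np.random.default_rng(5))
    rng = np.random.default_rng(7)

    def check(p, g):
        for k in p:
            if isinstance(p[k], dict):
                check(p[k], g[k])
            else:
                flat, gflat = p[k].ravel(), g[k].ravel()
                for ix in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                    eps, old = 1e-6, flat[ix]
                    flat[ix] = old + eps
                    lp = loss(params)
                    flat[ix] = old - eps
                    lm = loss(params)
                    flat[ix] = old
                    num = (lp - lm) / (2 * eps)
                    assert abs(num - gflat[ix]) < 1e-6 + 1e-3 * max(abs(num), abs(gflat[ix]))

    check(params, grads)


def test_epoch_selection_keeps_best_validation_model(tiny_model):
    model, _ = tiny_model
    assert len(model.loss_history_) == 3
    vals = [h["val_metric"] for h in model.loss_history_]
    assert model.best_val_metric_ == min(vals)  # rmse: lower is better
    assert model.best_epoch_ == int(np.argmin(vals))


def test_training_is_deterministic_under_seed(small_cohort):
    _, processed, split = small_cohort
    parts = _split_lists(processed, split)
    kwargs = dict(task="los", embedding_dim=4, hidden_size=6, epochs=2, seed=5)
    h1 = SequenceAutoencoder(**kwargs).fit(parts["train"], validation_data=parts["val"]).loss_history_
    h2 = SequenceAutoencoder(**kwargs).fit(parts["train"], validation_data=parts["val"]).loss_history_
    assert h1 == h2


def test_missing_validation_set_is_an_error(small_cohort):
    _, processed, split = small_cohort
    parts = _split_lists(processed, split)
    with pytest.raises(ValueError, match="validation"):
        SequenceAutoencoder(epochs=1).fit(parts["train"], validation_data=[])


# ----------------------------------------------------------------- inference
def test_embedding_uses_only_the_past(tiny_model):
    model, parts = tiny_model
    a = parts["test"][0]
    import copy

    b = copy.deepcopy(a)
    if b.n_days >= 2:
        b.features[-1] += 10.0  # diverge after day t
        t = b.n_days - 1
        np.testing.assert_array_equal(model.encode_day(a, t), model.encode_day(b, t))
        assert not np.array_equal(model.encode_day(a, b.n_days), model.encode_day(b, b.n_days))


def test_encode_day_bounds_and_shape(tiny_model):
    model, parts = tiny_model
    tl = parts["test"][0]
    with pytest.raises(IndexError):
        model.encode_day(tl, tl.n_days + 1)
    with pytest.raises(IndexError):
        model.encode_day(tl, 0)
    z = model.encode_day(tl, 1)
    assert z.shape == (model.embedding_dim,) and np.isfinite(z).all()


def test_transform_emits_one_embedding_per_stay_day(tiny_model):
    model, parts = tiny_model
    emb = model.transform(parts["test"])
    expected = sum(tl.n_days for tl in parts["test"])
    assert len(emb) == expected
    assert not emb.duplicated(["stay_id", "day"]).any()
    zcols = [c for c in emb.columns if c.startswith("z")]
    assert len(zcols) == model.embedding_dim


def test_head_predict_linearity_and_range(small_cohort):
    _, processed, split = small_cohort
    parts = _split_lists(processed, split)
    m = SequenceAutoencoder(task="mortality", embedding_dim=4, hidden_size=6, epochs=1, seed=3)
    m.fit(parts["train"], validation_data=parts["val"])
    bias = m.params_["head"]["b"][0]
    assert m.head_predict(np.zeros(4)) == pytest.approx(1 / (1 + np.exp(-bias)))
    probs = m.head_predict(np.random.default_rng(0).normal(size=(50, 4)))
    assert ((probs >= 0) & (probs <= 1)).all()
    with pytest.raises(ValueError):
        m.head_predict(np.zeros(5))


def test_checkpoint_round_trip_is_bit_identical(tiny_model, tmp_path):
    model, parts = tiny_model
    path = tmp_path / "model.npz"
    model.save(path)
    loaded = SequenceAutoencoder.load(path)
    a = model.transform(parts["test"][:3])
    b = loaded.transform(parts["test"][:3])
    zcols = [c for c in a.columns if c.startswith("z")]
    np.testing.assert_array_equal(a[zcols].to_numpy(), b[zcols].to_numpy())


def test_training_beats_untrained_reconstruction(small_cohort):
    """After training, the reconstruction term is below that of untrained
    models across random initialisations (noisy autoregressive-ish inputs)."""
    _, processed, split = small_cohort
    parts = _split_lists(processed, split)
    trained = SequenceAutoencoder(task="los", embedding_dim=6, hidden_size=10, epochs=4, seed=0)
    trained.fit(parts["train"], validation_data=parts["val"])
    final_lr = trained.loss_history_[-1]["Lr"]
    X, Xtgt, obs, lengths, ylos, _ = build_model_inputs(parts["train"])
    for init_seed in range(10):
        m = SequenceAutoencoder(task="los", embedding_dim=6, hidden_size=10, epochs=1, seed=init_seed)
        m._validate()
        m.n_features_ = Xtgt.shape[2]
        m.n_inputs_ = X.shape[2]
        params = m._init_params(np.random.default_rng(init_seed), m.n_inputs_)
        _, lr_untrained, _, _ = m._batch_step(
            params, X, Xtgt, obs, lengths, ylos, np.random.default_rng(0)
        )
        assert final_lr < lr_untrained


def test_linear_probe_beats_mean_baseline(small_cohort):
    """The supervised head must out-predict the train-mean LOS baseline."""
    _, processed, split = small_cohort
    parts = _split_lists(processed, split)
    m = SequenceAutoencoder(
        task="los", embedding_dim=8, hidden_size=16, epochs=30, learning_rate=3e-3, seed=1
    )
    m.fit(parts["train"], validation_data=parts["val"])
    y_val = np.array([tl.los_label for tl in parts["val"]])
    y_mean = np.mean([tl.los_label for tl in parts["train"]])
    baseline = np.sqrt(np.mean((y_val - y_mean) ** 2))
    assert m.best_val_metric_ < baseline


def test_separable_mortality_cohort_reaches_high_auroc():
    """On a cohort where death is sharply determined by observable severity,
    the supervised embedding head should discriminate well."""
    _, processed, split = prepare_cohort(
        SimConfig(n_stays=800, seed=42, mortality_severity_coef=6.0, feature_noise_sd=0.1)
    )
    parts = _split_lists(processed, split)
    m = SequenceAutoencoder(task="mortality", epochs=10, hidden_size=32, embedding_dim=16, seed=0)
    m.fit(parts["train"], validation_data=parts["val"])
    assert m.best_val_metric_ > 0.85
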
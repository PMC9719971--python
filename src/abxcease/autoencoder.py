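"""Task-specific bi-directional recurrent sequence autoencoder.

The encoder reads a patient-day feature sequence x<1..T> (values, missing
indicators and treatment covariates), produces a fixed-length embedding z,
and is trained with a combined loss: a reconstruction term Lr (RMSE between
the decoder output, emitted in reversed order, and the observed input cells)
plus a supervised term Ls from a linear head on z (RMSE against the LOS
label, or binary cross-entropy against mortality).  The supervised term makes
the embedding space a good linear predictor of the outcome, which the donor
weighting downstream relies on.

Implemented directly in NumPy (exact backpropagation through time, Adam), so
training and inference are deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.metrics import roc_auc_score

from ._rnn import Adam, init_lstm, lstm_backward, lstm_forward, reverse_padded, tree_add_
from .preprocess import StayTimeline

__all__ = ["SequenceAutoencoder", "combined_loss", "build_model_inputs"]

_EXTRA_CHANNELS = 4  # abx status, scaled cumulative course, retreatment, scaled age


def build_model_inputs(timelines: list[StayTimeline]):
    """Pack timelines into padded arrays.

    Model input per day: [normalised features | missing indicators |
    abx status, cumulative course / 21, retreatment, standardised-ish age].
    Reconstruction targets cover only the feature-value block, masked to
    observed cells.
    """
    if not timelines:
        raise ValueError("no timelines given")
    n_feat = timelines[0].features.shape[1]
    lengths = np.array([tl.n_days for tl in timelines], dtype=int)
    B, T = len(timelines), int(lengths.max())
    X = np.zeros((B, T, 2 * n_feat + _EXTRA_CHANNELS))
    Xtgt = np.zeros((B, T, n_feat))
    obs = np.zeros((B, T, n_feat))
    y_los = np.array([tl.los_label for tl in timelines], dtype=float)
    y_mort = np.array([tl.mortality_label for tl in timelines], dtype=float)
    for i, tl in enumerate(timelines):
        t = tl.n_days
        age = tl.age_at_admission
        age_z = 0.0 if not np.isfinite(age) else (age - 60.0) / 20.0
        X[i, :t, :n_feat] = tl.features
        X[i, :t, n_feat : 2 * n_feat] = tl.missing_mask
        X[i, :t, 2 * n_feat + 0] = tl.abx_status
        X[i, :t, 2 * n_feat + 1] = tl.cum_treatment_len / 21.0
        X[i, :t, 2 * n_feat + 2] = float(tl.course.retreatment)
        X[i, :t, 2 * n_feat + 3] = age_z
        Xtgt[i, :t] = tl.features
        obs[i, :t] = 1.0 - tl.missing_mask
    return X, Xtgt, obs, lengths, y_los, y_mort


def combined_loss(x, x_tilde, obs_mask, y, y_hat, task, loss_weights=(1.0, 1.0)):
    """w_r * Lr + w_s * Ls on aligned arrays.

    ``x_tilde`` must already be aligned to ``x`` (same time order); Lr is the
    RMSE over observed cells only and contributes 0 when no cell is observed.
    Ls is the RMSE of the head output for the LOS task, binary cross-entropy
    (on probabilities) for mortality.
    """
    x = np.asarray(x, dtype=float)
    x_tilde = np.asarray(x_tilde, dtype=float)
    obs_mask = np.asarray(obs_mask, dtype=float)
    y = np.atleast_1d(np.asarray(y, dtype=float))
    y_hat = np.atleast_1d(np.asarray(y_hat, dtype=float))
    w_r, w_s = loss_weights
    n_obs = obs_mask.sum()
    lr = float(np.sqrt((((x_tilde - x) * obs_mask) ** 2).sum() / n_obs)) if n_obs > 0 else 0.0
    if task == "los":
        ls = float(np.sqrt(np.mean((y - y_hat) ** 2)))
    elif task == "mortality":
        p = np.clip(y_hat, 1e-12, 1 - 1e-12)
        ls = float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
    else:
        raise ValueError(f"unknown task {task!r}")
    total = w_r * lr + w_s * ls
    if not np.isfinite(total):
        raise FloatingPointError(f"non-finite loss (Lr={lr}, Ls={ls})")
    return total, lr, ls


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class SequenceAutoencoder(BaseEstimator):
    """Bi-directional LSTM sequence autoencoder with a linear outcome head.

    Parameters
    ----------
    task : 'los' or 'mortality'.
    embedding_dim, hidden_size, num_layers : architecture sizes.
    learning_rate, batch_size, epochs : optimisation settings; after every
        epoch the validation selection metric is evaluated and the best
        epoch's weights are kept (RMSE for LOS, AUROC for mortality).
    loss_weights : (w_r, w_s) weighting of reconstruction vs supervision.
    supervision : 'final' applies Ls to the final-day embedding (one label
        per stay); 'per_day' additionally supervises the embedding of one
        uniformly drawn prefix day per stay and step.
    seed : controls initialisation and batch order; fixed seed gives
        bit-identical training runs.
    """

    def __init__(
        self,
        task: str = "los",
        embedding_dim: int = 32,
        hidden_size: int = 64,
        num_layers: int = 1,
        learning_rate: float = 1e-3,
        batch_size: int = 64,
        epochs: int = 50,
        loss_weights: tuple[float, float] = (1.0, 1.0),
        supervision: str = "final",
        selection_metric: str | None = None,
        seed: int = 0,
    ):
        self.task = task
        self.embedding_dim = embedding_dim
        self.hidden_size = hidden_size
        self.num_layers = num_layers
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.loss_weights = loss_weights
        self.supervision = supervision
        self.selection_metric = selection_metric
        self.seed = seed

    # ------------------------------------------------------------------ setup
    def _validate(self):
        if self.task not in ("los", "mortality"):
            raise ValueError("task must be 'los' or 'mortality'")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.embedding_dim < 2:
            raise ValueError("embedding_dim must be >= 2")
        if self.num_layers < 1:
            raise ValueError("num_layers must be >= 1")
        if self.supervision not in ("final", "per_day"):
            raise ValueError("supervision must be 'final' or 'per_day'")
        metric = self.selection_metric or ("rmse" if self.task == "los" else "auroc")
        if metric not in ("rmse", "auroc"):
            raise ValueError("selection_metric must be 'rmse' or 'auroc'")
        return metric

    def _init_params(self, rng, d_in):
        H, E = self.hidden_size, self.embedding_dim
        params = {}
        d = d_in
        for l in range(self.num_layers):
            params[f"enc_f{l}"] = init_lstm(rng, d, H)
            params[f"enc_b{l}"] = init_lstm(rng, d, H)
            d = 2 * H
        from ._rnn import glorot

        params["proj"] = {"W": glorot(rng, 2 * H, E, (2 * H, E)), "b": np.zeros(E)}
        d = E
        for l in range(self.num_layers):
            params[f"dec{l}"] = init_lstm(rng, d, H)
            d = H
        params["out"] = {
            "W": rng.uniform(-np.sqrt(6 / (H + self.n_features_)), np.sqrt(6 / (H + self.n_features_)), (H, self.n_features_)),
            "b": np.zeros(self.n_features_),
        }
        params["head"] = {"w": rng.normal(0.0, 0.1, E), "b": np.zeros(1)}
        return params

    # ------------------------------------------------------- forward/backward
    def _encoder_forward(self, params, X, lengths):
        caches = []
        inp = X
        B = X.shape[0]
        for l in range(self.num_layers):
            Hf, cf = lstm_forward(params[f"enc_f{l}"], inp, lengths)
            Hb_rev, cb = lstm_forward(params[f"enc_b{l}"], reverse_padded(inp, lengths), lengths)
            Hb = reverse_padded(Hb_rev, lengths)
            caches.append((cf, cb))
            inp = np.concatenate([Hf, Hb], axis=2)
        hf_last = Hf[np.arange(B), lengths - 1]
        hb_first = Hb[:, 0]
        cat = np.concatenate([hf_last, hb_first], axis=1)
        z = cat @ params["proj"]["W"] + params["proj"]["b"]
        caches.append(cat)
        return z, caches

    def _encoder_backward(self, params, X, lengths, caches, dz, grads):
        B, T = X.shape[:2]
        H = self.hidden_size
        cat = caches[-1]
        grads["proj"]["W"] += cat.T @ dz
        grads["proj"]["b"] += dz.sum(axis=0)
        dcat = dz @ params["proj"]["W"].T
        dHf = np.zeros((B, T, H))
        dHb = np.zeros((B, T, H))
        dHf[np.arange(B), lengths - 1] = dcat[:, :H]
        dHb[:, 0] = dcat[:, H:]
        for l in range(self.num_layers - 1, -1, -1):
            cf, cb = caches[l]
            dXf, gf = lstm_backward(params[f"enc_f{l}"], cf, dHf)
            dXb_rev, gb = lstm_backward(params[f"enc_b{l}"], cb, reverse_padded(dHb, lengths))
            dXb = reverse_padded(dXb_rev, lengths)
            tree_add_(grads[f"enc_f{l}"], gf)
            tree_add_(grads[f"enc_b{l}"], gb)
            dinp = dXf + dXb
            if l > 0:
                dHf = dinp[:, :, :H]
                dHb = dinp[:, :, H:]
        return None

    def _decoder_forward(self, params, z, T, lengths):
        B = z.shape[0]
        inp = np.repeat(z[:, None, :], T, axis=1)
        caches = []
        for l in range(self.num_layers):
            Hd, c = lstm_forward(params[f"dec{l}"], inp, lengths)
            caches.append(c)
            inp = Hd
        xrec = Hd @ params["out"]["W"] + params["out"]["b"]
        return xrec, Hd, caches

    def _decoder_backward(self, params, caches, Hd, dxrec, lengths, grads):
        B, T, _ = dxrec.shape
        grads["out"]["W"] += Hd.reshape(B * T, -1).T @ dxrec.reshape(B * T, -1)
        grads["out"]["b"] += dxrec.sum(axis=(0, 1))
        dH = dxrec @ params["out"]["W"].T
        for l in range(self.num_layers - 1, -1, -1):
            dX, g = lstm_backward(params[f"dec{l}"], caches[l], dH)
            tree_add_(grads[f"dec{l}"], g)
            dH = dX
        return dH.sum(axis=1)  # gradient wrt z via the repeated decoder input

    def _head(self, params, z):
        lin = z @ params["head"]["w"] + params["head"]["b"][0]
        return _sigmoid(lin) if self.task == "mortality" else lin

    def _batch_step(self, params, Xb, Xtgtb, obsb, lengths, yb, rng):
        """Forward + backward on one batch; returns (loss, lr, ls, grads)."""
        w_r, w_s = self.loss_weights
        B, T = Xb.shape[:2]
        from ._rnn import tree_zeros_like

        grads = tree_zeros_like(params)
        z, enc_caches = self._encoder_forward(params, Xb, lengths)

        # reconstruction branch (decoder emits reversed order)
        xrec, Hd, dec_caches = self._decoder_forward(params, z, T, lengths)
        xtgt_rev = reverse_padded(Xtgtb, lengths)
        obs_rev = reverse_padded(obsb, lengths)
        resid = (xrec - xtgt_rev) * obs_rev
        n_obs = obs_rev.sum()
        lr_val = float(np.sqrt((resid**2).sum() / n_obs)) if n_obs > 0 else 0.0

        # supervised branch
        if self.supervision == "per_day":
            sup_lengths = rng.integers(1, lengths + 1)
            z_sup, sup_caches = self._encoder_forward(params, Xb, sup_lengths)
        else:
            sup_lengths, z_sup, sup_caches = lengths, z, enc_caches
        lin = z_sup @ params["head"]["w"] + params["head"]["b"][0]
        if self.task == "los":
            ls_val = float(np.sqrt(np.mean((lin - yb) ** 2)))
            dlin = w_s * (lin - yb) / (B * max(ls_val, 1e-12))
        else:
            p = _sigmoid(lin)
            pc = np.clip(p, 1e-12, 1 - 1e-12)
            ls_val = float(-np.mean(yb * np.log(pc) + (1 - yb) * np.log(1 - pc)))
            dlin = w_s * (p - yb) / B
        total = w_r * lr_val + w_s * ls_val
        if not np.isfinite(total):
            raise FloatingPointError(
                f"non-finite training loss (Lr={lr_val}, Ls={ls_val}); try a lower learning rate"
            )

        # backward: reconstruction
        if n_obs > 0 and lr_val > 1e-12:
            dxrec = w_r * resid / (n_obs * lr_val)
        else:
            dxrec = np.zeros_like(xrec)
        dz = self._decoder_backward(params, dec_caches, Hd, dxrec, lengths, grads)
        # backward: head
        grads["head"]["w"] += z_sup.T @ dlin
        grads["head"]["b"] += dlin.sum(keepdims=True)
        dz_sup = np.outer(dlin, params["head"]["w"])
        if self.supervision == "per_day":
            self._encoder_backward(params, Xb, lengths, enc_caches, dz, grads)
            self._encoder_backward(params, Xb, sup_lengths, sup_caches, dz_sup, grads)
        else:
            self._encoder_backward(params, Xb, lengths, enc_caches, dz + dz_sup, grads)
        return total, lr_val, ls_val, grads

    # -------------------------------------------------------------------- fit
    def fit(self, timelines, y=None, *, validation_data=None, sample_index=None):
        """Train on ``timelines`` (list of normalised StayTimeline).

        ``validation_data`` (required) drives epoch selection.
        ``sample_index`` is an integer index into ``timelines`` defining the
        sampling distribution (e.g. the mortality oversampling index).
        """
        metric_name = self._validate()
        if not validation_data:
            raise ValueError("validation_data is required for epoch selection")
        X, Xtgt, obs, lengths, y_los, y_mort = build_model_inputs(list(timelines))
        y_train = y_los if self.task == "los" else y_mort
        Xv, _, _, len_v, yv_los, yv_mort = build_model_inputs(list(validation_data))
        y_val = yv_los if self.task == "los" else yv_mort

        self.n_features_ = Xtgt.shape[2]
        self.n_inputs_ = X.shape[2]
        rng = np.random.default_rng(self.seed)
        params = self._init_params(rng, self.n_inputs_)
        opt = Adam(params, lr=self.learning_rate)
        index = np.arange(len(timelines)) if sample_index is None else np.asarray(sample_index, dtype=int)

        best_metric, best_params, history = None, None, []
        for epoch in range(self.epochs):
            order = rng.permutation(index)
            tot = lr_sum = ls_sum = 0.0
            nb = 0
            for start in range(0, order.size, self.batch_size):
                sel = order[start : start + self.batch_size]
                tmax = int(lengths[sel].max())
                loss, lr_v, ls_v, grads = self._batch_step(
                    params, X[sel, :tmax], Xtgt[sel, :tmax], obs[sel, :tmax], lengths[sel], y_train[sel], rng
                )
                opt.step(params, grads)
                tot += loss; lr_sum += lr_v; ls_sum += ls_v; nb += 1
            self.params_ = params
            val_metric = self._validation_metric(params, Xv, len_v, y_val, metric_name)
            history.append(
                {"epoch": epoch, "train_loss": tot / nb, "Lr": lr_sum / nb, "Ls": ls_sum / nb,
                 "val_metric": val_metric, "metric": metric_name}
            )
            better = (
                best_metric is None
                or (metric_name == "rmse" and val_metric < best_metric)
                or (metric_name == "auroc" and val_metric > best_metric)
            )
            if better:
                best_metric = val_metric
                best_params = {k: _copy_tree(v) for k, v in params.items()}
                best_epoch = epoch
        self.params_ = best_params
        self.best_epoch_ = best_epoch
        self.best_val_metric_ = best_metric
        self.loss_history_ = history
        self.selection_metric_ = metric_name
        return self

    def _validation_metric(self, params, Xv, len_v, y_val, metric_name):
        z, _ = self._encoder_forward(params, Xv, len_v)
        pred = self._head(params, z)
        if metric_name == "rmse":
            return float(np.sqrt(np.mean((pred - y_val) ** 2)))
        if len(np.unique(y_val)) < 2:
            warnings.warn("single-class validation labels; using negated BCE for selection")
            pc = np.clip(pred, 1e-12, 1 - 1e-12)
            return float(np.mean(y_val * np.log(pc) + (1 - y_val) * np.log(1 - pc)))
        return float(roc_auc_score(y_val, pred))

    # -------------------------------------------------------------- inference
    def _check_fitted(self):
        if not hasattr(self, "params_") or self.params_ is None:
            raise RuntimeError("model is not fitted")

    def encode_day(self, timeline: StayTimeline, day: int) -> np.ndarray:
        """Embedding of one patient-day, computed from days 1..day only."""
        self._check_fitted()
        if not 1 <= day <= timeline.n_days:
            raise IndexError(f"day {day} outside stay of {timeline.n_days} days")
        X, _, _, lengths, _, _ = build_model_inputs([timeline])
        z, _ = self._encoder_forward(self.params_, X[:, :day], np.array([day]))
        return z[0]

    def transform(self, timelines) -> "pd.DataFrame":
        """Per-day embeddings for every day of every stay.

        Returns a DataFrame with stay_id, day, abx_status, the stay outcome
        labels and embedding columns z0..z{E-1}.  Each day's embedding uses
        only that stay's days 1..t (no future leakage): the bidirectional
        encoder is re-run on each prefix.
        """
        import pandas as pd

        self._check_fitted()
        timelines = list(timelines)
        X, _, _, lengths, y_los, y_mort = build_model_inputs(timelines)
        E = self.embedding_dim
        rows_sid, rows_day, rows_abx, Z = [], [], [], []
        for p in range(1, int(lengths.max()) + 1):
            sel = np.nonzero(lengths >= p)[0]
            z, _ = self._encoder_forward(self.params_, X[sel, :p], np.full(sel.size, p))
            Z.append(z)
            rows_sid.extend(timelines[i].stay_id for i in sel)
            rows_day.extend([p] * sel.size)
            rows_abx.extend(int(timelines[i].abx_status[p - 1]) for i in sel)
        Z = np.concatenate(Z, axis=0)
        df = pd.DataFrame({"stay_id": rows_sid, "day": rows_day, "abx_status": rows_abx})
        label_map_los = {tl.stay_id: tl.los_label for tl in timelines}
        label_map_mort = {tl.stay_id: tl.mortality_label for tl in timelines}
        stop_map = {tl.stay_id: tl.course.stop_day for tl in timelines}
        df["los_label"] = df["stay_id"].map(label_map_los)
        df["mortality_label"] = df["stay_id"].map(label_map_mort)
        df["is_stop_day"] = [
            stop_map[s] is not None and d == stop_map[s] for s, d in zip(df["stay_id"], df["day"])
        ]
        for j in range(E):
            df[f"z{j}"] = Z[:, j]
        return df.sort_values(["stay_id", "day"], kind="stable").reset_index(drop=True)

    def predict(self, timelines) -> np.ndarray:
        """Linear-head outcome prediction from the final-day embedding
        (probability of death for the mortality task)."""
        self._check_fitted()
        X, _, _, lengths, _, _ = build_model_inputs(list(timelines))
        z, _ = self._encoder_forward(self.params_, X, lengths)
        return self._head(self.params_, z)

    def head_predict(self, z: np.ndarray) -> np.ndarray:
        """Outcome estimate from an embedding matrix or vector."""
        self._check_fitted()
        z = np.atleast_2d(np.asarray(z, dtype=float))
        if z.shape[1] != self.embedding_dim:
            raise ValueError(f"embedding dim {z.shape[1]} != {self.embedding_dim}")
        out = self._head(self.params_, z)
        return out if out.size > 1 else float(out[0])

    # ------------------------------------------------------------ persistence
    def save(self, path) -> None:
        self._check_fitted()
        flat = {}

        def _flatten(prefix, tree):
            for k, v in tree.items():
                if isinstance(v, dict):
                    _flatten(f"{prefix}{k}/", v)
                else:
                    flat[f"{prefix}{k}"] = v

        _flatten("", self.params_)
        meta = json.dumps(
            {
                "config": self.get_params(),
                "n_features": int(self.n_features_),
                "n_inputs": int(self.n_inputs_),
                "best_epoch": int(self.best_epoch_),
                "best_val_metric": float(self.best_val_metric_),
                "loss_history": self.loss_history_,
            }
        )
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **flat)

    @classmethod
    def load(cls, path) -> "SequenceAutoencoder":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            cfg = meta["config"]
            cfg["loss_weights"] = tuple(cfg["loss_weights"])
            model = cls(**cfg)
            params: dict = {}
            for key in data.files:
                if key == "__meta__":
                    continue
                parts = key.split("/")
                node = params
                for p in parts[:-1]:
                    node = node.setdefault(p, {})
                node[parts[-1]] = data[key].copy()
        model.params_ = params
        model.n_features_ = meta["n_features"]
        model.n_inputs_ = meta["n_inputs"]
        model.best_epoch_ = meta["best_epoch"]
        model.best_val_metric_ = meta["best_val_metric"]
        model.loss_history_ = meta["loss_history"]
        model.selection_metric_ = meta["config"].get("selection_metric") or (
            "rmse" if cfg["task"] == "los" else "auroc"
        )
        return model


def _copy_tree(tree):
    if isinstance(tree, dict):
        return {k: _copy_tree(v) for k, v in tree.items()}
    return tree.copy()
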
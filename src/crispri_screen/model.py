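"""Locally connected sequence-to-fitness regression.

The regressor maps a one-hot-encoded DNA window (flattened position-major,
channel order A,C,G,T) to a predicted log2 fold change through a sparsely
connected feed-forward network: hidden layers of 40, 20, 10 and 5 tanh
units, where unit i of a layer sees only the 5 "proximal" units of the
previous layer — the window floor(i * N_prev / N) + {-2..2}, clipped at the
boundaries — followed by a dense linear scalar output.  Because the input
is flattened position-major, proximity in every layer respects sequence
order, so the network is a hierarchy of overlapping local receptive fields
rather than a dense map.  Training minimizes mean squared error with L2
weight decay using Adam, stopping early when the validation loss has not
improved for ``patience`` epochs (the best-epoch weights are restored).

The estimator follows the scikit-learn protocol (``get_params`` /
``set_params`` / ``fit`` / ``predict``, fitted attributes with trailing
underscores) and composes with sklearn model selection.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def one_hot_encode(sequence: str) -> np.ndarray:
    """One-hot encode an ACGT string as a (length, 4) matrix (A,C,G,T)."""
    idx = np.empty(len(sequence), dtype=np.intp)
    for i, c in enumerate(sequence):
        if c not in _BASE_INDEX:
            raise ValueError(f"non-ACGT character {c!r} at position {i}")
        idx[i] = _BASE_INDEX[c]
    out = np.zeros((len(sequence), 4))
    out[np.arange(len(sequence)), idx] = 1.0
    return out


def one_hot_decode(matrix: np.ndarray) -> str:
    return "".join(BASES[i] for i in np.asarray(matrix).reshape(-1, 4).argmax(axis=1))


def encode_batch(sequences) -> np.ndarray:
    """Encode equal-length sequences as a (n, 4*length) design matrix."""
    seqs = list(sequences)
    if not seqs:
        raise ValueError("no sequences")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences have unequal lengths")
    X = np.zeros((len(seqs), L * 4))
    for i, s in enumerate(seqs):
        X[i] = one_hot_encode(s).reshape(-1)
    return X


def local_connectivity_mask(n_prev: int, n_out: int, width: int = 5) -> np.ndarray:
    """Boolean (n_prev, n_out) mask: unit i sees floor(i*n_prev/n_out)+-2."""
    half = (width - 1) // 2
    mask = np.zeros((n_prev, n_out), dtype=bool)
    for i in range(n_out):
        anchor = (i * n_prev) // n_out
        lo = max(0, anchor - half)
        hi = min(n_prev, anchor + half + 1)
        mask[lo:hi, i] = True
    return mask


class LocallyConnectedNetworkRegressor(RegressorMixin, BaseEstimator):
    """Sparse locally connected network regressor on one-hot sequences.

    Parameters
    ----------
    hidden_layer_sizes : tuple of int
        Widths of the hidden tanh layers.
    connectivity : int
        Number of proximal previous-layer units each hidden unit sees.
    alpha : float
        L2 penalty on the (masked) weights.
    learning_rate, batch_size, max_epochs : Adam schedule.
    patience : int
        Epochs without validation improvement tolerated before stopping.
    min_epochs : int
        Burn-in before the stopping rule engages (the best-epoch weights
        are tracked from the start); guards against stopping on the initial
        optimization plateau.
    validation_fraction : float
        Held-out fraction when no explicit validation set is given to fit.
    random_state : int or None
        Seeds weight initialization, shuffling and the internal split;
        training is deterministic given the seed.
    """

    def __init__(self, hidden_layer_sizes=(40, 20, 10, 5), connectivity=5,
                 alpha=1e-4, learning_rate=1e-2, batch_size=64, max_epochs=300,
                 patience=2, min_epochs=20, tol=1e-5, validation_fraction=0.1,
                 random_state=None):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.connectivity = connectivity
        self.alpha = alpha
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.min_epochs = min_epochs
        self.tol = tol
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _init_params(self, n_features: int, rng) -> None:
        sizes = [n_features, *self.hidden_layer_sizes]
        if any(self.connectivity > s for s in sizes[:-1]):
            raise ValueError("connectivity width exceeds a layer width")
        self.masks_ = [local_connectivity_mask(sizes[i], sizes[i + 1],
                                               self.connectivity)
                       for i in range(len(sizes) - 1)]
        self.coefs_, self.intercepts_ = [], []
        for i, mask in enumerate(self.masks_):
            fan_in = mask.sum(axis=0).clip(min=1)
            w = rng.normal(0.0, 1.0, size=mask.shape) / np.sqrt(fan_in)[None, :]
            self.coefs_.append(np.where(mask, w, 0.0))
            self.intercepts_.append(np.zeros(mask.shape[1]))
        # dense scalar read-out over the last hidden layer
        w_out = rng.normal(0.0, 1.0, size=(sizes[-1], 1)) / np.sqrt(sizes[-1])
        self.coefs_.append(w_out)
        self.intercepts_.append(np.zeros(1))
        self.masks_.append(np.ones_like(w_out, dtype=bool))

    def _forward(self, X):
        acts = [X]
        a = X
        for W, b in zip(self.coefs_[:-1], self.intercepts_[:-1]):
            a = np.tanh(a @ W + b)
            acts.append(a)
        out = a @ self.coefs_[-1] + self.intercepts_[-1]
        acts.append(out)
        return acts

    def _loss(self, X, y) -> float:
        pred = self._forward(X)[-1][:, 0]
        return float(np.mean((pred - y) ** 2))

    def fit(self, X, y, X_val=None, y_val=None):
        """Fit with Adam + early stopping.

        If no explicit validation set is supplied, ``validation_fraction``
        of the training data is held out (seeded split).
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be (n_samples, n_features) matching y")
        if len(X) == 0:
            raise ValueError("empty training set")
        rng = np.random.default_rng(self.random_state)
        if X_val is None:
            n_val = max(1, int(round(self.validation_fraction * len(X)))) \
                if len(X) > 4 else 1
            perm = rng.permutation(len(X))
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            X_val, y_val = X[val_idx], y[val_idx]
            X, y = X[tr_idx], y[tr_idx]
        else:
            X_val = np.asarray(X_val, dtype=float)
            y_val = np.asarray(y_val, dtype=float).reshape(-1)
        if len(X) == 0 or len(X_val) == 0:
            raise ValueError("empty train or validation split")

        self.n_features_in_ = X.shape[1]
        self._init_params(self.n_features_in_, rng)

        m = [np.zeros_like(w) for w in self.coefs_]
        v = [np.zeros_like(w) for w in self.coefs_]
        mb = [np.zeros_like(b) for b in self.intercepts_]
        vb = [np.zeros_like(b) for b in self.intercepts_]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0

        best_val = np.inf
        best = None
        since_best = 0
        self.loss_curve_ = []
        self.validation_scores_ = []
        n = len(X)
        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for s in range(0, n, self.batch_size):
                idx = order[s:s + self.batch_size]
                xb, yb = X[idx], y[idx]
                acts = self._forward(xb)
                pred = acts[-1][:, 0]
                err = pred - yb
                epoch_loss += float(np.sum(err ** 2))
                t += 1
                # backprop
                delta = (2.0 / len(idx)) * err[:, None]      # d loss / d out
                grads_w, grads_b = [], []
                for li in range(len(self.coefs_) - 1, -1, -1):
                    a_prev = acts[li]
                    gw = a_prev.T @ delta + 2.0 * self.alpha * self.coefs_[li]
                    gw = np.where(self.masks_[li], gw, 0.0)
                    gb = delta.sum(axis=0)
                    grads_w.append(gw)
                    grads_b.append(gb)
                    if li > 0:
                        delta = (delta @ self.coefs_[li].T) * (1.0 - acts[li] ** 2)
                grads_w.reverse()
                grads_b.reverse()
                lr_t = self.learning_rate * np.sqrt(1 - beta2 ** t) / (1 - beta1 ** t)
                for li in range(len(self.coefs_)):
                    m[li] = beta1 * m[li] + (1 - beta1) * grads_w[li]
                    v[li] = beta2 * v[li] + (1 - beta2) * grads_w[li] ** 2
                    self.coefs_[li] -= lr_t * m[li] / (np.sqrt(v[li]) + eps)
                    self.coefs_[li] = np.where(self.masks_[li], self.coefs_[li], 0.0)
                    mb[li] = beta1 * mb[li] + (1 - beta1) * grads_b[li]
                    vb[li] = beta2 * vb[li] + (1 - beta2) * grads_b[li] ** 2
                    self.intercepts_[li] -= lr_t * mb[li] / (np.sqrt(vb[li]) + eps)
            self.loss_curve_.append(epoch_loss / n)
            val_loss = self._loss(X_val, y_val)
            self.validation_scores_.append(val_loss)
            if val_loss < best_val - self.tol:
                best_val = val_loss
                best = ([w.copy() for w in self.coefs_],
                        [b.copy() for b in self.intercepts_])
                since_best = 0
                self.best_epoch_ = epoch
            else:
                since_best += 1
                if since_best > self.patience and epoch + 1 >= self.min_epochs:
                    break
        if best is not None:
            self.coefs_, self.intercepts_ = best
        self.n_iter_ = len(self.loss_curve_)
        self.best_validation_loss_ = best_val
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; the model expects {self.n_features_in_}"
            )
        return self._forward(X)[-1][:, 0]

    def n_parameters(self) -> int:
        """Number of trainable (unmasked) weights and biases."""
        return int(sum(m.sum() for m in self.masks_)
                   + sum(b.size for b in self.intercepts_))


# ---------------------------------------------------------------------------
# training-set assembly and evaluation


def stratified_split(seeds, fractions=(0.8, 0.1, 0.1), rng=None):
    """Proportional train/val/test allocation within each seed-5mer group.

    Returns integer index arrays (train, val, test).  Small groups fall
    entirely into the training set; groups large enough contribute to every
    split, so no seed is represented in test without training examples.
    """
    rng = np.random.default_rng(rng)
    seeds = pd.Series(list(seeds)).reset_index(drop=True)
    train, val, test = [], [], []
    for _, grp in seeds.groupby(seeds, sort=True):
        idx = rng.permutation(grp.index.to_numpy())
        n = len(idx)
        n_test = int(np.floor(fractions[2] * n))
        n_val = int(np.floor(fractions[1] * n))
        test.extend(idx[:n_test])
        val.extend(idx[n_test:n_test + n_val])
        train.extend(idx[n_test + n_val:])
    # per-group floors under-fill val/test when groups are small (singleton
    # seeds); top up from the training pool to the global targets
    n_total = len(seeds)
    want_val = max(1, int(round(fractions[1] * n_total)))
    want_test = max(1, int(round(fractions[2] * n_total)))
    pool = list(rng.permutation(np.array(train, dtype=int)))
    while len(test) < want_test and len(pool) > 1:
        test.append(pool.pop())
    while len(val) < want_val and len(pool) > 1:
        val.append(pool.pop())
    train = pool
    return (np.sort(np.array(train, dtype=int)),
            np.sort(np.array(val, dtype=int)),
            np.sort(np.array(test, dtype=int)))


def train_model(sequences, targets, split_indices=None, random_state=0,
                **model_params) -> dict:
    """Train the regressor on spacer (or window) sequences.

    ``split_indices`` may be a (train, val, test) triple of index arrays;
    when absent an 80/10/10 split stratified by the 5 PAM-proximal bases is
    drawn.  Returns a dict with keys ``model``, ``train``/``val``/``test``
    index arrays, and ``history`` (per-epoch train and validation loss).
    """
    sequences = list(sequences)
    y = np.asarray(targets, dtype=float)
    if len(sequences) != len(y):
        raise ValueError("sequences and targets differ in length")
    if split_indices is None:
        split_indices = stratified_split([s[-5:] for s in sequences],
                                         rng=random_state)
    tr, va, te = (np.asarray(ix, dtype=int) for ix in split_indices)
    if len(tr) == 0 or len(va) == 0 or len(te) == 0:
        raise ValueError("empty train/val/test split")
    if set(tr) & set(va) or set(tr) & set(te) or set(va) & set(te):
        raise ValueError("splits are not disjoint")
    X = encode_batch(sequences)
    model = LocallyConnectedNetworkRegressor(random_state=random_state,
                                             **model_params)
    model.fit(X[tr], y[tr], X_val=X[va], y_val=y[va])
    history = pd.DataFrame({
        "epoch": np.arange(model.n_iter_),
        "train_mse": model.loss_curve_,
        "val_mse": model.validation_scores_,
    })
    return {"model": model, "train": tr, "val": va, "test": te,
            "history": history}


def evaluate_model(model, sequences, targets) -> tuple[float, float]:
    """Pearson r and RMSE of model predictions on held-out sequences.

    Zero-variance predictions yield r = NaN (RMSE stays valid).
    """
    y = np.asarray(targets, dtype=float)
    pred = model.predict(encode_batch(sequences))
    rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
    if np.std(pred) == 0 or np.std(y) == 0:
        return float("nan"), rmse
    r = float(stats.pearsonr(pred, y)[0])
    return r, rmse


def predict_sequences(model, sequences) -> np.ndarray:
    """Vectorized, order-preserving prediction for raw sequences."""
    return model.predict(encode_batch(sequences))


# ---------------------------------------------------------------------------
# persistence: JSON spec + npz weight blob


FORMAT_VERSION = 1


def save_model(model: LocallyConnectedNetworkRegressor, prefix):
    prefix = Path(prefix)
    spec = {"format_version": FORMAT_VERSION,
            "params": model.get_params(),
            "n_features_in": int(model.n_features_in_),
            "n_iter": int(model.n_iter_),
            "best_validation_loss": float(model.best_validation_loss_)}
    spec["params"]["hidden_layer_sizes"] = list(spec["params"]["hidden_layer_sizes"])
    prefix.with_suffix(".json").write_text(json.dumps(spec, indent=1, sort_keys=True))
    arrays = {}
    for i, (w, b, msk) in enumerate(zip(model.coefs_, model.intercepts_, model.masks_)):
        arrays[f"W{i}"] = w
        arrays[f"b{i}"] = b
        arrays[f"M{i}"] = msk
    np.savez(prefix.with_suffix(".npz"), **arrays)


def load_model(prefix) -> LocallyConnectedNetworkRegressor:
    prefix = Path(prefix)
    spec = json.loads(prefix.with_suffix(".json").read_text())
    if spec["format_version"] != FORMAT_VERSION:
        raise ValueError(f"unsupported model format {spec['format_version']}")
    params = spec["params"]
    params["hidden_layer_sizes"] = tuple(params["hidden_layer_sizes"])
    model = LocallyConnectedNetworkRegressor(**params)
    blob = np.load(prefix.with_suffix(".npz"))
    n_layers = len([k for k in blob.files if k.startswith("W")])
    model.coefs_ = [blob[f"W{i}"] for i in range(n_layers)]
    model.intercepts_ = [blob[f"b{i}"] for i in range(n_layers)]
    model.masks_ = [blob[f"M{i}"] for i in range(n_layers)]
    model.n_features_in_ = spec["n_features_in"]
    model.n_iter_ = spec["n_iter"]
    model.best_validation_loss_ = spec["best_validation_loss"]
    model.loss_curve_ = []
    model.validation_scores_ = []
    return model
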
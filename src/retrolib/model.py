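"""retDNN: a convolutional sequence-to-activity regressor for retron ncRNAs.

The model maps a one-hot-encoded ncRNA sequence to its (inverse-normal-
transformed) msDNA production. Architecture: two convolutional blocks, a
residual dilated-convolution block (one dilated convolution per configured
dilation rate, added back to the running representation), global pooling
over sequence positions, and a two-layer perceptron head. Trained by Adam
on mean-squared error with early stopping on a validation split.

The network is implemented directly in NumPy (batched-matmul convolutions
with explicit backward passes), which keeps the model fully deterministic
given its seed and dependency-light. It follows the scikit-learn estimator
API (``fit``/``predict``/``get_params``) and accepts either raw sequences
or pre-encoded tensors.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

BASE_ORDER = "ACGT"  # fixed channel order
_BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Encoding and splitting
# ---------------------------------------------------------------------------


def one_hot(seq: str, max_len: int) -> np.ndarray:
    """4 × max_len binary matrix (channels A,C,G,T), zero columns beyond the
    sequence end."""
    if len(seq) > max_len:
        raise ModelError(f"sequence length {len(seq)} exceeds max_len {max_len}")
    mat = np.zeros((4, max_len), dtype=np.float32)
    for j, b in enumerate(seq):
        try:
            mat[_BASE_INDEX[b], j] = 1.0
        except KeyError:
            raise ModelError(f"ambiguity code {b!r} not encodable") from None
    return mat


def decode_one_hot(mat: np.ndarray) -> str:
    """Inverse of :func:`one_hot` (padding columns terminate the sequence)."""
    out = []
    for j in range(mat.shape[1]):
        col = mat[:, j]
        if col.sum() == 0:
            break
        out.append(BASE_ORDER[int(col.argmax())])
    return "".join(out)


def encode_sequences(seqs: Sequence[str], max_len: int | None = None) -> np.ndarray:
    if max_len is None:
        max_len = max(len(s) for s in seqs)
    return np.stack([one_hot(s, max_len) for s in seqs])


def split_dataset(
    n_or_labels,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    stratify_by: Sequence | None = None,
) -> np.ndarray:
    """Seeded disjoint train/validation/test assignment.

    Returns an array of split labels ('train'/'validation'/'test') of length
    n. ``n_or_labels`` is either the dataset size or a sequence (whose length
    is used). Optional stratification assigns proportionally within each
    class of ``stratify_by``.
    """
    n = n_or_labels if isinstance(n_or_labels, (int, np.integer)) else len(n_or_labels)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ModelError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    labels = np.empty(n, dtype=object)

    def assign(indices: np.ndarray) -> None:
        m = len(indices)
        perm = rng.permutation(indices)
        n_train = int(round(fractions[0] * m))
        n_val = int(round(fractions[1] * m))
        n_train = min(n_train, m)
        n_val = min(n_val, m - n_train)
        labels[perm[:n_train]] = "train"
        labels[perm[n_train : n_train + n_val]] = "validation"
        labels[perm[n_train + n_val :]] = "test"

    if stratify_by is None:
        assign(np.arange(n))
    else:
        strat = np.asarray(stratify_by)
        for cls in np.unique(strat):
            assign(np.flatnonzero(strat == cls))
    for name, frac in zip(("train", "validation", "test"), fractions):
        if frac > 0 and not (labels == name).any():
            raise ModelError(f"fraction {frac} yields an empty {name} split")
    return labels


# ---------------------------------------------------------------------------
# NumPy layers
# ---------------------------------------------------------------------------


def _unfold(x: np.ndarray, kernel: int, dilation: int) -> np.ndarray:
    """im2col for 1-D same-padding convolution: (N,Cin,L) → (N,Cin*K,L)."""
    n, c, length = x.shape
    pad = dilation * (kernel // 2)
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    cols = np.empty((n, c, kernel, length), dtype=x.dtype)
    for k in range(kernel):
        cols[:, :, k, :] = xp[:, :, k * dilation : k * dilation + length]
    return cols.reshape(n, c * kernel, length)


def _conv_forward(x, W, b, dilation):
    cout, cin, kernel = W.shape
    cols = _unfold(x, kernel, dilation)
    out = np.matmul(W.reshape(cout, cin * kernel), cols) + b[:, None]
    return out, cols


def _conv_backward(dout, cols, x_shape, W, dilation):
    n, cin, length = x_shape
    cout, _, kernel = W.shape
    wr = W.reshape(cout, cin * kernel)
    dW = np.matmul(dout, cols.transpose(0, 2, 1)).sum(axis=0).reshape(W.shape)
    db = dout.sum(axis=(0, 2))
    dcols = np.matmul(wr.T, dout).reshape(n, cin, kernel, length)
    pad = dilation * (kernel // 2)
    dxp = np.zeros((n, cin, length + 2 * pad), dtype=dout.dtype)
    for k in range(kernel):
        dxp[:, :, k * dilation : k * dilation + length] += dcols[:, :, k, :]
    return dxp[:, :, pad : pad + length], dW, db


class _Adam:
    def __init__(self, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for key, g in grads.items():
            if key not in self.m:
                self.m[key] = np.zeros_like(g)
                self.v[key] = np.zeros_like(g)
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            mhat = self.m[key] / (1 - self.b1**self.t)
            vhat = self.v[key] / (1 - self.b2**self.t)
            params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------


class RetDNNRegressor(BaseEstimator, RegressorMixin):
    """Convolutional sequence-to-activity regressor.

    Parameters
    ----------
    channels : filters per convolution.
    kernel_size : convolution kernel width (odd, same padding).
    n_conv_blocks : leading conv+ReLU blocks.
    dilations : dilation rates of the residual dilated block (one dilated
        convolution per rate, residually added).
    hidden : width of the perceptron head's hidden layer.
    pool : 'mean' or 'max' global pooling over positions.
    learning_rate, epochs, batch_size, patience : Adam step size, epoch cap,
        minibatch size, early-stopping patience (epochs without validation
        improvement).
    validation_fraction : held out from fit() when no explicit validation
        set is passed.
    seed : controls initialization, shuffling and the internal split.
    max_len : input width; inferred from the training data when None.
    """

    def __init__(
        self,
        channels: int = 32,
        kernel_size: int = 5,
        n_conv_blocks: int = 2,
        dilations: tuple[int, ...] = (1, 2, 4),
        hidden: int = 32,
        pool: str = "mean",
        learning_rate: float = 1e-3,
        epochs: int = 40,
        batch_size: int = 64,
        patience: int = 8,
        validation_fraction: float = 0.1,
        seed: int = 0,
        max_len: int | None = None,
    ):
        self.channels = channels
        self.kernel_size = kernel_size
        self.n_conv_blocks = n_conv_blocks
        self.dilations = dilations
        self.hidden = hidden
        self.pool = pool
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.seed = seed
        self.max_len = max_len

    # -- plumbing -----------------------------------------------------------

    def _encode(self, X) -> np.ndarray:
        if isinstance(X, np.ndarray) and X.ndim == 3:
            if X.shape[2] != self.max_len_:
                raise ModelError(
                    f"encoded width {X.shape[2]} != model max_len {self.max_len_}"
                )
            return X.astype(np.float32)
        return encode_sequences(list(X), self.max_len_)

    def _validate_config(self) -> None:
        if self.channels < 1 or self.hidden < 1 or self.n_conv_blocks < 1:
            raise ModelError("channels, hidden and n_conv_blocks must be positive")
        if len(self.dilations) < 1 or any(d < 1 for d in self.dilations):
            raise ModelError("need at least one dilation rate >= 1")
        if self.kernel_size % 2 != 1:
            raise ModelError("kernel_size must be odd (same padding)")
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ModelError("learning_rate, epochs, batch_size must be positive")
        if self.pool not in ("mean", "max"):
            raise ModelError("pool must be 'mean' or 'max'")

    def _init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        c, k, h = self.channels, self.kernel_size, self.hidden
        params: dict[str, np.ndarray] = {}

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float64)

        cin = 4
        for i in range(self.n_conv_blocks):
            params[f"conv{i}_W"] = he((c, cin, k), cin * k)
            params[f"conv{i}_b"] = np.zeros(c)
            cin = c
        for i, _ in enumerate(self.dilations):
            params[f"dil{i}_W"] = he((c, c, k), c * k)
            params[f"dil{i}_b"] = np.zeros(c)
        params["fc1_W"] = he((c, h), c)
        params["fc1_b"] = np.zeros(h)
        params["fc2_W"] = he((h, 1), h)
        params["fc2_b"] = np.zeros(1)
        return params

    def _forward(self, x: np.ndarray, params: Mapping[str, np.ndarray], cache=None):
        h = x.astype(np.float64)
        if cache is not None:
            cache["x0"] = h
        for i in range(self.n_conv_blocks):
            out, cols = _conv_forward(h, params[f"conv{i}_W"], params[f"conv{i}_b"], 1)
            mask = out > 0
            if cache is not None:
                cache[f"conv{i}"] = (h.shape, cols, mask)
            h = out * mask
        for i, d in enumerate(self.dilations):
            out, cols = _conv_forward(h, params[f"dil{i}_W"], params[f"dil{i}_b"], d)
            mask = out > 0
            if cache is not None:
                cache[f"dil{i}"] = (h.shape, cols, mask)
            h = h + out * mask  # residual connection
        if self.pool == "mean":
            pooled = h.mean(axis=2)
            if cache is not None:
                cache["pool"] = ("mean", h.shape[2])
        else:
            idx = h.argmax(axis=2)
            pooled = np.take_along_axis(h, idx[:, :, None], axis=2)[:, :, 0]
            if cache is not None:
                cache["pool"] = ("max", h.shape, idx)
        z1 = pooled @ params["fc1_W"] + params["fc1_b"]
        m1 = z1 > 0
        a1 = z1 * m1
        pred = (a1 @ params["fc2_W"] + params["fc2_b"])[:, 0]
        if cache is not None:
            cache["head"] = (pooled, m1, a1)
        return pred

    def _backward(self, dpred, params, cache):
        grads: dict[str, np.ndarray] = {}
        pooled, m1, a1 = cache["head"]
        dpred = dpred[:, None]
        grads["fc2_W"] = a1.T @ dpred
        grads["fc2_b"] = dpred.sum(axis=0)
        da1 = dpred @ params["fc2_W"].T
        dz1 = da1 * m1
        grads["fc1_W"] = pooled.T @ dz1
        grads["fc1_b"] = dz1.sum(axis=0)
        dpooled = dz1 @ params["fc1_W"].T
        if cache["pool"][0] == "mean":
            _, length = cache["pool"]
            dh = np.repeat(dpooled[:, :, None] / length, length, axis=2)
        else:
            _, shape, idx = cache["pool"]
            dh = np.zeros(shape)
            np.put_along_axis(dh, idx[:, :, None], dpooled[:, :, None], axis=2)
        for i in reversed(list(range(len(self.dilations)))):
            x_shape, cols, mask = cache[f"dil{i}"]
            dout = dh * mask
            dx, dW, db = _conv_backward(
                dout, cols, x_shape, params[f"dil{i}_W"], self.dilations[i]
            )
            grads[f"dil{i}_W"] = dW
            grads[f"dil{i}_b"] = db
            dh = dh + dx  # residual path
        for i in reversed(range(self.n_conv_blocks)):
            x_shape, cols, mask = cache[f"conv{i}"]
            dout = dh * mask
            dh, dW, db = _conv_backward(dout, cols, x_shape, params[f"conv{i}_W"], 1)
            grads[f"conv{i}_W"] = dW
            grads[f"conv{i}_b"] = db
        return grads

    # -- sklearn API --------------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None):
        """Train on (X, y); early-stops on validation MSE and restores the
        best-validation weights. X: sequences or (N,4,L) one-hot tensor."""
        self._validate_config()
        y = np.asarray(y, dtype=np.float64)
        if not np.all(np.isfinite(y)):
            raise ModelError("targets must be finite")
        if self.max_len is not None:
            self.max_len_ = int(self.max_len)
        elif isinstance(X, np.ndarray) and X.ndim == 3:
            self.max_len_ = X.shape[2]
        else:
            self.max_len_ = max(len(s) for s in X)
        Xenc = self._encode(X)
        if len(Xenc) != len(y):
            raise ModelError("X and y length mismatch")
        # targets are standardized internally (restored at predict time) so
        # the step size is insensitive to the activity scale
        self.y_mean_ = float(y.mean())
        self.y_std_ = float(y.std()) or 1.0
        y = (y - self.y_mean_) / self.y_std_
        rng = np.random.default_rng(self.seed)
        if X_val is None:
            n_val = max(1, int(round(self.validation_fraction * len(y))))
            if n_val >= len(y):
                raise ModelError("validation fraction leaves no training data")
            perm = rng.permutation(len(y))
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            Xtr, ytr = Xenc[tr_idx], y[tr_idx]
            Xva, yva = Xenc[val_idx], y[val_idx]
        else:
            Xtr, ytr = Xenc, y
            Xva = self._encode(X_val)
            yva = (np.asarray(y_val, dtype=np.float64) - self.y_mean_) / self.y_std_
        if len(Xtr) == 0 or len(Xva) == 0:
            raise ModelError("train and validation splits must be nonempty")

        params = self._init_params(rng)
        opt = _Adam(self.learning_rate)
        best_val = np.inf
        best_params = {k: v.copy() for k, v in params.items()}
        best_epoch = 0
        history = {"train_loss": [], "val_loss": []}
        n = len(Xtr)
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for lo in range(0, n, self.batch_size):
                idx = order[lo : lo + self.batch_size]
                xb, yb = Xtr[idx], ytr[idx]
                cache: dict = {}
                pred = self._forward(xb, params, cache)
                err = pred - yb
                loss = float(np.mean(err**2))
                if not np.isfinite(loss):
                    raise ModelError(
                        f"NaN/inf loss at epoch {epoch}; lower the learning rate "
                        f"(lr={self.learning_rate})"
                    )
                losses.append(loss)
                dpred = 2 * err / len(yb)
                grads = self._backward(dpred, params, cache)
                opt.step(params, grads)
            val_pred = self._predict_params(Xva, params)
            val_loss = float(np.mean((val_pred - yva) ** 2))
            history["train_loss"].append(float(np.mean(losses)))
            history["val_loss"].append(val_loss)
            if val_loss < best_val:
                best_val = val_loss
                best_params = {k: v.copy() for k, v in params.items()}
                best_epoch = epoch
            elif epoch - best_epoch >= self.patience:
                break
        self.params_ = best_params
        self.history_ = history
        self.best_val_loss_ = best_val
        self.n_epochs_ = len(history["train_loss"])
        return self

    def _predict_params(self, Xenc: np.ndarray, params, chunk: int = 512) -> np.ndarray:
        preds = []
        for lo in range(0, len(Xenc), chunk):
            preds.append(self._forward(Xenc[lo : lo + chunk], params))
        return np.concatenate(preds) if preds else np.empty(0)

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "params_"):
            raise ModelError("model is not fitted")
        raw = self._predict_params(self._encode(X), self.params_)
        return raw * getattr(self, "y_std_", 1.0) + getattr(self, "y_mean_", 0.0)

    # -- persistence ----------------------------------------------------------

    def save(self, path) -> None:
        """Checkpoint weights + config (npz)."""
        import json

        if not hasattr(self, "params_"):
            raise ModelError("model is not fitted")
        cfg = self.get_params()
        cfg["dilations"] = list(cfg["dilations"])
        np.savez(
            path,
            __config__=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8),
            __max_len__=np.array([self.max_len_]),
            __y_scale__=np.array([getattr(self, "y_mean_", 0.0), getattr(self, "y_std_", 1.0)]),
            **self.params_,
        )

    @classmethod
    def load(cls, path) -> "RetDNNRegressor":
        import json

        data = np.load(path)
        cfg = json.loads(bytes(data["__config__"]).decode())
        cfg["dilations"] = tuple(cfg["dilations"])
        model = cls(**cfg)
        model.max_len_ = int(data["__max_len__"][0])
        model.y_mean_, model.y_std_ = map(float, data["__y_scale__"])
        model.params_ = {
            k: data[k] for k in data.files if not k.startswith("__")
        }
        return model


# ---------------------------------------------------------------------------
# Module-level wrappers
# ---------------------------------------------------------------------------


def train(X, y, X_val=None, y_val=None, **config) -> RetDNNRegressor:
    """Fit a :class:`RetDNNRegressor` with the given config; returns the
    fitted estimator (training history in ``.history_``)."""
    return RetDNNRegressor(**config).fit(X, y, X_val=X_val, y_val=y_val)


def evaluate(model: RetDNNRegressor, X, y) -> float:
    """Pearson correlation between predictions and observed activity."""
    pred = model.predict(X)
    obs = np.asarray(y, dtype=float)
    if np.std(pred) == 0 or np.std(obs) == 0:
        raise ModelError("zero-variance predictions or targets: R undefined")
    return float(np.corrcoef(pred, obs)[0, 1])


def query_variants(model: RetDNNRegressor, variants) -> dict:
    """Predict activity for designed variants; when variants carry GC-bin
    metadata, also fit prediction vs GC% by ordinary least squares.

    ``variants``: list of Variant objects, (id, sequence) pairs, or plain
    sequences. Returns {'predictions': DataFrame, 'gc_slope': float|None,
    'gc_slope_p': float|None, 'gc_bin_means': DataFrame|None}.
    """
    import pandas as pd

    ids, seqs, gc = [], [], []
    for i, v in enumerate(variants):
        if isinstance(v, str):
            ids.append(f"v{i}")
            seqs.append(v)
            gc.append(np.nan)
        elif isinstance(v, tuple):
            ids.append(v[0])
            seqs.append(v[1])
            gc.append(np.nan)
        else:
            ids.append(v.variant_id)
            seqs.append(v.sequence)
            gc.append(v.params.get("gc_percent", np.nan))
    pred = model.predict(seqs)
    df = pd.DataFrame({"variant_id": ids, "prediction": pred, "gc_percent": gc})
    out = {"predictions": df, "gc_slope": None, "gc_slope_p": None, "gc_bin_means": None}
    have_gc = df["gc_percent"].notna()
    if have_gc.sum() >= 3:
        sub = df[have_gc]
        if np.std(sub["prediction"]) == 0:
            out["gc_slope"], out["gc_slope_p"] = 0.0, 1.0
        else:
            fit = stats.linregress(sub["gc_percent"], sub["prediction"])
            out["gc_slope"], out["gc_slope_p"] = float(fit.slope), float(fit.pvalue)
        out["gc_bin_means"] = (
            sub.groupby("gc_percent")["prediction"].mean().reset_index()
        )
    return out


def grid_tune(X, y, grid: Mapping[str, Sequence], seed: int = 0, **base) -> dict:
    """Exhaustive small-grid hyperparameter search on validation R.

    Grid keys are estimator parameters (e.g. n_conv_blocks, learning_rate,
    dilations). A 3:1 train:validation split is made once (seeded) and
    reused for every configuration; ties break toward the earlier grid
    point. Returns {'best_params', 'best_r', 'results'}.
    """
    import itertools as it

    keys = list(grid.keys())
    points = list(it.product(*(grid[k] for k in keys)))
    if not points:
        raise ModelError("empty grid")
    y = np.asarray(y, dtype=float)
    labels = split_dataset(len(y), (0.75, 0.25, 0.0), seed=seed)
    tr = labels == "train"
    va = labels == "validation"
    X = np.asarray(X) if not isinstance(X, np.ndarray) else X
    results = []
    best = None
    for point in points:
        cfg = dict(base)
        cfg.update(dict(zip(keys, point)))
        cfg.setdefault("seed", seed)
        model = RetDNNRegressor(**cfg).fit(X[tr], y[tr], X_val=X[va], y_val=y[va])
        r = evaluate(model, X[va], y[va])
        results.append({**dict(zip(keys, point)), "val_r": r})
        if best is None or r > best[0]:
            best = (r, dict(zip(keys, point)))
    return {"best_params": best[1], "best_r": best[0], "results": results}
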
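"""Static-to-sequence recurrent model for complete release profiles.

The architecture maps a formulation's static feature vector to an entire
T-point release profile without ever seeing time as an input:

    X (N,d) --FC+ReLU--> Z (N,f) --repeat T--> ZZ (N,T,f)
      --RNN stack (LSTM or GRU, hidden h, 1..3 layers)--> Y (N,T,h)
      --reshape (N*T,h) --FC--> (N*T,1) --reshape--> R_hat (N,T)

Time-independence is structural: the forward pass consumes only the
feature matrix, and the sequence dimension exists solely because the
embedded feature vector is repeated T times before the recurrent stack.

The network, backpropagation-through-time and the Adam optimizer are
implemented directly in NumPy; gradients are exercised against finite
differences in the test suite.  Training minimizes the mean squared
error over all N*T profile points.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .errors import ConfigError, DivergenceError, ShapeError

HIDDEN_CHOICES = (32, 64, 128, 256)
LAYER_CHOICES = (1, 2, 3)
DROPOUT_CHOICES = (0.2, 0.3, 0.4)
LR_CHOICES = (1e-3, 1e-4)
BATCH_CHOICES = (16, 32, 64, 128)
CELL_CHOICES = ("lstm", "gru")

#: Inner/outer-fold training epochs used by the nested-CV protocol.
EPOCHS_INNER = 250
EPOCHS_OUTER = 500


@dataclass(frozen=True)
class SequenceModelConfig:
    """Architecture and training settings for the sequence model.

    ``f`` (embedded feature width) is held fixed during hyperparameter
    tuning; the tuned choices are hidden size, number of recurrent
    layers, cell type, dropout, learning rate and batch size.
    """

    f: int = 64
    hidden: int = 64
    layers: int = 1
    cell: str = "lstm"
    dropout: float = 0.2
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = EPOCHS_OUTER
    T: int = 101
    seed: int = 42

    def validate(self) -> None:
        """Validate tunable choices against the encoded search space."""
        if self.hidden not in HIDDEN_CHOICES:
            raise ConfigError(f"hidden size {self.hidden} not in {HIDDEN_CHOICES}")
        if self.layers not in LAYER_CHOICES:
            raise ConfigError(f"layers {self.layers} not in {LAYER_CHOICES}")
        if self.dropout not in DROPOUT_CHOICES:
            raise ConfigError(f"dropout {self.dropout} not in {DROPOUT_CHOICES}")
        if self.learning_rate not in LR_CHOICES:
            raise ConfigError(
                f"learning rate {self.learning_rate} not in {LR_CHOICES}"
            )
        if self.batch_size not in BATCH_CHOICES:
            raise ConfigError(f"batch size {self.batch_size} not in {BATCH_CHOICES}")
        self.validate_basic()

    def validate_basic(self) -> None:
        """Structural checks that apply to any config, tuned or not."""
        if self.cell not in CELL_CHOICES:
            raise ConfigError(f"cell {self.cell!r} not in {CELL_CHOICES}")
        if self.T < 2 or self.f < 1 or self.hidden < 1 or self.layers < 1:
            raise ConfigError("T, f, hidden and layers must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ConfigError("dropout must be in [0, 1)")


@dataclass(frozen=True)
class PredictedProfileBatch:
    """Predicted release fractions, one T-point profile per formulation."""

    ids: list
    R_hat: np.ndarray


def mse_profile_loss(R: np.ndarray, R_hat: np.ndarray) -> float:
    """Mean squared error over all N x T profile points.

    ``(1/N)(1/T) sum_i sum_t (R[i,t] - R_hat[i,t])^2``; equals the squared
    per-profile RMSE when N == 1.
    """
    R = np.asarray(R, dtype=float)
    R_hat = np.asarray(R_hat, dtype=float)
    if R.shape != R_hat.shape:
        raise ShapeError(f"profile shapes differ: {R.shape} vs {R_hat.shape}")
    return float(np.mean((R - R_hat) ** 2))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class SequenceModel:
    """FC-embed -> repeat -> recurrent stack -> FC head, in NumPy."""

    def __init__(self, config: SequenceModelConfig, d: int):
        config.validate_basic()
        if d < 1:
            raise ConfigError(f"input width d must be positive, got {d}")
        self.config = config
        self.d = d
        self.params: dict[str, np.ndarray] = {}
        self._init_params(np.random.default_rng(config.seed))
        self.loss_history: list[float] = []

    # ------------------------------------------------------------------ init
    def _init_params(self, rng: np.random.Generator) -> None:
        c = self.config
        G = 4 if c.cell == "lstm" else 3
        p = self.params
        p["We"] = rng.normal(0.0, np.sqrt(2.0 / self.d), (self.d, c.f))
        p["be"] = np.zeros(c.f)
        k = 1.0 / np.sqrt(c.hidden)
        for layer in range(c.layers):
            in_dim = c.f if layer == 0 else c.hidden
            p[f"Wx{layer}"] = rng.uniform(-k, k, (in_dim, G * c.hidden))
            p[f"Wh{layer}"] = rng.uniform(-k, k, (c.hidden, G * c.hidden))
            p[f"bi{layer}"] = np.zeros(G * c.hidden)
            if c.cell == "gru":
                p[f"bh{layer}"] = np.zeros(G * c.hidden)
        p["Wo"] = rng.uniform(-k, k, (c.hidden, 1))
        p["bo"] = np.zeros(1)

    def zero_params(self) -> None:
        """Zero every weight and bias (diagnostic: output becomes constant)."""
        for key in self.params:
            self.params[key] = np.zeros_like(self.params[key])

    # --------------------------------------------------------------- forward
    def _lstm_layer_forward(self, x_seq, layer):
        """x_seq: (T, N, in) -> h_seq (T, N, h) plus caches for backward."""
        p, h = self.params, self.config.hidden
        Wx, Wh, b = p[f"Wx{layer}"], p[f"Wh{layer}"], p[f"bi{layer}"]
        T, N, _ = x_seq.shape
        h_prev = np.zeros((N, h))
        c_prev = np.zeros((N, h))
        h_seq = np.empty((T, N, h))
        cache = []
        for t in range(T):
            a = x_seq[t] @ Wx + h_prev @ Wh + b
            i = _sigmoid(a[:, :h])
            f = _sigmoid(a[:, h : 2 * h])
            g = np.tanh(a[:, 2 * h : 3 * h])
            o = _sigmoid(a[:, 3 * h :])
            c_t = f * c_prev + i * g
            h_t = o * np.tanh(c_t)
            cache.append((x_seq[t], h_prev, c_prev, i, f, g, o, c_t))
            h_prev, c_prev = h_t, c_t
            h_seq[t] = h_t
        return h_seq, cache

    def _lstm_layer_backward(self, dh_seq, cache, layer, grads):
        p, h = self.params, self.config.hidden
        Wx, Wh = p[f"Wx{layer}"], p[f"Wh{layer}"]
        T, N, _ = dh_seq.shape
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros(4 * h)
        dx_seq = np.empty((T, N, Wx.shape[0]))
        dh_next = np.zeros((N, h))
        dc_next = np.zeros((N, h))
        for t in reversed(range(T)):
            x_t, h_prev, c_prev, i, f, g, o, c_t = cache[t]
            dh = dh_seq[t] + dh_next
            tc = np.tanh(c_t)
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc**2)
            di, dg, df = dc * g, dc * i, dc * c_prev
            da = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            dWx += x_t.T @ da
            dWh += h_prev.T @ da
            db += da.sum(axis=0)
            dx_seq[t] = da @ Wx.T
            dh_next = da @ Wh.T
            dc_next = dc * f
        grads[f"Wx{layer}"] = dWx
        grads[f"Wh{layer}"] = dWh
        grads[f"bi{layer}"] = db
        return dx_seq

    def _gru_layer_forward(self, x_seq, layer):
        p, h = self.params, self.config.hidden
        Wx, Wh = p[f"Wx{layer}"], p[f"Wh{layer}"]
        bi, bh = p[f"bi{layer}"], p[f"bh{layer}"]
        T, N, _ = x_seq.shape
        h_prev = np.zeros((N, h))
        h_seq = np.empty((T, N, h))
        cache = []
        for t in range(T):
            xi = x_seq[t] @ Wx + bi
            hh = h_prev @ Wh + bh
            r = _sigmoid(xi[:, :h] + hh[:, :h])
            z = _sigmoid(xi[:, h : 2 * h] + hh[:, h : 2 * h])
            m = hh[:, 2 * h :]  # candidate's hidden contribution, gated by r
            n = np.tanh(xi[:, 2 * h :] + r * m)
            h_t = (1.0 - z) * n + z * h_prev
            cache.append((x_seq[t], h_prev, r, z, n, m))
            h_prev = h_t
            h_seq[t] = h_t
        return h_seq, cache

    def _gru_layer_backward(self, dh_seq, cache, layer, grads):
        p, h = self.params, self.config.hidden
        Wx, Wh = p[f"Wx{layer}"], p[f"Wh{layer}"]
        T, N, _ = dh_seq.shape
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        dbi = np.zeros(3 * h)
        dbh = np.zeros(3 * h)
        dx_seq = np.empty((T, N, Wx.shape[0]))
        dh_next = np.zeros((N, h))
        for t in reversed(range(T)):
            x_t, h_prev, r, z, n, m = cache[t]
            dh = dh_seq[t] + dh_next
            dz = dh * (h_prev - n)
            dn = dh * (1.0 - z)
            dh_prev = dh * z
            da_n = dn * (1.0 - n**2)
            dr = da_n * m
            dm = da_n * r
            da_r = dr * r * (1 - r)
            da_z = dz * z * (1 - z)
            da_x = np.concatenate([da_r, da_z, da_n], axis=1)
            da_h = np.concatenate([da_r, da_z, dm], axis=1)
            dWx += x_t.T @ da_x
            dbi += da_x.sum(axis=0)
            dWh += h_prev.T @ da_h
            dbh += da_h.sum(axis=0)
            dx_seq[t] = da_x @ Wx.T
            dh_next = dh_prev + da_h @ Wh.T
        grads[f"Wx{layer}"] = dWx
        grads[f"Wh{layer}"] = dWh
        grads[f"bi{layer}"] = dbi
        grads[f"bh{layer}"] = dbh
        return dx_seq

    def forward(self, X: np.ndarray, training: bool = False, rng=None):
        """Forward pass.  Returns (R_hat, caches); caches is None in eval."""
        c = self.config
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.d:
            raise ShapeError(
                f"expected input of width {self.d}, got shape {X.shape}"
            )
        N = X.shape[0]
        p = self.params
        z_pre = X @ p["We"] + p["be"]
        z = np.maximum(z_pre, 0.0)
        x_seq = np.broadcast_to(z, (c.T, N, c.f)).copy()  # repeat along time
        layer_caches, drop_masks = [], []
        for layer in range(c.layers):
            if c.cell == "lstm":
                h_seq, cache = self._lstm_layer_forward(x_seq, layer)
            else:
                h_seq, cache = self._gru_layer_forward(x_seq, layer)
            layer_caches.append(cache)
            if training and c.dropout > 0 and layer < c.layers - 1:
                mask = (rng.random(h_seq.shape) >= c.dropout) / (1.0 - c.dropout)
                h_seq = h_seq * mask
                drop_masks.append(mask)
            else:
                drop_masks.append(None)
            x_seq = h_seq
        flat = x_seq.transpose(1, 0, 2).reshape(N * c.T, c.hidden)
        R_hat = (flat @ p["Wo"] + p["bo"]).reshape(N, c.T)
        if not training:
            return R_hat, None
        return R_hat, {
            "X": X,
            "z_pre": z_pre,
            "z": z,
            "h_top": x_seq,
            "flat": flat,
            "layer_caches": layer_caches,
            "drop_masks": drop_masks,
        }

    def backward(self, dR_hat: np.ndarray, caches) -> dict[str, np.ndarray]:
        """Backpropagate a loss gradient on R_hat; returns parameter grads."""
        c, p = self.config, self.params
        N = dR_hat.shape[0]
        grads: dict[str, np.ndarray] = {}
        dflat = dR_hat.reshape(N * c.T, 1) @ p["Wo"].T
        grads["Wo"] = caches["flat"].T @ dR_hat.reshape(N * c.T, 1)
        grads["bo"] = np.array([dR_hat.sum()])
        dh_seq = dflat.reshape(N, c.T, c.hidden).transpose(1, 0, 2)
        for layer in reversed(range(c.layers)):
            mask = caches["drop_masks"][layer]
            if mask is not None:
                dh_seq = dh_seq * mask
            if c.cell == "lstm":
                dh_seq = self._lstm_layer_backward(
                    dh_seq, caches["layer_caches"][layer], layer, grads
                )
            else:
                dh_seq = self._gru_layer_backward(
                    dh_seq, caches["layer_caches"][layer], layer, grads
                )
        dz = dh_seq.sum(axis=0)  # gradient pools over the repeated axis
        dz_pre = dz * (caches["z_pre"] > 0)
        grads["We"] = caches["X"].T @ dz_pre
        grads["be"] = dz_pre.sum(axis=0)
        return grads

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Deterministic eval-mode forward pass -> (N, T) profiles."""
        R_hat, _ = self.forward(X, training=False)
        return R_hat

    # -------------------------------------------------------------- persist
    def save(self, path: str) -> None:
        """Save parameters with the config embedded."""
        meta = json.dumps({"config": asdict(self.config), "d": self.d})
        np.savez(path, _meta=np.array(meta), **self.params)

    @classmethod
    def load(cls, path: str) -> "SequenceModel":
        data = np.load(path if str(path).endswith(".npz") else f"{path}.npz")
        meta = json.loads(str(data["_meta"]))
        model = cls(SequenceModelConfig(**meta["config"]), meta["d"])
        for key in model.params:
            model.params[key] = data[key]
        return model


def build_sequence_model(config: SequenceModelConfig, d: int) -> SequenceModel:
    """Instantiate the FC->repeat->RNN->FC model for ``d`` input features."""
    return SequenceModel(config, d)


class _Adam:
    """Adam optimizer over a parameter dict."""

    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train_sequence_model(
    X: np.ndarray,
    R: np.ndarray,
    config: SequenceModelConfig,
    epochs: int | None = None,
    enforce_space: bool = False,
) -> SequenceModel:
    """Train the sequence model by mini-batch Adam on the profile MSE.

    ``X`` is the standardized feature matrix (N, d); ``R`` the matching
    (N, T) normalized profiles.  Fully seeded: identical inputs, config
    and seed give identical trained weights.  ``enforce_space=True``
    additionally validates the config against the tuning search space.
    """
    if enforce_space:
        config.validate()
    X = np.asarray(X, dtype=float)
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[1] != config.T:
        raise ShapeError(f"profiles must be (N, {config.T}), got {R.shape}")
    if X.shape[0] != R.shape[0]:
        raise ShapeError("feature and profile row counts differ")
    n_epochs = epochs if epochs is not None else config.epochs
    model = SequenceModel(config, X.shape[1])
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x7A1]))
    opt = _Adam(model.params, config.learning_rate)
    n = X.shape[0]
    for epoch in range(n_epochs):
        order = rng.permutation(n)
        total, count = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            Xb, Rb = X[idx], R[idx]
            R_hat, caches = model.forward(Xb, training=True, rng=rng)
            loss = mse_profile_loss(Rb, R_hat)
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch} with config {config}"
                )
            dR_hat = 2.0 * (R_hat - Rb) / R_hat.size
            grads = model.backward(dR_hat, caches)
            if config.learning_rate > 0:
                opt.step(model.params, grads)
            total += loss * len(idx)
            count += len(idx)
        model.loss_history.append(total / count)
    return model


def predict_release_profile(model: SequenceModel, features) -> PredictedProfileBatch:
    """Predict complete profiles for a feature matrix (no time input).

    The network head is linear; reported profiles are clipped to the
    physically meaningful [0, 1.1] release-fraction range.
    """
    X = features.X if hasattr(features, "X") else np.asarray(features, dtype=float)
    ids = list(features.ids) if hasattr(features, "ids") else [
        str(i) for i in range(len(X))
    ]
    return PredictedProfileBatch(ids=ids, R_hat=np.clip(model.predict(X), 0.0, 1.1))
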
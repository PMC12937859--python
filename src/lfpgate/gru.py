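"""A small gated recurrent unit (GRU) binary classifier, in pure NumPy.

The deployment target for this cascade is a nanowatt-class edge device, so
the models are deliberately tiny (one layer, 32 hidden units). At that
scale a NumPy implementation with hand-derived backpropagation-through-time
is fast enough for training and keeps the package free of deep-learning
framework dependencies.

Cell equations (update gate z, reset gate r, candidate n):

    z_t = sigmoid(x_t Wz + h_{t-1} Uz + bz)
    r_t = sigmoid(x_t Wr + h_{t-1} Ur + br)
    n_t = tanh(x_t Wn + r_t * (h_{t-1} Un + bn))
    h_t = (1 - z_t) * n_t + z_t * h_{t-1}

followed by a logistic read-out p = sigmoid(h_T w + b) on the final hidden
state. Training minimizes class-weighted binary cross-entropy with Adam
and early stopping on a validation metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GRUClassifier", "TrainHistory"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_metric: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1


class GRUClassifier:
    """One-layer GRU + logistic head for sequence binary classification.

    Parameters
    ----------
    input_size : features per timestep.
    hidden_size : GRU state width (default 32).
    seed : initialization seed; all weights drawn U(-k, k), k = 1/sqrt(H),
        except when ``zero_init`` is set (then every parameter is 0 and the
        untrained model outputs exactly 0.5 for any input).
    """

    PARAM_NAMES = ("Wz", "Wr", "Wn", "Uz", "Ur", "Un", "bz", "br", "bn", "w", "b")

    def __init__(
        self,
        input_size: int,
        hidden_size: int = 32,
        seed: int = 0,
        zero_init: bool = False,
    ):
        self.input_size = input_size
        self.hidden_size = hidden_size
        rng = np.random.default_rng(seed)
        H, D = hidden_size, input_size
        k = 1.0 / np.sqrt(H)

        def init(shape):
            if zero_init:
                return np.zeros(shape)
            return rng.uniform(-k, k, size=shape)

        self.params: dict[str, np.ndarray] = {
            "Wz": init((D, H)), "Wr": init((D, H)), "Wn": init((D, H)),
            "Uz": init((H, H)), "Ur": init((H, H)), "Un": init((H, H)),
            "bz": np.zeros(H), "br": np.zeros(H), "bn": np.zeros(H),
            "w": init((H, 1)), "b": np.zeros(1),
        }

    # ---------------------------------------------------------------- forward

    def _forward(self, X: np.ndarray, keep_cache: bool = False):
        """Run the recurrence over a batch. X: (B, T, D)."""
        p = self.params
        B, T, D = X.shape
        H = self.hidden_size
        h = np.zeros((B, H))
        cache = [] if keep_cache else None
        for t in range(T):
            x = X[:, t, :]
            z = _sigmoid(x @ p["Wz"] + h @ p["Uz"] + p["bz"])
            r = _sigmoid(x @ p["Wr"] + h @ p["Ur"] + p["br"])
            c = h @ p["Un"] + p["bn"]
            n = np.tanh(x @ p["Wn"] + r * c)
            h_new = (1.0 - z) * n + z * h
            if keep_cache:
                cache.append((x, h, z, r, c, n))
            h = h_new
        logits = (h @ p["w"] + p["b"]).ravel()
        return logits, h, cache

    def predict_proba(self, X: np.ndarray, batch_size: int = 4096) -> np.ndarray:
        """P(positive class) per sequence. X: (B, T, D)."""
        X = np.asarray(X, dtype=np.float64)
        outs = []
        for i in range(0, len(X), batch_size):
            logits, _, _ = self._forward(X[i : i + batch_size])
            outs.append(_sigmoid(logits))
        return np.concatenate(outs) if outs else np.empty(0)

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)

    # --------------------------------------------------------------- backward

    def loss_and_grads(
        self, X: np.ndarray, y: np.ndarray, sample_weight: np.ndarray | None = None
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Weighted BCE loss and gradients for a batch (full BPTT)."""
        p = self.params
        B = len(X)
        if sample_weight is None:
            sample_weight = np.ones(B)
        wsum = sample_weight.sum()
        logits, hT, cache = self._forward(X, keep_cache=True)
        prob = _sigmoid(logits)
        eps = 1e-12
        loss = -np.sum(
            sample_weight * (y * np.log(prob + eps) + (1 - y) * np.log(1 - prob + eps))
        ) / wsum

        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dlogit = (sample_weight * (prob - y) / wsum)[:, None]  # (B, 1)
        grads["w"] = hT.T @ dlogit
        grads["b"] = dlogit.sum(axis=0)
        dh = dlogit @ p["w"].T
        for t in range(len(cache) - 1, -1, -1):
            x, h_prev, z, r, c, n = cache[t]
            dz = dh * (h_prev - n)
            dn = dh * (1.0 - z)
            dh_prev = dh * z
            dan = dn * (1.0 - n * n)
            dc = dan * r
            dr = dan * c
            dar = dr * r * (1.0 - r)
            daz = dz * z * (1.0 - z)
            grads["Wz"] += x.T @ daz
            grads["Wr"] += x.T @ dar
            grads["Wn"] += x.T @ dan
            grads["Uz"] += h_prev.T @ daz
            grads["Ur"] += h_prev.T @ dar
            grads["Un"] += h_prev.T @ dc
            grads["bz"] += daz.sum(axis=0)
            grads["br"] += dar.sum(axis=0)
            grads["bn"] += dc.sum(axis=0)
            dh = dh_prev + daz @ p["Uz"].T + dar @ p["Ur"].T + dc @ p["Un"].T
        return float(loss), grads

    # ---------------------------------------------------------------- training

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
        lr: float = 3e-4,
        max_epochs: int = 300,
        batch_size: int = 256,
        patience: int = 20,
        class_weight: str | dict | None = "balanced",
        seed: int = 0,
        val_metric=None,
    ) -> TrainHistory:
        """Adam + early stopping, restoring the best-validation weights.

        ``class_weight='balanced'`` weights each class inversely to its
        prevalence, which matters here because active windows are sparse.
        ``val_metric(y_true, prob) -> float`` is maximized (default: F1 at
        threshold 0.5). Without a validation set, training runs to
        ``max_epochs`` and keeps the final weights.
        """
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training set must contain both classes")
        if class_weight == "balanced":
            cw = {c: len(y) / (2.0 * np.sum(y == c)) for c in classes}
        elif isinstance(class_weight, dict):
            cw = class_weight
        else:
            cw = {c: 1.0 for c in classes}
        sw = np.array([cw[c] for c in y])

        if val_metric is None:
            val_metric = _f1_at_half

        rng = np.random.default_rng(seed)
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(v) for k, v in self.params.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0
        history = TrainHistory()
        best_metric = -np.inf
        best_params = None
        bad_epochs = 0

        for epoch in range(max_epochs):
            order = rng.permutation(len(X))
            epoch_loss = 0.0
            nb = 0
            for i in range(0, len(X), batch_size):
                idx = order[i : i + batch_size]
                loss, grads = self.loss_and_grads(X[idx], y[idx], sw[idx])
                epoch_loss += loss
                nb += 1
                step += 1
                for k in self.params:
                    g = grads[k]
                    m[k] = b1 * m[k] + (1 - b1) * g
                    v[k] = b2 * v[k] + (1 - b2) * g * g
                    mhat = m[k] / (1 - b1 ** step)
                    vhat = v[k] / (1 - b2 ** step)
                    self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)
            history.train_loss.append(epoch_loss / max(nb, 1))

            if X_val is not None and y_val is not None:
                metric = float(val_metric(np.asarray(y_val).ravel(),
                                          self.predict_proba(X_val)))
                history.val_metric.append(metric)
                if metric > best_metric + 1e-12:
                    best_metric = metric
                    best_params = {k: p.copy() for k, p in self.params.items()}
                    history.best_epoch = epoch
                    bad_epochs = 0
                else:
                    bad_epochs += 1
                    if bad_epochs >= patience:
                        history.stopped_epoch = epoch
                        break

        if best_params is not None:
            self.params = best_params
        if history.stopped_epoch < 0:
            history.stopped_epoch = len(history.train_loss) - 1
        return history

    # ------------------------------------------------------------- persistence

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k in self.PARAM_NAMES:
            self.params[k] = np.asarray(weights[k], dtype=np.float64)
        self.input_size, self.hidden_size = self.params["Wz"].shape


def _f1_at_half(y_true: np.ndarray, prob: np.ndarray) -> float:
    pred = prob >= 0.5
    pos = y_true > 0.5
    tp = np.sum(pred & pos)
    fp = np.sum(pred & ~pos)
    fn = np.sum(~pred & pos)
    if tp == 0:
        return 0.0
    return 2.0 * tp / (2.0 * tp + fp + fn)
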
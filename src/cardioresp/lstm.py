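"""A compact LSTM binary sequence classifier in NumPy.

Single LSTM layer over a scalar input sequence, last hidden state fed to a
sigmoid read-out, trained with binary cross-entropy via full
backpropagation through time and Adam. Sized for short physiological
sequences (an 80-sample fused effort window) where a small recurrent model
trains in seconds on one CPU; width and depth of large frameworks are not
needed at this scale. Gradients are verified against finite differences in
the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LSTMClassifier"]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class LSTMClassifier:
    """Binary classifier over fixed-length 1-D sequences.

    Parameters
    ----------
    hidden : int
        LSTM state size.
    lr : float
        Adam learning rate.
    epochs : int
        Maximum training epochs (full-batch).
    patience : int
        Early-stopping patience on validation loss, in epochs.
    seed : int
        Parameter-initialisation seed; fixed seed gives reproducible fits.
    """

    hidden: int = 32
    lr: float = 1e-2
    epochs: int = 300
    patience: int = 30
    seed: int = 0
    params: dict = field(default_factory=dict, repr=False)
    input_mean_: float = 0.0
    input_std_: float = 1.0

    # -- parameter handling -------------------------------------------------

    def _init_params(self, rng: np.random.Generator) -> dict:
        H = self.hidden
        scale = 1.0 / np.sqrt(H + 1)
        p = {
            "W": rng.normal(0, scale, size=(4 * H, H + 1)),
            "b": np.zeros(4 * H),
            "w_out": rng.normal(0, scale, size=H),
            "b_out": np.zeros(1),
        }
        p["b"][H: 2 * H] = 1.0  # forget-gate bias, standard initialisation
        return p

    # -- forward / backward -------------------------------------------------

    def _forward(self, params: dict, X: np.ndarray):
        """Forward pass; X is (B, T) standardized. Returns probs and cache."""
        B, T = X.shape
        H = self.hidden
        W, b = params["W"], params["b"]
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        cache = []
        for t in range(T):
            inp = np.column_stack([X[:, t], h])  # (B, 1+H)
            z = inp @ W.T + b  # (B, 4H)
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H: 2 * H])
            g = np.tanh(z[:, 2 * H: 3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            cache.append((inp, i, f, g, o, c, c_new))
            h, c = h_new, c_new
        logits = h @ params["w_out"] + params["b_out"][0]
        return _sigmoid(logits), h, cache

    def loss_and_grads(self, params: dict, X: np.ndarray, y: np.ndarray):
        """Mean BCE loss and its gradients (used by fit and by tests)."""
        B, T = X.shape
        H = self.hidden
        probs, h_last, cache = self._forward(params, X)
        eps = 1e-12
        loss = float(-np.mean(y * np.log(probs + eps) + (1 - y) * np.log(1 - probs + eps)))

        grads = {k: np.zeros_like(v) for k, v in params.items()}
        dlogit = (probs - y) / B  # (B,)
        grads["w_out"] = h_last.T @ dlogit
        grads["b_out"] = np.array([np.sum(dlogit)])
        dh = np.outer(dlogit, params["w_out"])  # (B, H)
        dc = np.zeros((B, H))
        W = params["W"]
        for t in range(T - 1, -1, -1):
            inp, i, f, g, o, c_prev, c_new = cache[t]
            tanh_c = np.tanh(c_new)
            do = dh * tanh_c
            dc = dc + dh * o * (1 - tanh_c ** 2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g ** 2), do * o * (1 - o)],
                axis=1,
            )  # (B, 4H)
            grads["W"] += dz.T @ inp
            grads["b"] += dz.sum(axis=0)
            dinp = dz @ W  # (B, 1+H)
            dh = dinp[:, 1:]
            dc = dc * f
        return loss, grads

    # -- training -----------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
    ) -> "LSTMClassifier":
        """Train on sequences X (n, T) with binary labels y.

        Inputs are standardized with the training mean/SD. With validation
        data, training stops when validation loss has not improved for
        ``patience`` epochs and the best-validation parameters are kept.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("labels must be binary 0/1")
        self.input_mean_ = float(np.mean(X))
        self.input_std_ = float(np.std(X)) or 1.0
        Xs = (X - self.input_mean_) / self.input_std_
        Xv = None
        if X_val is not None:
            Xv = (np.asarray(X_val, dtype=float) - self.input_mean_) / self.input_std_
            yv = np.asarray(y_val, dtype=float)

        rng = np.random.default_rng(self.seed)
        params = self._init_params(rng)
        m = {k: np.zeros_like(v) for k, v in params.items()}
        v = {k: np.zeros_like(v_) for k, v_ in params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        best_val = np.inf
        best_params = {k: p.copy() for k, p in params.items()}
        stale = 0
        for epoch in range(1, self.epochs + 1):
            _, grads = self.loss_and_grads(params, Xs, y)
            for k in params:
                m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
                mhat = m[k] / (1 - beta1 ** epoch)
                vhat = v[k] / (1 - beta2 ** epoch)
                params[k] = params[k] - self.lr * mhat / (np.sqrt(vhat) + eps)
            if Xv is not None:
                probs, _, _ = self._forward(params, Xv)
                e = 1e-12
                val_loss = float(-np.mean(yv * np.log(probs + e) + (1 - yv) * np.log(1 - probs + e)))
                if val_loss < best_val - 1e-5:
                    best_val = val_loss
                    best_params = {k: p.copy() for k, p in params.items()}
                    stale = 0
                else:
                    stale += 1
                    if stale >= self.patience:
                        break
        self.params = best_params if Xv is not None else params
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probability of the positive class for each sequence."""
        if not self.params:
            raise RuntimeError("model is not fitted")
        Xs = (np.asarray(X, dtype=float) - self.input_mean_) / self.input_std_
        probs, _, _ = self._forward(self.params, Xs)
        return probs

    # -- persistence ----------------------------------------------------------

    def save(self, path) -> None:
        np.savez(
            path,
            hidden=self.hidden,
            input_mean=self.input_mean_,
            input_std=self.input_std_,
            **{f"param_{k}": v for k, v in self.params.items()},
        )

    @classmethod
    def load(cls, path) -> "LSTMClassifier":
        data = np.load(path)
        model = cls(hidden=int(data["hidden"]))
        model.input_mean_ = float(data["input_mean"])
        model.input_std_ = float(data["input_std"])
        model.params = {
            k[len("param_"):]: data[k] for k in data.files if k.startswith("param_")
        }
        return model
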
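"""Reference classifiers satisfying the training-harness contract.

The contract (see :mod:`augsplit.harness`) is deliberately small so that any
probabilistic image classifier can be benchmarked:

* ``train_epoch(X, y, order, cfg)`` — one pass over the training images in
  the given mini-batch order, updating parameters by momentum SGD with an
  L2 penalty per the training configuration;
* ``predict_proba(X)`` — positive-class probability per image,
  side-effect-free;
* ``get_state()`` / ``set_state(state)`` — parameter snapshots for
  validation-gated checkpointing.

Two implementations are bundled.  :class:`SmallConvNet` is the study's
reference model: a single 3x3 convolution bank, ReLU, 2x2 average pooling
and a dense sigmoid head.  The convolution gives it access to local texture
statistics (the class signal), while the spatially-resolved dense head gives
it enough capacity to partly memorize individual training images — the
ability that makes orbit-level information leakage visible.
:class:`PixelLogistic` is a pixel-space logistic regression used as the fast
tier in tests.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SmallConvNet", "PixelLogistic"]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _im2col3(X: np.ndarray) -> np.ndarray:
    """3x3 zero-padded patches: ``(n, side, side) -> (n, side*side, 9)``."""
    n, s, _ = X.shape
    padded = np.pad(X, ((0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(padded, (3, 3), axis=(1, 2))
    return np.ascontiguousarray(win.reshape(n, s * s, 9))


class _SGDMixin:
    """Momentum SGD step shared by the bundled classifiers."""

    def _step(self, grads: dict, cfg) -> None:
        for name, g in grads.items():
            if name in self._decayed:
                g = g + cfg.l2_factor * getattr(self, name)
            v = self._vel[name]
            v *= cfg.momentum
            v -= cfg.learning_rate * g
            setattr(self, name, getattr(self, name) + v)

    def get_state(self) -> dict:
        return {name: getattr(self, name).copy() for name in self._params}

    def set_state(self, state: dict) -> None:
        for name in self._params:
            setattr(self, name, state[name].copy())


class SmallConvNet(_SGDMixin):
    """One 3x3 convolution bank -> ReLU -> 2x2 average pool -> dense sigmoid.

    Inputs are centered at 0.5 and scaled by ``gain``; the gain and the
    initialization scales are chosen so that the model trains in tens of
    epochs at the study's small learning rate.  Patch features are cached
    per input array (keyed by object identity), so repeated epochs over the
    same training array cost one matrix product each.
    """

    def __init__(self, image_size: int, seed: int, channels: int = 8, gain: float = 12.0):
        if image_size % 2:
            raise ValueError("image_size must be even")
        rng = np.random.default_rng(seed)
        self.side = image_size
        self.channels = channels
        self.gain = gain
        s2 = image_size // 2
        self.W1 = rng.normal(0.0, 0.35, size=(9, channels)).astype(np.float32)
        self.b1 = np.zeros(channels, dtype=np.float32)
        self.w2 = rng.normal(0.0, 1.0 / np.sqrt(s2 * s2 * channels),
                             size=(s2 * s2 * channels,)).astype(np.float32)
        self.b2 = np.zeros(1, dtype=np.float32)
        self._params = ("W1", "b1", "w2", "b2")
        self._decayed = ("W1", "w2")
        self._vel = {n: np.zeros_like(getattr(self, n)) for n in self._params}
        self._cache: dict[int, np.ndarray] = {}

    # -- features -----------------------------------------------------------
    def _cols(self, X: np.ndarray) -> np.ndarray:
        # keyed by object identity; the array itself is kept in the entry so a
        # recycled id of a freed array can never alias a stale cache line
        key = id(X)
        hit = self._cache.get(key)
        if hit is None or hit[0] is not X:
            if len(self._cache) >= 4:
                self._cache.pop(next(iter(self._cache)))
            Z = (np.asarray(X, dtype=np.float32) - 0.5) * self.gain
            self._cache[key] = (X, _im2col3(Z))
        return self._cache[key][1]

    def _forward(self, cols: np.ndarray):
        n = cols.shape[0]
        s, s2 = self.side, self.side // 2
        pre = (cols.reshape(-1, 9) @ self.W1).reshape(n, s * s, self.channels)
        pre += self.b1
        H = np.maximum(pre, 0.0)
        pooled = H.reshape(n, s2, 2, s2, 2, self.channels).mean(axis=(2, 4))
        flat = pooled.reshape(n, -1)
        logit = flat @ self.w2 + self.b2
        return pre, flat, logit

    # -- contract ------------------------------------------------------------
    def train_epoch(self, X: np.ndarray, y: np.ndarray, order: np.ndarray, cfg) -> None:
        cols = self._cols(X)
        yf = np.asarray(y, dtype=np.float32)
        s, s2, C = self.side, self.side // 2, self.channels
        bs = cfg.minibatch_size
        for start in range(0, len(order), bs):
            idx = order[start:start + bs]
            cb, yb = cols[idx], yf[idx]
            n = len(idx)
            pre, flat, logit = self._forward(cb)
            dlogit = (_sigmoid(logit) - yb) / n                      # (n,)
            dw2 = flat.T @ dlogit
            db2 = dlogit.sum(keepdims=True)
            dflat = np.outer(dlogit, self.w2)                        # (n, D)
            dpool = dflat.reshape(n, s2, s2, C)
            dH = np.repeat(np.repeat(dpool, 2, axis=1), 2, axis=2) * 0.25
            dpre = dH.reshape(n, s * s, C)
            dpre[pre <= 0.0] = 0.0
            dpre2 = dpre.reshape(-1, C)
            dW1 = cb.reshape(-1, 9).T @ dpre2
            db1 = dpre2.sum(axis=0)
            self._step({"W1": dW1, "b1": db1, "w2": dw2, "b2": db2}, cfg)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        cols = self._cols(X)
        out = np.empty(cols.shape[0], dtype=np.float64)
        for start in range(0, cols.shape[0], 512):
            _, _, logit = self._forward(cols[start:start + 512])
            out[start:start + 512] = _sigmoid(logit)
        return out


class PixelLogistic(_SGDMixin):
    """Logistic regression on centered raw pixels (the fast test tier)."""

    def __init__(self, image_size: int, seed: int, gain: float = 6.0):
        rng = np.random.default_rng(seed)
        self.side = image_size
        self.gain = gain
        d = image_size * image_size
        self.w = rng.normal(0.0, 1e-3, size=(d,)).astype(np.float32)
        self.b = np.zeros(1, dtype=np.float32)
        self._params = ("w", "b")
        self._decayed = ("w",)
        self._vel = {n: np.zeros_like(getattr(self, n)) for n in self._params}

    def _flat(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=np.float32) - 0.5) * self.gain
        return Z.reshape(Z.shape[0], -1)

    def train_epoch(self, X: np.ndarray, y: np.ndarray, order: np.ndarray, cfg) -> None:
        flat = self._flat(X)
        yf = np.asarray(y, dtype=np.float32)
        bs = cfg.minibatch_size
        for start in range(0, len(order), bs):
            idx = order[start:start + bs]
            fb, yb = flat[idx], yf[idx]
            dlogit = (_sigmoid(fb @ self.w + self.b) - yb) / len(idx)
            self._step({"w": fb.T @ dlogit, "b": dlogit.sum(keepdims=True)}, cfg)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _sigmoid(self._flat(X) @ self.w + self.b).astype(np.float64)
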
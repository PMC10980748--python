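"""Compact seeded conv-regression network used by the zero-shot decoder.

Architecture: 1-D convolution over the time bins (electrodes are the
input channels) -> ReLU -> flatten -> dense hidden layer -> ReLU ->
dropout -> dense output, trained with Adam on mean squared error and
early stopping on a development set.  Everything is plain NumPy with a
single seeded generator, so training is bit-reproducible for a fixed
seed and configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NetConfig", "ConvRegressor"]


@dataclass
class NetConfig:
    conv_channels: int = 32
    kernel: int = 3
    hidden: int = 128
    dropout: float = 0.2
    lr: float = 2e-3
    batch_size: int = 32
    patience: int = 10
    max_epochs: int = 150
    activation: str = "relu"  # "relu" | "linear"


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    return np.maximum(z, 0.0) if kind == "relu" else z


def _act_grad(z: np.ndarray, kind: str) -> np.ndarray:
    return (z > 0).astype(z.dtype) if kind == "relu" else np.ones_like(z)


class ConvRegressor:
    """Map (n_electrodes x n_bins) inputs to a continuous target vector."""

    def __init__(self, n_channels: int, n_bins: int, n_out: int, config: NetConfig,
                 seed: int = 0):
        self.cfg = config
        self.n_bins = n_bins
        self.rng = np.random.default_rng(seed)
        c, k, h = config.conv_channels, config.kernel, config.hidden
        # He-style init scaled by fan-in
        self.Wc = self.rng.standard_normal((c, n_channels, k)) / np.sqrt(n_channels * k)
        self.bc = np.zeros(c)
        flat = c * n_bins
        self.W1 = self.rng.standard_normal((flat, h)) / np.sqrt(flat)
        self.b1 = np.zeros(h)
        self.W2 = self.rng.standard_normal((h, n_out)) / np.sqrt(h)
        self.b2 = np.zeros(n_out)
        self._adam_state = None

    # -- forward / backward -------------------------------------------------

    def _unfold(self, x: np.ndarray) -> np.ndarray:
        """Pad bins and stack sliding windows: (B, E, K, T)."""
        k = self.cfg.kernel
        pad = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        return np.stack([xp[:, :, j : j + self.n_bins] for j in range(k)], axis=2)

    def _forward(self, x: np.ndarray, train: bool = False):
        cfg = self.cfg
        xu = self._unfold(x)
        zc = np.einsum("bekt,cek->bct", xu, self.Wc) + self.bc[:, None]
        ac = _act(zc, cfg.activation)
        flat = ac.reshape(x.shape[0], -1)
        z1 = flat @ self.W1 + self.b1
        a1 = _act(z1, cfg.activation)
        if train and cfg.dropout > 0:
            mask = (self.rng.random(a1.shape) >= cfg.dropout) / (1 - cfg.dropout)
            a1 = a1 * mask
        else:
            mask = None
        y = a1 @ self.W2 + self.b2
        cache = (xu, zc, flat, z1, a1, mask)
        return y, cache

    def predict(self, x: np.ndarray) -> np.ndarray:
        y, _ = self._forward(np.asarray(x, dtype=float), train=False)
        return y

    def _backward(self, x, y_true, y_pred, cache):
        cfg = self.cfg
        xu, zc, flat, z1, a1, mask = cache
        B = x.shape[0]
        dy = 2.0 * (y_pred - y_true) / (B * y_true.shape[1])  # d MSE
        gW2 = a1.T @ dy
        gb2 = dy.sum(axis=0)
        da1 = dy @ self.W2.T
        if mask is not None:
            da1 = da1 * mask
        dz1 = da1 * _act_grad(z1, cfg.activation)
        gW1 = flat.T @ dz1
        gb1 = dz1.sum(axis=0)
        dflat = dz1 @ self.W1.T
        dac = dflat.reshape(zc.shape)
        dzc = dac * _act_grad(zc, cfg.activation)
        gWc = np.einsum("bct,bekt->cek", dzc, xu)
        gbc = dzc.sum(axis=(0, 2))
        return [gWc, gbc, gW1, gb1, gW2, gb2]

    # -- training -----------------------------------------------------------

    @property
    def _params(self):
        return [self.Wc, self.bc, self.W1, self.b1, self.W2, self.b2]

    def _adam_step(self, grads):
        if self._adam_state is None:
            self._adam_state = {
                "m": [np.zeros_like(p) for p in self._params],
                "v": [np.zeros_like(p) for p in self._params],
                "t": 0,
            }
        st = self._adam_state
        st["t"] += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(self._params, grads, st["m"], st["v"]):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** st["t"])
            vhat = v / (1 - b2 ** st["t"])
            p -= self.cfg.lr * mhat / (np.sqrt(vhat) + eps)

    def mse(self, x, y) -> float:
        pred = self.predict(x)
        return float(np.mean((pred - y) ** 2))

    def fit(self, train_x, train_y, dev_x, dev_y) -> dict:
        """Minimize training MSE, early-stopping on the dev set.

        Keeps the best (dev-MSE) parameters seen; raises on non-finite
        loss with a dump of the configuration.
        """
        cfg = self.cfg
        train_x = np.asarray(train_x, dtype=float)
        train_y = np.asarray(train_y, dtype=float)
        n = train_x.shape[0]
        best = self.mse(dev_x, dev_y)
        best_params = [p.copy() for p in self._params]
        history = {"dev_mse": [best], "init_dev_mse": best}
        stall = 0
        for _ in range(cfg.max_epochs):
            order = self.rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb, yb = train_x[idx], train_y[idx]
                pred, cache = self._forward(xb, train=True)
                if not np.isfinite(pred).all():
                    raise FloatingPointError(
                        f"decoder training diverged (non-finite loss); config={cfg}"
                    )
                grads = self._backward(xb, yb, pred, cache)
                self._adam_step(grads)
            dev = self.mse(dev_x, dev_y)
            history["dev_mse"].append(dev)
            if dev < best - 1e-12:
                best = dev
                best_params = [p.copy() for p in self._params]
                stall = 0
            else:
                stall += 1
                if stall >= cfg.patience:
                    break
        for p, bp in zip(self._params, best_params):
            p[...] = bp
        history["best_dev_mse"] = best
        return history
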
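"""Minimal NumPy CNN engine for the residual grid-removal denoiser.

Implements just what the patch denoiser needs: same-padded 2-D convolutions
(im2col), per-channel batch normalization, ReLU, Adam, and an early-stopped
training loop minimizing the residual-learning loss

    l(Theta) = 1/(2N) sum_i || R(y_i; Theta) - (y_i - x_i) ||_F^2

so the network output approximates the grid component v = y - x, which is
then subtracted from the observation.  float32 throughout.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .errors import ParameterError


@dataclass
class DenoiserSpec:
    """Architecture and training configuration of the residual denoiser.

    The default architecture is the full 17-layer network (Conv+ReLU, then
    15 Conv+BN+ReLU blocks, then a single-filter Conv) with 64 filters of
    7x7; ``desk()`` returns a reduced preset sized for CPU-scale training.
    """

    depth: int = 17
    filters: int = 64
    kernel: int = 7
    residual_output: bool = True
    epochs: int = 30
    batch_size: int = 128
    lr: float = 1e-3
    patience: int = 5
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.depth < 2:
            raise ParameterError("depth must be >= 2")
        if self.kernel % 2 == 0:
            raise ParameterError("kernel must be odd")

    @staticmethod
    def desk() -> "DenoiserSpec":
        """CPU-scale preset used by the test suite and desk-scale training."""
        return DenoiserSpec(depth=5, filters=8, kernel=5, epochs=5,
                            batch_size=8, lr=1e-2, patience=5)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H, W) -> (B*H*W, C*k*k) with same-padding."""
    b, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (B, C, H, W, k, k) -> (B, H, W, C, k, k)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b * h * w, c * k * k)
    return np.ascontiguousarray(cols)


class _Conv:
    def __init__(self, c_in, c_out, k, rng):
        fan_in = c_in * k * k
        self.w = (rng.standard_normal((c_out, fan_in))
                  * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.c_in = c_in
        self._cache = None
        self._adam = {}

    def forward(self, x, train):
        b, c, h, w = x.shape
        cols = _im2col(x, self.k)
        out = cols @ self.w.T + self.b
        if train:
            self._cache = (cols, (b, c, h, w))
        return out.reshape(b, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, dout):
        cols, (b, c, h, w) = self._cache
        k, p = self.k, self.k // 2
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, dout.shape[1])
        self.dw = (dflat.T @ cols).astype(np.float32)
        self.db = dflat.sum(axis=0).astype(np.float32)
        dcols = (dflat @ self.w).reshape(b, h, w, c, k, k)
        dxp = np.zeros((b, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + h, j:j + w] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2)
        self._cache = None
        return dxp[:, :, p:p + h, p:p + w]

    def params(self):
        return (("w", self.w, "dw"), ("b", self.b, "db"))


class _BatchNorm:
    def __init__(self, c, momentum=0.9, eps=1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None
        self._adam = {}

    def forward(self, x, train):
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu).astype(np.float32)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(np.float32)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dout):
        xhat, inv = self._cache
        n = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.dgamma = (dout * xhat).sum(axis=(0, 2, 3)).astype(np.float32)
        self.dbeta = dout.sum(axis=(0, 2, 3)).astype(np.float32)
        g = self.gamma[None, :, None, None] * inv[None, :, None, None]
        dx = g * (dout
                  - self.dbeta[None, :, None, None] / n
                  - xhat * self.dgamma[None, :, None, None] / n)
        self._cache = None
        return dx.astype(np.float32)

    def params(self):
        return (("gamma", self.gamma, "dgamma"), ("beta", self.beta, "dbeta"))


class _ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x, train):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout):
        dx = dout * self._mask
        self._mask = None
        return dx

    def params(self):
        return ()


class DnCNN:
    """Residual patch denoiser: predicts the grid component of an input patch.

    ``fit`` trains on (noisy, clean) patch pairs; ``predict_residual``
    evaluates R(y); ``denoise`` returns y - R(y).
    """

    def __init__(self, spec: DenoiserSpec = None):
        self.spec = spec or DenoiserSpec()
        rng = np.random.default_rng(self.spec.seed)
        s = self.spec
        layers = [_Conv(1, s.filters, s.kernel, rng), _ReLU()]
        for _ in range(s.depth - 2):
            layers += [_Conv(s.filters, s.filters, s.kernel, rng),
                       _BatchNorm(s.filters), _ReLU()]
        layers += [_Conv(s.filters, 1, s.kernel, rng)]
        # zero-init the output conv: the residual branch starts at the exact
        # identity and only departs where the data demands it
        layers[-1].w[:] = 0.0
        self.layers = layers
        self.history_ = []
        self._step = 0

    # ------------------------------------------------------------------
    def _forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def _backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def _adam_update(self):
        self._step += 1
        lr, b1, b2, eps = self.spec.lr, 0.9, 0.999, 1e-8
        t = self._step
        for layer in self.layers:
            for name, param, gname in layer.params():
                g = getattr(layer, gname)
                state = layer._adam.setdefault(name, [np.zeros_like(param),
                                                      np.zeros_like(param)])
                m, v = state
                m[:] = b1 * m + (1 - b1) * g
                v[:] = b2 * v + (1 - b2) * g * g
                mhat = m / (1 - b1 ** t)
                vhat = v / (1 - b2 ** t)
                param -= lr * mhat / (np.sqrt(vhat) + eps)

    # ------------------------------------------------------------------
    def fit(self, noisy: np.ndarray, clean: np.ndarray) -> "DnCNN":
        """Train on paired patches in [0, 1]; shapes (N, H, W) must match."""
        noisy = np.asarray(noisy, dtype=np.float32)
        clean = np.asarray(clean, dtype=np.float32)
        if noisy.shape != clean.shape or noisy.ndim != 3:
            raise ParameterError("noisy/clean patch stacks must have equal "
                                 "(N, H, W) shapes")
        n = noisy.shape[0]
        rng = np.random.default_rng(self.spec.seed + 1)
        idx = rng.permutation(n)
        n_val = max(1, int(round(self.spec.val_fraction * n))) if n > 10 else 0
        val_idx, train_idx = idx[:n_val], idx[n_val:]
        target = noisy - clean                       # v = y - x
        best_val = np.inf
        best_state = None
        stale = 0
        bs = self.spec.batch_size
        for epoch in range(self.spec.epochs):
            order = rng.permutation(train_idx)
            losses = []
            for k in range(0, len(order), bs):
                batch = order[k:k + bs]
                y = noisy[batch][:, None]
                v = target[batch][:, None]
                r = self._forward(y, train=True)
                diff = r - v
                loss = 0.5 * float(np.mean(np.sum(diff ** 2, axis=(1, 2, 3))))
                losses.append(loss)
                self._backward(diff / len(batch))
                self._adam_update()
            if n_val:
                val = self.evaluate_loss(noisy[val_idx], clean[val_idx])
            else:
                val = float(np.mean(losses))
            self.history_.append({"epoch": epoch,
                                  "train_loss": float(np.mean(losses)),
                                  "val_loss": val})
            if val < best_val - 1e-9:
                best_val = val
                best_state = self.get_weights()
                stale = 0
            else:
                stale += 1
                if stale >= self.spec.patience:
                    break
        if best_state is not None:
            self.set_weights(best_state)
        return self

    def evaluate_loss(self, noisy, clean) -> float:
        noisy = np.asarray(noisy, dtype=np.float32)
        clean = np.asarray(clean, dtype=np.float32)
        r = self.predict_residual(noisy)
        diff = r - (noisy - clean)
        return 0.5 * float(np.mean(np.sum(diff ** 2, axis=(1, 2))))

    def predict_residual(self, patches: np.ndarray) -> np.ndarray:
        """R(y) for a stack of patches (N, H, W), evaluated in batches."""
        patches = np.asarray(patches, dtype=np.float32)
        single = patches.ndim == 2
        if single:
            patches = patches[None]
        out = np.empty_like(patches)
        bs = max(1, self.spec.batch_size)
        for k in range(0, patches.shape[0], bs):
            out[k:k + bs] = self._forward(patches[k:k + bs][:, None])[:, 0]
        return out[0] if single else out

    def denoise(self, patches: np.ndarray) -> np.ndarray:
        return np.asarray(patches, dtype=np.float32) - self.predict_residual(patches)

    # ------------------------------------------------------------------
    def get_weights(self) -> list:
        out = []
        for layer in self.layers:
            entry = {name: param.copy() for name, param, _ in layer.params()}
            if isinstance(layer, _BatchNorm):
                entry["running_mean"] = layer.running_mean.copy()
                entry["running_var"] = layer.running_var.copy()
            out.append(entry)
        return out

    def set_weights(self, state: list) -> None:
        for layer, entry in zip(self.layers, state):
            for name, param, _ in layer.params():
                param[:] = entry[name]
            if isinstance(layer, _BatchNorm):
                layer.running_mean[:] = entry["running_mean"]
                layer.running_var[:] = entry["running_var"]

    def save(self, path: str) -> None:
        """Single-file weights archive + JSON spec sidecar."""
        arrays = {}
        for i, entry in enumerate(self.get_weights()):
            for name, arr in entry.items():
                arrays[f"l{i}_{name}"] = arr
        np.savez(path, **arrays)
        with open(str(path) + ".spec.json", "w") as fh:
            json.dump(asdict(self.spec), fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "DnCNN":
        with open(str(path) + ".spec.json") as fh:
            spec = DenoiserSpec(**json.load(fh))
        model = cls(spec)
        path_npz = path if str(path).endswith(".npz") else str(path) + ".npz"
        data = np.load(path_npz)
        state = model.get_weights()
        for i, entry in enumerate(state):
            for name in entry:
                entry[name] = data[f"l{i}_{name}"]
        model.set_weights(state)
        return model
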
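"""CNN deep-feature extraction from PNCC images.

A small convolutional network — three convolution+max-pool blocks, a
dropout layer and a 64-unit fully connected layer feeding a 3-class
softmax head — is trained on labeled PNCC images with Adam. The class
head exists only to supervise training: at extraction time it is
discarded and the 64 penultimate activations are the deep features
fused with the time/frequency descriptors.

The network is implemented directly on numpy (im2col convolutions,
explicit backward passes). At this scale — images of about 64 x 40,
tens of thousands of parameters — that is fast on a single CPU and,
unlike GPU frameworks, bitwise reproducible for a given seed, which
the pipeline's reproducibility contract relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .audio_io import CLASS_ORDER
from .pncc import PnccImage


@dataclass
class CnnSpec:
    """Architecture and optimization settings of the feature extractor."""

    input_shape: Tuple[int, int] = (64, 40)
    conv_filters: Tuple[int, int, int] = (16, 32, 64)
    kernel: int = 3
    pool: int = 2
    fc_units: int = 64
    n_classes: int = 3
    dropout_rate: float = 0.5
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    epochs: int = 50
    batch_size: int = 32
    seed: int = 0


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B,H,W,C) -> (B,H,W,k*k*C) patch matrix for same-padded stride-1 conv."""
    b, h, w, c = x.shape
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    cols = np.empty((b, h, w, k * k * c), dtype=x.dtype)
    idx = 0
    for i in range(k):
        for j in range(k):
            cols[..., idx : idx + c] = xp[:, i : i + h, j : j + w, :]
            idx += c
    return cols


def _col2im(dcols: np.ndarray, shape: Tuple[int, ...], k: int) -> np.ndarray:
    b, h, w, c = shape
    pad = k // 2
    dxp = np.zeros((b, h + 2 * pad, w + 2 * pad, c))
    idx = 0
    for i in range(k):
        for j in range(k):
            dxp[:, i : i + h, j : j + w, :] += dcols[..., idx : idx + c]
            idx += c
    return dxp[:, pad : pad + h, pad : pad + w, :]


class _Adam:
    def __init__(self, params: List[np.ndarray], lr: float, b1: float, b2: float):
        self.params = params
        self.lr, self.b1, self.b2 = lr, b1, b2
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: List[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + 1e-8)


class DeepFeatureExtractor:
    """Conv(3x3)->pool blocks + dropout + FC-64 + softmax head.

    Use :meth:`fit` on labeled PNCC images, then :meth:`transform` to
    obtain 64-dimensional deep-feature vectors (dropout off, head
    ignored).
    """

    def __init__(self, spec: Optional[CnnSpec] = None):
        self.spec = spec or CnnSpec()
        self.trained = False
        self.loss_history: List[float] = []
        self._norm: Tuple[float, float] = (0.0, 1.0)
        self._init_params()

    def _init_params(self) -> None:
        s = self.spec
        rng = np.random.default_rng(s.seed)
        h, w = s.input_shape
        if h % (s.pool ** 3) or w % (s.pool ** 3):
            raise ValueError(
                f"input shape {s.input_shape} must be divisible by "
                f"{s.pool ** 3} for three pooling stages"
            )
        self.W: List[np.ndarray] = []
        self.b: List[np.ndarray] = []
        c_in = 1
        for f in s.conv_filters:
            fan_in = s.kernel * s.kernel * c_in
            self.W.append(rng.normal(0, np.sqrt(2.0 / fan_in), (fan_in, f)))
            self.b.append(np.zeros(f))
            c_in = f
        flat = (h // s.pool**3) * (w // s.pool**3) * s.conv_filters[-1]
        self.W.append(rng.normal(0, np.sqrt(2.0 / flat), (flat, s.fc_units)))
        self.b.append(np.zeros(s.fc_units))
        self.W.append(
            rng.normal(0, np.sqrt(2.0 / s.fc_units), (s.fc_units, s.n_classes))
        )
        self.b.append(np.zeros(s.n_classes))

    # -- forward/backward ------------------------------------------------

    def _forward(
        self, x: np.ndarray, rng: Optional[np.random.Generator]
    ) -> Tuple[np.ndarray, np.ndarray, dict]:
        """Returns (fc64 activations, class logits, cache). rng=None => eval."""
        s = self.spec
        cache: dict = {"conv": []}
        a = x
        for li in range(3):
            cols = _im2col(a, s.kernel)
            z = cols @ self.W[li] + self.b[li]
            relu = np.maximum(z, 0.0)
            b_, h_, w_, c_ = relu.shape
            pooled = relu.reshape(
                b_, h_ // s.pool, s.pool, w_ // s.pool, s.pool, c_
            ).max(axis=(2, 4))
            cache["conv"].append((a.shape, cols, z, relu, pooled))
            a = pooled
        flat = a.reshape(a.shape[0], -1)
        if rng is not None and s.dropout_rate > 0:
            keep = 1.0 - s.dropout_rate
            mask = (rng.random(flat.shape) < keep) / keep
            flat = flat * mask
            cache["dropout"] = mask
        cache["flat"] = flat
        z_fc = flat @ self.W[3] + self.b[3]
        fc = np.maximum(z_fc, 0.0)
        cache["z_fc"], cache["fc"] = z_fc, fc
        logits = fc @ self.W[4] + self.b[4]
        return fc, logits, cache

    def _backward(
        self, dlogits: np.ndarray, cache: dict
    ) -> List[np.ndarray]:
        s = self.spec
        grads: List[np.ndarray] = [None] * len(self.W)  # type: ignore
        fc, flat = cache["fc"], cache["flat"]
        grads[4] = fc.T @ dlogits
        db4 = dlogits.sum(axis=0)
        dfc = dlogits @ self.W[4].T
        dz_fc = dfc * (cache["z_fc"] > 0)
        grads[3] = flat.T @ dz_fc
        db3 = dz_fc.sum(axis=0)
        dflat = dz_fc @ self.W[3].T
        if "dropout" in cache:
            dflat = dflat * cache["dropout"]
        a_shape, _, _, _, pooled = cache["conv"][2]
        da = dflat.reshape(pooled.shape)
        dbs = [None, None, None, db3, db4]
        for li in range(2, -1, -1):
            in_shape, cols, z, relu, pooled = cache["conv"][li]
            b_, h_, w_, c_ = relu.shape
            rs = relu.reshape(b_, h_ // s.pool, s.pool, w_ // s.pool, s.pool, c_)
            mask = rs == pooled[:, :, None, :, None, :]
            # distribute pooled gradient to max positions (ties split evenly)
            counts = mask.sum(axis=(2, 4), keepdims=True)
            drelu = (
                mask * (da[:, :, None, :, None, :] / counts)
            ).reshape(b_, h_, w_, c_)
            dz = drelu * (z > 0)
            grads[li] = cols.reshape(-1, cols.shape[-1]).T @ dz.reshape(-1, c_)
            dbs[li] = dz.sum(axis=(0, 1, 2))
            dcols = dz @ self.W[li].T
            da = _col2im(dcols, in_shape, s.kernel)
        self._dbs = dbs
        return grads

    # -- public API ------------------------------------------------------

    @staticmethod
    def _stack(images: Sequence[PnccImage]) -> np.ndarray:
        arrs = [np.asarray(im.values, dtype=np.float64) for im in images]
        shapes = {a.shape for a in arrs}
        if len(shapes) != 1:
            raise ValueError(f"images must share one shape, got {shapes}")
        return np.stack(arrs)[..., None]

    def fit(
        self,
        images: Sequence[PnccImage],
        labels: Sequence[str],
        epochs: Optional[int] = None,
    ) -> "DeepFeatureExtractor":
        """Train on labeled images; records per-epoch mean loss."""
        s = self.spec
        x = self._stack(images)
        if x.shape[1:3] != tuple(s.input_shape):
            raise ValueError(
                f"image shape {x.shape[1:3]} != spec input {s.input_shape}"
            )
        classes = sorted(set(labels), key=lambda c: (
            CLASS_ORDER.index(c) if c in CLASS_ORDER else len(CLASS_ORDER), c
        ))
        if len(classes) < 2:
            raise ValueError("training requires at least two classes")
        if len(classes) > s.n_classes:
            raise ValueError("more classes than the network head supports")
        self.classes_ = classes
        y = np.array([classes.index(l) for l in labels])
        mean, std = float(x.mean()), float(x.std())
        self._norm = (mean, std if std > 0 else 1.0)
        x = (x - self._norm[0]) / self._norm[1]

        rng = np.random.default_rng(s.seed)
        params = self.W + self.b
        opt = _Adam(params, s.learning_rate, s.beta1, s.beta2)
        n = x.shape[0]
        n_epochs = s.epochs if epochs is None else epochs
        self.loss_history = []
        for _ in range(n_epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, s.batch_size):
                idx = order[start : start + s.batch_size]
                xb, yb = x[idx], y[idx]
                _, logits, cache = self._forward(xb, rng)
                logits = logits - logits.max(axis=1, keepdims=True)
                expz = np.exp(logits)
                probs = expz / expz.sum(axis=1, keepdims=True)
                loss = -np.mean(
                    np.log(probs[np.arange(len(yb)), yb] + 1e-12)
                )
                losses.append(loss * len(yb))
                dlogits = probs.copy()
                dlogits[np.arange(len(yb)), yb] -= 1.0
                dlogits /= len(yb)
                grads = self._backward(dlogits, cache)
                opt.step(grads + self._dbs)
            self.loss_history.append(float(np.sum(losses) / n))
        self.trained = True
        return self

    def transform(self, images: Sequence[PnccImage]) -> np.ndarray:
        """64-dim deep-feature vectors (n_images x fc_units), dropout off."""
        if not self.trained:
            raise RuntimeError("extractor must be trained before extraction")
        x = self._stack(images)
        x = (x - self._norm[0]) / self._norm[1]
        out = []
        for start in range(0, x.shape[0], 64):
            fc, _, _ = self._forward(x[start : start + 64], rng=None)
            out.append(fc)
        return np.concatenate(out)

    def predict_classes(self, images: Sequence[PnccImage]) -> List[str]:
        """Class-head predictions (used only for training diagnostics)."""
        if not self.trained:
            raise RuntimeError("extractor must be trained first")
        x = self._stack(images)
        x = (x - self._norm[0]) / self._norm[1]
        labels = []
        for start in range(0, x.shape[0], 64):
            _, logits, _ = self._forward(x[start : start + 64], rng=None)
            labels.extend(self.classes_[int(i)] for i in np.argmax(logits, axis=1))
        return labels


    def save(self, path) -> None:
        """Persist weights, normalization and class list to an .npz file."""
        if not self.trained:
            raise RuntimeError("nothing to save: extractor untrained")
        arrays = {f"W{i}": w for i, w in enumerate(self.W)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.b)})
        np.savez(
            path,
            norm=np.array(self._norm),
            classes=np.array(self.classes_),
            loss=np.array(self.loss_history),
            **arrays,
        )

    @classmethod
    def load(cls, path, spec: Optional[CnnSpec] = None) -> "DeepFeatureExtractor":
        data = np.load(path, allow_pickle=False)
        ext = cls(spec)
        ext.W = [data[f"W{i}"] for i in range(5)]
        ext.b = [data[f"b{i}"] for i in range(5)]
        ext._norm = (float(data["norm"][0]), float(data["norm"][1]))
        ext.classes_ = [str(c) for c in data["classes"]]
        ext.loss_history = [float(v) for v in data["loss"]]
        ext.trained = True
        return ext


def extract_deep_features(
    image: PnccImage, extractor: DeepFeatureExtractor
) -> np.ndarray:
    """64 activations of the trained extractor's penultimate layer."""
    return extractor.transform([image])[0]
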
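"""A compact residual CNN classifier implemented on numpy.

The network follows the classic 18-weighted-layer residual design: one
3x3 stem convolution, four stages of two basic blocks (two 3x3
convolutions each, identity or 1x1-projection skip), global average
pooling and a 2-node fully-connected head (True/False class scores).
Convolutions run through im2col + BLAS matmul; all gradients are written
by hand and checked against numerical differentiation in the test suite.
Training uses Adam with class-weighted cross-entropy; the parameter set
with minimal validation loss across epochs is the one kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .images import ProfileImage

__all__ = [
    "ResNetClassifier",
    "TrainedModel",
    "TrainConfig",
    "train",
    "predict",
    "predict_proba",
]


# ---------------------------------------------------------------------------
# layers


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # n, c, ho, wo, k, k
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(dcols: np.ndarray, x_shape, k: int, stride: int, pad: int, ho: int, wo: int):
    n, c, h, w = x_shape
    dx = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    dwin = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            dx[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += dwin[
                :, :, :, :, i, j
            ]
    if pad:
        dx = dx[:, :, pad:-pad, pad:-pad]
    return dx


class Conv2d:
    def __init__(self, cin: int, cout: int, k: int, stride: int, rng: np.random.Generator):
        fan_in = cin * k * k
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k)).astype(
            np.float32
        )
        self.k, self.stride, self.pad = k, stride, k // 2
        self.dw = np.zeros_like(self.w)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        cols, ho, wo = _im2col(x, self.k, self.stride, self.pad)
        wmat = self.w.reshape(self.w.shape[0], -1)
        out = cols @ wmat.T
        if train:
            self._cache = (cols, x.shape, ho, wo)
        n = x.shape[0]
        return out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape, ho, wo = self._cache
        n, cout = dy.shape[0], dy.shape[1]
        dy_mat = dy.transpose(0, 2, 3, 1).reshape(n * ho * wo, cout)
        self.dw = (dy_mat.T @ cols).reshape(self.w.shape)
        dcols = dy_mat @ self.w.reshape(cout, -1)
        return _col2im(dcols, x_shape, self.k, self.stride, self.pad, ho, wo)

    def params(self):
        yield self.w, self.dw


class BatchNorm2d:
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self._batch_mean, self._batch_var = mean, var
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.dgamma = (dy * xhat).sum(axis=(0, 2, 3))
        self.dbeta = dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma[None, :, None, None]
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) * inv[None, :, None, None]
        return dx

    def params(self):
        yield self.gamma, self.dgamma
        yield self.beta, self.dbeta


class ReLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask

    def params(self):
        return iter(())


class Linear:
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / cin), size=(cout, cin)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w.T + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dw = dy.T @ self._x
        self.db = dy.sum(axis=0)
        return dy @ self.w

    def params(self):
        yield self.w, self.dw
        yield self.b, self.db


class BasicBlock:
    """conv-bn-relu-conv-bn + skip (1x1 projection when shape changes), relu."""

    def __init__(self, cin: int, cout: int, stride: int, rng: np.random.Generator):
        self.conv1 = Conv2d(cin, cout, 3, stride, rng)
        self.bn1 = BatchNorm2d(cout)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, 1, rng)
        self.bn2 = BatchNorm2d(cout)
        self.relu2 = ReLU()
        if stride != 1 or cin != cout:
            self.proj: Conv2d | None = Conv2d(cin, cout, 1, stride, rng)
            self.proj_bn: BatchNorm2d | None = BatchNorm2d(cout)
        else:
            self.proj = self.proj_bn = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        out = self.bn2.forward(self.conv2.forward(out, train), train)
        skip = x if self.proj is None else self.proj_bn.forward(self.proj.forward(x, train), train)
        return self.relu2.forward(out + skip, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dsum = self.relu2.backward(dy)
        dmain = self.conv1.backward(
            self.bn1.backward(self.relu1.backward(self.conv2.backward(self.bn2.backward(dsum))))
        )
        if self.proj is None:
            dskip = dsum
        else:
            dskip = self.proj.backward(self.proj_bn.backward(dsum))
        return dmain + dskip

    def params(self):
        mods = [self.conv1, self.bn1, self.conv2, self.bn2]
        if self.proj is not None:
            mods += [self.proj, self.proj_bn]
        for m in mods:
            yield from m.params()


class ResNetClassifier:
    """18-weighted-layer residual CNN with a 2-node head."""

    ARCH_ID = "resnet18-numpy"

    def __init__(self, in_channels: int = 3, width: int = 8, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.width = width
        self.in_channels = in_channels
        self.stem = Conv2d(in_channels, width, 3, 1, rng)
        self.stem_bn = BatchNorm2d(width)
        self.stem_relu = ReLU()
        self.blocks: list[BasicBlock] = []
        cin = width
        for stage, (cout, stride) in enumerate(
            [(width, 1), (2 * width, 2), (4 * width, 2), (8 * width, 2)]
        ):
            self.blocks.append(BasicBlock(cin, cout, stride, rng))
            self.blocks.append(BasicBlock(cout, cout, 1, rng))
            cin = cout
        self.head = Linear(8 * width, 2, rng)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        out = self.stem_relu.forward(self.stem_bn.forward(self.stem.forward(x, train), train), train)
        for blk in self.blocks:
            out = blk.forward(out, train)
        self._pool_shape = out.shape
        pooled = out.mean(axis=(2, 3))
        return self.head.forward(pooled, train)

    def backward(self, dlogits: np.ndarray) -> None:
        dpool = self.head.backward(dlogits)
        n, c, h, w = self._pool_shape
        dout = np.broadcast_to(dpool[:, :, None, None] / (h * w), self._pool_shape).copy()
        for blk in reversed(self.blocks):
            dout = blk.backward(dout)
        self.stem.backward(self.stem_bn.backward(self.stem_relu.backward(dout)))

    def params(self):
        yield from self.stem.params()
        yield from self.stem_bn.params()
        for blk in self.blocks:
            yield from blk.params()
        yield from self.head.params()

    def state(self) -> list[np.ndarray]:
        arrays = [p for p, _ in self.params()]
        for bn in self._batchnorms():
            arrays += [bn.running_mean, bn.running_var]
        return [a.copy() for a in arrays]

    def load_state(self, arrays: list[np.ndarray]) -> None:
        params = [p for p, _ in self.params()]
        stats = []
        for bn in self._batchnorms():
            stats += [("mean", bn), ("var", bn)]
        if len(arrays) != len(params) + len(stats):
            raise ValueError("state size mismatch with architecture")
        for p, a in zip(params, arrays[: len(params)]):
            p[...] = a
        for (kind, bn), a in zip(stats, arrays[len(params) :]):
            if kind == "mean":
                bn.running_mean = a.copy()
            else:
                bn.running_var = a.copy()

    def _batchnorms(self):
        out = [self.stem_bn]
        for blk in self.blocks:
            out += [blk.bn1, blk.bn2]
            if blk.proj_bn is not None:
                out.append(blk.proj_bn)
        return out


def recalibrate_batchnorm(
    net: ResNetClassifier, x: np.ndarray, batch_size: int = 256, max_batches: int = 8
) -> None:
    """Replace BN running statistics with exact averages over training batches.

    With few optimizer steps the momentum-averaged statistics lag the
    distribution the deeper layers were actually trained on, which wrecks
    eval-mode inference on small corpora; recomputing them (precise BN)
    restores train/eval consistency.
    """
    bns = net._batchnorms()
    sums = [np.zeros_like(b.running_mean, dtype=np.float64) for b in bns]
    sqs = [np.zeros_like(b.running_var, dtype=np.float64) for b in bns]
    n = 0
    for start in range(0, min(len(x), batch_size * max_batches), batch_size):
        xb = x[start : start + batch_size]
        if len(xb) < 2:
            continue
        net.forward(xb, train=True)
        for i, b in enumerate(bns):
            sums[i] += b._batch_mean
            sqs[i] += b._batch_var
        n += 1
    if n == 0:
        return
    for i, b in enumerate(bns):
        b.running_mean = (sums[i] / n).astype(np.float32)
        b.running_var = (sqs[i] / n).astype(np.float32)


# ---------------------------------------------------------------------------
# loss / optimizer


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_cross_entropy(
    logits: np.ndarray, y: np.ndarray, class_weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean weighted CE and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    w = class_weights[y]
    loss = float(-(w * np.log(p[np.arange(n), y] + 1e-12)).sum() / w.sum())
    grad = p * w[:, None]
    grad[np.arange(n), y] -= w
    return loss, grad / w.sum()


class Adam:
    def __init__(self, model: ResNetClassifier, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.model, self.lr, self.b1, self.b2, self.eps = model, lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in model.params()]
        self.v = [np.zeros_like(p) for p, _ in model.params()]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, (p, g) in enumerate(self.model.params()):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# training API


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 8
    batch_size: int = 128
    learning_rate: float = 1e-3
    width: int = 8
    seed: int = 0


@dataclass
class TrainedModel:
    """Trained classifier plus training metadata."""

    network: ResNetClassifier
    image_size: int
    class_weights: tuple[float, float]
    config: TrainConfig
    history: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = float("inf")

    @staticmethod
    def _paths(path: str | Path) -> tuple[Path, Path]:
        blob = Path(path)
        if blob.suffix != ".npz":
            blob = Path(str(blob) + ".npz")
        return blob, Path(str(blob) + ".meta")

    def save(self, path: str | Path) -> None:
        """Parameter blob (.npz) plus a key=value text sidecar (.npz.meta)."""
        blob, sidecar = self._paths(path)
        arrays = {f"a{i}": a for i, a in enumerate(self.network.state())}
        np.savez(blob, **arrays)
        meta = {
            "architecture": self.network.ARCH_ID,
            "width": self.network.width,
            "in_channels": self.network.in_channels,
            "image_size": self.image_size,
            "epochs": self.config.epochs,
            "batch_size": self.config.batch_size,
            "learning_rate": self.config.learning_rate,
            "seed": self.config.seed,
            "class_weight_true": self.class_weights[0],
            "class_weight_false": self.class_weights[1],
            "best_epoch": self.best_epoch,
            "best_val_loss": self.best_val_loss,
        }
        sidecar.write_text("".join(f"{k} = {v}\n" for k, v in meta.items()))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        blob, sidecar = cls._paths(path)
        meta = {}
        for line in sidecar.read_text().splitlines():
            if "=" in line:
                k, v = (s.strip() for s in line.split("=", 1))
                meta[k] = v
        net = ResNetClassifier(int(meta["in_channels"]), int(meta["width"]), seed=0)
        with np.load(blob) as data:
            net.load_state([data[f"a{i}"] for i in range(len(data.files))])
        cfg = TrainConfig(
            epochs=int(meta["epochs"]),
            batch_size=int(meta["batch_size"]),
            learning_rate=float(meta["learning_rate"]),
            width=int(meta["width"]),
            seed=int(meta["seed"]),
        )
        model = cls(
            net,
            image_size=int(meta["image_size"]),
            class_weights=(float(meta["class_weight_true"]), float(meta["class_weight_false"])),
            config=cfg,
            best_epoch=int(meta["best_epoch"]),
            best_val_loss=float(meta["best_val_loss"]),
        )
        return model


def _to_arrays(images: list[ProfileImage]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([im.tensor for im in images]).astype(np.float32)
    y = np.array([1 if im.label else 0 for im in images], dtype=np.int64)
    return x, y


def class_weight_vector(y: np.ndarray) -> np.ndarray:
    """Inverse-frequency class weights, normalized to mean 1.

    Index 0 = False, index 1 = True (matching the label encoding).
    """
    counts = np.bincount(y, minlength=2).astype(float)
    counts[counts == 0] = 1.0
    w = counts.sum() / (2.0 * counts)
    return w


def train(
    train_images: list[ProfileImage],
    val_images: list[ProfileImage],
    config: TrainConfig = TrainConfig(),
) -> TrainedModel:
    """Train the residual CNN; keep the epoch with minimal validation loss."""
    if not train_images or not val_images:
        raise ValueError("training and validation sets must be non-empty")
    xtr, ytr = _to_arrays(train_images)
    xva, yva = _to_arrays(val_images)
    size = xtr.shape[-1]
    weights = class_weight_vector(ytr)
    net = ResNetClassifier(in_channels=3, width=config.width, seed=config.seed)
    opt = Adam(net, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    model = TrainedModel(
        net, size, (float(weights[1]), float(weights[0])), config
    )
    best_state: list[np.ndarray] | None = None
    for epoch in range(config.epochs):
        order = rng.permutation(len(xtr))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(xtr), config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = net.forward(xtr[idx], train=True)
            loss, dlogits = weighted_cross_entropy(logits, ytr[idx], weights)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at epoch {epoch}, batch {n_batches}"
                )
            net.backward(dlogits)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        recalibrate_batchnorm(net, xtr, batch_size=max(config.batch_size, 128))
        val_loss, val_acc = evaluate(net, xva, yva, weights, config.batch_size)
        model.history.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss / max(n_batches, 1),
                "val_loss": val_loss,
                "val_accuracy": val_acc,
            }
        )
        if val_loss < model.best_val_loss:
            model.best_val_loss = val_loss
            model.best_epoch = epoch
            best_state = net.state()
    if best_state is not None:
        net.load_state(best_state)
    return model


def evaluate(
    net: ResNetClassifier,
    x: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    batch_size: int = 128,
) -> tuple[float, float]:
    losses, hits, total_w = 0.0, 0, 0.0
    n = 0
    for start in range(0, len(x), batch_size):
        xb, yb = x[start : start + batch_size], y[start : start + batch_size]
        logits = net.forward(xb, train=False)
        loss, _ = weighted_cross_entropy(logits, yb, weights)
        losses += loss * len(xb)
        hits += int((logits.argmax(axis=1) == yb).sum())
        n += len(xb)
    return losses / n, hits / n


def predict_proba(model: TrainedModel, images: list[ProfileImage]) -> np.ndarray:
    """P(True) per image; batch-order invariant (eval-mode batch norm)."""
    for im in images:
        if im.tensor.shape[-1] != model.image_size:
            raise ValueError(
                f"image size {im.tensor.shape[-1]} does not match "
                f"training size {model.image_size}"
            )
    x = np.stack([im.tensor for im in images]).astype(np.float32)
    out = []
    for start in range(0, len(x), 256):
        logits = model.network.forward(x[start : start + 256], train=False)
        out.append(softmax(logits)[:, 1])
    return np.concatenate(out)


def predict(model: TrainedModel, image: ProfileImage) -> tuple[float, bool]:
    """(p_true, label) for one image."""
    p = float(predict_proba(model, [image])[0])
    return p, p >= 0.5
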
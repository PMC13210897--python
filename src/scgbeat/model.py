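"""1D U-Net for per-sample heartbeat segmentation, with training loop.

The network maps a 3-channel SCG segment to a per-sample probability
distribution over two classes (heartbeat / non-heartbeat).  Encoder stages
double their filter count and halve the length; the decoder mirrors them
with stride-2 transposed convolutions and skip concatenation; the head is
a per-sample linear map (kernel-size-1 convolution) followed by softmax,
so the trained network accepts any length divisible by ``2**depth``.

Defaults reproduce the reference configuration: depth 5, 16 initial
filters, kernel size 30, 4096-sample inputs, batch 128, Adam from 1e-3
with a reduce-on-plateau schedule (factor 10, patience 2 epochs) down to
1e-6.  Smaller instances of the same family are used for CPU-scale
experiments.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._nn import (
    Adam,
    BatchNorm1d,
    Conv1d,
    ConvTranspose1d,
    MaxPool1d,
    ReLU,
    softmax,
    weighted_cross_entropy,
)
from .datatypes import SampleMask, ScgRecording

__all__ = [
    "UNetConfig",
    "TrainConfig",
    "UNet1D",
    "build_network",
    "train",
    "predict_proba",
]

log = logging.getLogger(__name__)


@dataclass
class UNetConfig:
    depth: int = 5
    init_filters: int = 16
    kernel_size: int = 30
    in_channels: int = 3
    classes: int = 2
    input_len: int = 4096

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError(f"depth must be >= 1; got {self.depth}")
        if self.kernel_size < 1:
            raise ValueError(f"kernel_size must be >= 1; got {self.kernel_size}")
        if self.input_len % (2**self.depth):
            raise ValueError(
                f"input_len ({self.input_len}) must be divisible by "
                f"2**depth ({2**self.depth})"
            )

    @property
    def encoder_filters(self) -> list[int]:
        return [self.init_filters * 2**s for s in range(self.depth)]


@dataclass
class TrainConfig:
    batch_size: int = 128
    lr_init: float = 1e-3
    lr_factor: float = 0.1
    lr_patience_epochs: int = 2
    lr_min: float = 1e-6
    max_epochs: int = 100
    class_weights: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.lr_min <= self.lr_init:
            raise ValueError("require 0 < lr_min <= lr_init")
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be >= 1; got {self.batch_size}")


@dataclass
class SegmentBatch:
    """Stacked training segments: inputs (N, 3, L), targets (N, L) in {0,1}."""

    inputs: np.ndarray
    targets: np.ndarray

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs)
        self.targets = np.asarray(self.targets)
        if self.inputs.ndim != 3 or self.targets.ndim != 2:
            raise ValueError("inputs must be (N, C, L) and targets (N, L)")
        if self.inputs.shape[0] != self.targets.shape[0] or (
            self.inputs.shape[2] != self.targets.shape[1]
        ):
            raise ValueError("inputs and targets must agree in count and length")


class _DoubleConv:
    """(conv -> batch-norm -> ReLU) x 2."""

    def __init__(self, cin, cout, k, rng, dtype):
        self.layers = [
            Conv1d(cin, cout, k, rng, dtype),
            BatchNorm1d(cout, dtype),
            ReLU(),
            Conv1d(cout, cout, k, rng, dtype),
            BatchNorm1d(cout, dtype),
            ReLU(),
        ]

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]


class UNet1D:
    """Encoder–decoder segmentation network (NumPy, CPU)."""

    def __init__(self, config: UNetConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        c = config
        self.enc = []
        self.pools = []
        cin = c.in_channels
        for f in c.encoder_filters:
            self.enc.append(_DoubleConv(cin, f, c.kernel_size, rng, dtype))
            self.pools.append(MaxPool1d())
            cin = f
        bridge_f = c.init_filters * 2**c.depth
        self.bridge = _DoubleConv(cin, bridge_f, c.kernel_size, rng, dtype)
        self.ups = []
        self.dec = []
        cur = bridge_f
        for f in reversed(c.encoder_filters):
            self.ups.append(ConvTranspose1d(cur, f, rng, dtype))
            self.dec.append(_DoubleConv(2 * f, f, c.kernel_size, rng, dtype))
            cur = f
        self.head = Conv1d(cur, c.classes, 1, rng, dtype)

    # -- plumbing ---------------------------------------------------------
    def _modules(self):
        return (
            self.enc + self.pools + [self.bridge] + self.ups + self.dec + [self.head]
        )

    def parameters(self) -> list[dict]:
        return [p for m in self._modules() for p in m.parameters()]

    def n_parameters(self) -> int:
        return sum(p["value"].size for p in self.parameters())

    def _bn_layers(self) -> list[BatchNorm1d]:
        out = []
        for m in self._modules():
            if isinstance(m, BatchNorm1d):
                out.append(m)
            elif isinstance(m, _DoubleConv):
                out += [l for l in m.layers if isinstance(l, BatchNorm1d)]
        return out

    def get_weights(self) -> dict:
        return {
            "params": [p["value"].copy() for p in self.parameters()],
            "bn_stats": [
                (bn.running_mean.copy(), bn.running_var.copy())
                for bn in self._bn_layers()
            ],
        }

    def set_weights(self, weights: dict) -> None:
        for p, w in zip(self.parameters(), weights["params"]):
            p["value"][...] = w
        for bn, (mean, var) in zip(self._bn_layers(), weights["bn_stats"]):
            bn.running_mean[...] = mean
            bn.running_var[...] = var

    # -- forward / backward ----------------------------------------------
    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 2:
            x = x[None]
        if x.shape[2] % (2**self.config.depth):
            raise ValueError(
                f"input length {x.shape[2]} not divisible by 2**depth"
            )
        skips = []
        for enc, pool in zip(self.enc, self.pools):
            x = enc.forward(x, training)
            skips.append(x)
            x = pool.forward(x, training)
        x = self.bridge.forward(x, training)
        self._skip_channels = []
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, training)
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = dec.forward(x, training)
        return self.head.forward(x, training)

    def backward(self, dlogits: np.ndarray) -> None:
        dy = self.head.backward(dlogits)
        dskips = []
        for up, dec, c_skip in zip(
            reversed(self.ups), reversed(self.dec), reversed(self._skip_channels)
        ):
            dy = dec.backward(dy)
            dskip, dy = dy[:, :c_skip], dy[:, c_skip:]
            dskips.append(dskip)
            dy = up.backward(dy)
        dy = self.bridge.backward(dy)
        dskips.reverse()  # now ordered deepest-encoder-first
        for enc, pool, dskip in zip(
            reversed(self.enc), reversed(self.pools), dskips
        ):
            dy = pool.backward(dy)
            dy = enc.backward(dy + dskip)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities (N, classes, L) using running BN statistics."""
        return softmax(self.forward_logits(x, training=False), axis=1)


def build_network(config: UNetConfig, seed: int = 0, dtype=np.float32) -> UNet1D:
    """Construct the segmentation network for a configuration."""
    return UNet1D(config, seed=seed, dtype=dtype)


def _class_weights_from_masks(targets: np.ndarray, n_classes: int) -> np.ndarray:
    """Inverse class frequency, normalised to mean 1."""
    counts = np.bincount(targets.ravel().astype(np.int64), minlength=n_classes)
    counts = np.maximum(counts, 1)
    w = counts.sum() / (n_classes * counts.astype(np.float64))
    return w / w.mean()


def _epoch_loss(net: UNet1D, batch: SegmentBatch, w: np.ndarray,
                batch_size: int) -> float:
    total, total_n = 0.0, 0
    for i in range(0, batch.inputs.shape[0], batch_size):
        xb = batch.inputs[i : i + batch_size]
        yb = batch.targets[i : i + batch_size].astype(np.int64)
        logits = net.forward_logits(xb, training=False)
        loss, _ = weighted_cross_entropy(logits, yb, w.astype(net.dtype))
        total += loss * xb.shape[0]
        total_n += xb.shape[0]
    return total / total_n


def train(
    net: UNet1D,
    train_data: SegmentBatch,
    val_data: SegmentBatch,
    tc: TrainConfig | None = None,
) -> list[dict]:
    """Optimise class-weighted cross entropy with Adam and a plateau schedule.

    The learning rate is divided by ``1/lr_factor`` whenever validation
    loss fails to improve for ``lr_patience_epochs`` consecutive epochs;
    training stops once the rate would fall below ``lr_min`` (or at
    ``max_epochs``).  The best-validation weights are restored before
    returning.  Returns the per-epoch history
    (epoch, train_loss, val_loss, lr).
    """
    tc = tc or TrainConfig()
    if train_data.inputs.shape[0] == 0 or val_data.inputs.shape[0] == 0:
        raise ValueError("training and validation sets must be non-empty")

    if tc.class_weights is None:
        w = _class_weights_from_masks(train_data.targets, net.config.classes)
    else:
        w = np.asarray(tc.class_weights, dtype=np.float64)
    log.info("class weights: %s", np.round(w, 4))

    rng = np.random.default_rng(tc.seed)
    opt = Adam(net.parameters(), lr=tc.lr_init)
    history: list[dict] = []
    best_val = np.inf
    best_weights = net.get_weights()
    stall = 0
    lr = tc.lr_init

    x_train = train_data.inputs.astype(net.dtype)
    y_train = train_data.targets.astype(np.int64)
    wd = w.astype(net.dtype)

    for epoch in range(tc.max_epochs):
        order = rng.permutation(x_train.shape[0])
        run_loss, run_n = 0.0, 0
        for i in range(0, order.size, tc.batch_size):
            idx = order[i : i + tc.batch_size]
            logits = net.forward_logits(x_train[idx], training=True)
            loss, dlogits = weighted_cross_entropy(logits, y_train[idx], wd)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {loss}"
                )
            net.backward(dlogits.astype(net.dtype))
            opt.step()
            run_loss += loss * idx.size
            run_n += idx.size
        val_loss = _epoch_loss(net, val_data, w, tc.batch_size)
        history.append(
            {
                "epoch": epoch,
                "train_loss": run_loss / run_n,
                "val_loss": val_loss,
                "lr": lr,
            }
        )
        log.info(
            "epoch %d: train %.5f val %.5f lr %.2e",
            epoch, run_loss / run_n, val_loss, lr,
        )
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_weights = net.get_weights()
            stall = 0
        else:
            stall += 1
            if stall >= tc.lr_patience_epochs:
                lr *= tc.lr_factor
                stall = 0
                if lr < tc.lr_min:
                    break
                opt.lr = lr
    net.set_weights(best_weights)
    return history


def save_model(net: UNet1D, path: str) -> None:
    """Checkpoint weights (.npz) with a JSON sidecar for the config."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    w = net.get_weights()
    arrays = {f"param_{i}": a for i, a in enumerate(w["params"])}
    for i, (mean, var) in enumerate(w["bn_stats"]):
        arrays[f"bn_mean_{i}"] = mean
        arrays[f"bn_var_{i}"] = var
    np.savez(path, **arrays)
    sidecar = Path(path).with_suffix(".json")
    sidecar.write_text(json.dumps(asdict(net.config), indent=2))


def load_model(path: str) -> UNet1D:
    import json
    from pathlib import Path

    cfg = UNetConfig(**json.loads(Path(path).with_suffix(".json").read_text()))
    net = UNet1D(cfg)
    data = np.load(path if str(path).endswith(".npz") else str(path) + ".npz")
    n_params = len([k for k in data.files if k.startswith("param_")])
    n_bn = len([k for k in data.files if k.startswith("bn_mean_")])
    net.set_weights(
        {
            "params": [data[f"param_{i}"] for i in range(n_params)],
            "bn_stats": [
                (data[f"bn_mean_{i}"], data[f"bn_var_{i}"]) for i in range(n_bn)
            ],
        }
    )
    return net


def predict_proba(net: UNet1D, rec: ScgRecording) -> SampleMask:
    """Heartbeat-class probability for every sample of a recording.

    The recording is tiled into ``input_len`` windows with 50% overlap
    (tail window right-aligned); overlapping predictions are averaged.
    Recordings shorter than one window are reflect-padded, predicted, and
    cropped.
    """
    if rec.n_samples < 2:
        raise ValueError("recording must have at least 2 samples")
    win = net.config.input_len
    x = rec.data.astype(net.dtype)
    n = x.shape[1]
    if n < win:
        pad = win - n
        x = np.pad(x, ((0, 0), (0, pad)), mode="reflect")
        p = net.predict(x[None])[0, 1, :n]
        return SampleMask(np.clip(p, 0, 1), fs=rec.fs, t0=rec.t0)

    offsets = list(range(0, n - win + 1, win // 2))
    if offsets[-1] + win < n:
        offsets.append(n - win)
    acc = np.zeros(n)
    cnt = np.zeros(n)
    for off in offsets:
        p = net.predict(x[None, :, off : off + win])[0, 1]
        acc[off : off + win] += p
        cnt[off : off + win] += 1
    return SampleMask(np.clip(acc / cnt, 0, 1), fs=rec.fs, t0=rec.t0)
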
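"""Training loop: MSE objective, step learning-rate schedule, checkpoints.

The objective is mean squared error between predicted and ground-truth
targets, summed over keypoints and divided by (M * w * h) where M is the
number of keypoints and (w, h) the target resolution.  In cross-tensor mode
the same formula is applied to the width and height vectors separately and
combined by configurable weights (equal by default).

The default schedule follows the published recipe: Adam, batch size 24,
120 epochs, learning rate 0.001 dropped to 0.0001 at epoch 40 and 0.00001
at epoch 80 (1-based epochs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .annotations import AnnotatedImage, DatasetIndex, KeypointSet
from .errors import ConfigurationError, DataError, NumericalError
from .evaluation import OksParams, compute_oks
from .model import CSHTNet, NetworkSpec, build_network
from .nn import Adam
from .nn import autograd as ag
from .nn.autograd import Tensor
from .targets import (CrossHeatTensor, HeatmapSpec, HeatmapStack, decode_heatmap,
                      decode_keypoints, make_cross_tensor_gt,
                      make_isotropic_heatmap)


@dataclass
class TrainConfig:
    """Optimization schedule and target-encoding settings."""

    batch_size: int = 24
    epochs: int = 120
    base_lr: float = 1e-3
    lr_drops: dict[int, float] = field(default_factory=lambda: {40: 1e-4, 80: 1e-5})
    input_size: tuple[int, int] = (384, 288)   # (width, height)
    seed: int = 0
    head_mode: str = "csht"
    heatmap_sigma: float = 3.0
    csht_sigma: float = 1.0
    loss_weights: tuple[float, float] = (0.5, 0.5)  # (width, height) in csht mode
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        boundaries = sorted(self.lr_drops)
        if boundaries != list(self.lr_drops):
            raise ConfigurationError("lr_drops boundaries must be strictly increasing")

    def lr_at_epoch(self, epoch: int) -> float:
        """Learning rate in force during a given 1-based epoch."""
        lr = self.base_lr
        for boundary in sorted(self.lr_drops):
            if epoch >= boundary:
                lr = self.lr_drops[boundary]
        return lr


@dataclass
class TrainState:
    """Progress record returned by :func:`train`."""

    epoch: int
    history: list[dict]
    best_val_oks: float
    best_checkpoint: str | None
    last_checkpoint: str | None
    seed: int


def mse_loss(pred, gt, loss_weights: tuple[float, float] = (0.5, 0.5)) -> Tensor:
    """MSE between predicted and GT targets (heatmap stacks or vector pairs).

    Heatmap mode: sum of pixelwise squared differences over all keypoints
    divided by (M * w * h).  Cross-tensor mode: the same per-axis, combined
    by ``loss_weights``.
    """
    if isinstance(pred, HeatmapStack):
        pred = Tensor(pred.values)
    elif isinstance(pred, CrossHeatTensor):
        pred = (Tensor(pred.width_vectors), Tensor(pred.height_vectors))
    if isinstance(pred, tuple):
        wv_pred, hv_pred = pred
        if not isinstance(gt, CrossHeatTensor):
            raise DataError("cross-tensor prediction requires CrossHeatTensor GT")
        if (wv_pred.shape[-1] != gt.width_vectors.shape[-1]
                or hv_pred.shape[-1] != gt.height_vectors.shape[-1]):
            raise DataError("cross-tensor shape mismatch between pred and gt")
        gw = np.broadcast_to(gt.width_vectors, wv_pred.shape)
        gh = np.broadcast_to(gt.height_vectors, hv_pred.shape)
        m = wv_pred.shape[-2]
        lw = ag.mse(wv_pred, gw, denom=float(m * np.prod(wv_pred.shape[:-2] or [1]) * wv_pred.shape[-1]))
        lh = ag.mse(hv_pred, gh, denom=float(m * np.prod(hv_pred.shape[:-2] or [1]) * hv_pred.shape[-1]))
        a, b = loss_weights
        return ag.add(_scale(lw, a), _scale(lh, b))
    target = gt.values if isinstance(gt, HeatmapStack) else np.asarray(gt)
    target = np.broadcast_to(target, pred.shape)
    if pred.shape != target.shape:
        raise DataError(f"shape mismatch: pred {pred.shape}, gt {target.shape}")
    m, h, w = pred.shape[-3], pred.shape[-2], pred.shape[-1]
    n = int(np.prod(pred.shape[:-3])) if pred.data.ndim > 3 else 1
    return ag.mse(pred, target, denom=float(n * m * h * w))


def _scale(t: Tensor, a: float) -> Tensor:
    out = Tensor(t.data * a, parents=(t,))

    def backward(g):
        if t.requires_grad:
            t._accumulate(g * a)

    out._backward = backward
    return out


def image_to_input(img: AnnotatedImage, in_channels: int) -> np.ndarray:
    """Convert a raster to the (C, H, W) float32 array the network consumes."""
    px = np.asarray(img.pixels)
    if np.issubdtype(px.dtype, np.integer):
        px = px.astype(np.float32) / 255.0
    else:
        px = px.astype(np.float32)
    if px.ndim == 3:
        gray = px.mean(axis=2)
    else:
        gray = px
    if in_channels == 1:
        return gray[None]
    return np.repeat(gray[None], in_channels, axis=0)


def _encode_gt(images: list[AnnotatedImage], model: CSHTNet, cfg: TrainConfig):
    stride = model.output_stride
    w_hm = images[0].width // stride
    h_hm = images[0].height // stride
    if cfg.head_mode == "heatmap":
        spec = HeatmapSpec(cfg.heatmap_sigma, cfg.heatmap_sigma, stride)
        stacks = [make_isotropic_heatmap(im.keypoints, spec, (w_hm, h_hm)).values
                  for im in images]
        return np.stack(stacks).astype(np.float32)
    cts = [make_cross_tensor_gt(im.keypoints, (w_hm, h_hm), cfg.csht_sigma, stride)
           for im in images]
    wv = np.stack([ct.width_vectors for ct in cts]).astype(np.float32)
    hv = np.stack([ct.height_vectors for ct in cts]).astype(np.float32)
    return wv, hv


def _batch_loss(model: CSHTNet, x: np.ndarray, gt, cfg: TrainConfig) -> Tensor:
    pred = model(Tensor(x))
    if cfg.head_mode == "csht":
        wv, hv = gt
        gt_obj = CrossHeatTensor(wv, hv, model.output_stride)
        return mse_loss(pred, gt_obj, cfg.loss_weights)
    return mse_loss(pred, HeatmapStack(gt, model.output_stride))


def save_checkpoint(model: CSHTNet, path: str | Path, cfg: TrainConfig | None = None,
                    epoch: int = 0) -> Path:
    """Serialize spec + weights (+ config metadata) to an .npz checkpoint."""
    path = Path(path)
    meta = {
        "spec": asdict(model.spec),
        "epoch": epoch,
        "config": asdict(cfg) if cfg is not None else None,
    }
    arrays = {k.replace("/", "_"): v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)
    return path


def load_checkpoint(path: str | Path) -> CSHTNet:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        spec_dict = meta["spec"]
        spec_dict["widths"] = tuple(spec_dict["widths"])
        spec_dict["coconv_branch_kernels"] = tuple(spec_dict["coconv_branch_kernels"])
        spec = NetworkSpec(**spec_dict)
        model = build_network(spec)
        state = {k: data[k] for k in data.files if k != "__meta__"}
    model.load_state_dict(state)
    return model


def predict(model: CSHTNet, images: list[AnnotatedImage],
            refine: bool = True, batch_size: int = 16) -> list[KeypointSet]:
    """Forward pass + decoding to input-resolution keypoint coordinates."""
    model.eval()
    out: list[KeypointSet] = []
    for start in range(0, len(images), batch_size):
        chunk = images[start:start + batch_size]
        x = np.stack([image_to_input(im, model.spec.in_channels) for im in chunk])
        pred = model(Tensor(x))
        if model.head_mode == "csht":
            wv, hv = pred
            for i in range(len(chunk)):
                ct = CrossHeatTensor(wv.data[i], hv.data[i], model.output_stride)
                out.append(decode_keypoints(ct, refine=refine))
        else:
            for i in range(len(chunk)):
                stack = HeatmapStack(pred.data[i], model.output_stride)
                out.append(decode_heatmap(stack, refine=refine))
    return out


def _mean_val_oks(model: CSHTNet, images: list[AnnotatedImage]) -> float:
    preds = predict(model, images)
    params = OksParams()
    vals = [compute_oks(p, im.keypoints, params) for p, im in zip(preds, images)]
    return float(np.mean(vals)) if vals else float("nan")


def train(model: CSHTNet, images: list[AnnotatedImage], index: DatasetIndex,
          cfg: TrainConfig) -> TrainState:
    """Run the optimization schedule; returns the progress record.

    Logs per-epoch train loss, validation loss and validation mean OKS, and
    (when ``cfg.out_dir`` is set) writes best-by-validation-OKS and last
    checkpoints plus a JSONL log.  Fully seeded: a fixed seed and
    single-threaded execution reproduce the loss trajectory.
    """
    by_id = {im.image_id: im for im in images}
    train_imgs = [by_id[i] for i in index.ids("train") if i in by_id]
    val_imgs = [by_id[i] for i in index.ids("val") if i in by_id]
    if not train_imgs:
        raise DataError("empty training split")
    if model.head_mode != cfg.head_mode:
        raise ConfigurationError(
            f"model head ({model.head_mode}) does not match config ({cfg.head_mode})")

    rng = np.random.default_rng(cfg.seed)
    x_train = np.stack([image_to_input(im, model.spec.in_channels) for im in train_imgs])
    gt_train = _encode_gt(train_imgs, model, cfg)
    x_val = gt_val = None
    if val_imgs:
        x_val = np.stack([image_to_input(im, model.spec.in_channels) for im in val_imgs])
        gt_val = _encode_gt(val_imgs, model, cfg)

    optimizer = Adam(model.parameters(), lr=cfg.base_lr)
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    history: list[dict] = []
    best_oks = -np.inf
    best_path = last_path = None
    n = len(train_imgs)
    for epoch in range(1, cfg.epochs + 1):
        optimizer.lr = cfg.lr_at_epoch(epoch)
        model.train()
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            xb = x_train[sel]
            gb = (gt_train[0][sel], gt_train[1][sel]) if cfg.head_mode == "csht" \
                else gt_train[sel]
            optimizer.zero_grad()
            loss = _batch_loss(model, xb, gb, cfg)
            value = float(loss.data)
            if not np.isfinite(value):
                raise NumericalError(
                    f"non-finite loss {value} at epoch {epoch}; aborting")
            loss.backward()
            optimizer.step()
            epoch_loss += value
            n_batches += 1
        record = {"epoch": epoch, "lr": optimizer.lr,
                  "train_loss": epoch_loss / max(n_batches, 1)}
        if val_imgs:
            model.eval()
            val_loss = float(_batch_loss(model, x_val,
                                         gt_val if cfg.head_mode == "heatmap"
                                         else (gt_val[0], gt_val[1]), cfg).data)
            val_oks = _mean_val_oks(model, val_imgs)
            record.update(val_loss=val_loss, val_oks=val_oks)
            if val_oks > best_oks:
                best_oks = val_oks
                if out_dir:
                    best_path = str(save_checkpoint(model, out_dir / "best.npz", cfg, epoch))
        history.append(record)
        if out_dir:
            with open(out_dir / "log.jsonl", "a") as fh:
                fh.write(json.dumps(record) + "\n")
    if out_dir:
        last_path = str(save_checkpoint(model, out_dir / "last.npz", cfg, cfg.epochs))
    model.eval()
    return TrainState(cfg.epochs, history, float(best_oks), best_path, last_path,
                      cfg.seed)
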
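"""Training loop: AdamW, per-epoch exponential LR decay, validation metrics.

The optimizer is decoupled-weight-decay Adam (weight decay 5×10⁻³) with the
learning rate following ``lr(epoch) = lr0 · gamma^epoch`` (lr0 = 1.25×10⁻³,
gamma = 0.95, stepped per epoch).  Each epoch logs the per-term loss
breakdown on the training set and precision/recall/F1 plus the conductance
MSE on the validation set; the checkpoint with the best validation F1 is
retained.  Everything is seeded: weight initialization, data order and the
synthetic data itself (through the dataset manifest).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass, field

import imageio.v3 as iio
import numpy as np

from .annotations import AnnotationSet, read_annotations
from .evaluation import (EvalCounts, match_detections, precision_recall_f1,
                         regression_metrics)
from .measure import ConductanceParams, decode_detections, gsmax, measure_image
from .network import HeadOutputs, NetConfig, RotatedStomataNet
from .nn import Tensor, gather_centers, no_grad
from .targets import (HeadTargets, LossWeights, angle_loss, conductance_loss,
                      encode_targets, heatmap_loss, offset_loss, size_loss,
                      total_loss)

_METRIC_COLUMNS = ("epoch", "lr", "train_total", "val_total", "LH", "Loff",
                   "Lsize", "Lang", "Lcon", "val_precision", "val_recall",
                   "val_f1", "val_gsmax_mse")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyper-parameters; defaults follow the published recipe
    (AdamW, lr0 = 1.25e-3, gamma = 0.95, 20 epochs, weight decay 5e-3)."""

    lr0: float = 1.25e-3
    gamma: float = 0.95
    epochs: int = 20
    weight_decay: float = 5e-3
    batch_size: int = 4
    seed: int = 0
    loss_weights: LossWeights = field(default_factory=LossWeights)
    net: NetConfig = field(default_factory=NetConfig)
    score_threshold: float = 0.3
    top_k: int = 100
    iou_threshold: float = 0.5
    grad_clip: float = 10.0
    angle_wrap: bool = False
    eval_every: int = 1  # validate every k-th epoch (the last always runs)

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must lie in (0, 1]")
        if self.epochs < 1 or self.lr0 <= 0:
            raise ValueError("need epochs >= 1 and lr0 > 0")


def lr_schedule(lr0: float, gamma: float, epoch: int) -> float:
    """Exponential decay ``lr0 · gamma^epoch`` (epoch 0 gives lr0)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return lr0 * gamma ** epoch


class AdamW:
    """Adam with decoupled weight decay; state per parameter tensor."""

    def __init__(self, params: list[Tensor], lr: float,
                 weight_decay: float = 0.0,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        # decay only matrix/kernel weights, not norm scales or biases
        self._decay_mask = [1.0 if p.data.ndim > 1 else 0.0
                            for p in self.params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v, decay in zip(self.params, self._m, self._v,
                                  self._decay_mask):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data -= self.lr * (update
                                 + decay * self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def clip_gradients(params: list[Tensor], max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float(np.sum(p.grad.astype(np.float64) ** 2))
    norm = math.sqrt(total)
    if norm > max_norm > 0:
        scale = max_norm / (norm + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm


# -- data -------------------------------------------------------------------


@dataclass
class DatasetItem:
    image: np.ndarray
    annotations: AnnotationSet
    targets: HeadTargets


def load_dataset(data_dir: str | os.PathLike, stride: int = 4,
                 gsmax_params: ConductanceParams = ConductanceParams(),
                 ) -> tuple[list[DatasetItem], list[DatasetItem]]:
    """Read a generated dataset directory into (train, val) item lists."""
    data_dir = os.fspath(data_dir)
    manifest_path = os.path.join(data_dir, "manifest.json")
    if not os.path.exists(manifest_path):
        raise FileNotFoundError(f"no manifest.json under {data_dir!r}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    train, val = [], []
    for entry in manifest["images"]:
        image = iio.imread(os.path.join(data_dir, entry["image"]))
        ann = read_annotations(os.path.join(data_dir, entry["annotations"]))
        item = DatasetItem(image, ann, encode_targets(ann, stride, gsmax_params))
        (train if entry["split"] == "train" else val).append(item)
    return train, val


# -- loss assembly ----------------------------------------------------------


def batch_losses(heads: HeadOutputs, items: list[DatasetItem],
                 weights: LossWeights, angle_wrap: bool = False,
                 gsmax_params: ConductanceParams = ConductanceParams(),
                 ) -> tuple[Tensor, dict[str, float]]:
    """Assemble the five losses for a forward pass over ``items``."""
    hg, wg = heads.heatmap.data.shape[2:]
    q = np.zeros((len(items), 1, hg, wg), dtype=np.float32)
    for i, item in enumerate(items):
        th, tw = item.targets.heatmap_q.shape[1:]
        q[i, :, :th, :tw] = item.targets.heatmap_q
    n_idx, y_idx, x_idx = [], [], []
    true_size, true_off, true_ang, true_um, dens = [], [], [], [], []
    for i, item in enumerate(items):
        t = item.targets
        ps = item.annotations.pixel_scale
        for j, (cx, cy) in enumerate(t.centers):
            n_idx.append(i)
            x_idx.append(cx)
            y_idx.append(cy)
            true_size.append(t.size[j])
            true_off.append(t.offset[j])
            true_ang.append(t.angle[j])
            true_um.append(t.size[j] * heads.stride * ps)
            dens.append(t.density_per_mm2)
    k = len(n_idx)
    components = {"heatmap": heatmap_loss(heads.heatmap, q, weights.alpha,
                                          weights.beta)}
    if k:
        n_idx = np.asarray(n_idx)
        y_idx = np.asarray(y_idx)
        x_idx = np.asarray(x_idx)
        pred_size = gather_centers(heads.size, n_idx, y_idx, x_idx)
        pred_off = gather_centers(heads.offset, n_idx, y_idx, x_idx)
        pred_ang = gather_centers(heads.angle, n_idx, y_idx, x_idx).reshape(k)
        ps = items[0].annotations.pixel_scale
        components["offset"] = offset_loss(pred_off, np.asarray(true_off))
        components["size"] = size_loss(pred_size, np.asarray(true_size))
        components["angle"] = angle_loss(pred_ang, np.asarray(true_ang),
                                         wrap=angle_wrap)
        components["conductance"] = conductance_loss(
            pred_size, np.asarray(true_um), np.asarray(dens), ps,
            heads.stride, gsmax_params)
    else:
        zero = Tensor(np.float32(0.0))
        components.update(offset=zero, size=zero, angle=zero,
                          conductance=zero)
    return total_loss(components, weights)


# -- validation -------------------------------------------------------------


def _slice_heads(heads: HeadOutputs, i: int) -> HeadOutputs:
    return HeadOutputs(
        Tensor(heads.heatmap.data[i:i + 1]), Tensor(heads.size.data[i:i + 1]),
        Tensor(heads.offset.data[i:i + 1]), Tensor(heads.angle.data[i:i + 1]),
        heads.stride, heads.input_hw)


def evaluate_model(model: RotatedStomataNet, items: list[DatasetItem],
                   config: TrainConfig,
                   gsmax_params: ConductanceParams = ConductanceParams(),
                   ) -> dict[str, float]:
    """Validation pass: P/R/F1 at the configured IoU plus conductance MSE.

    The conductance comparison runs the full measurement path on the
    decoded detections of each image (predicted count → predicted density)
    against the same measurement on the ground-truth boxes.
    """
    model.eval()
    counts = EvalCounts(0, 0, 0)
    g_pred, g_true = [], []
    loss_sum = 0.0
    with no_grad():
        for start in range(0, len(items), config.batch_size):
            chunk = items[start:start + config.batch_size]
            images = np.stack([c.image for c in chunk])
            heads = model(images)
            loss, _ = batch_losses(heads, chunk, config.loss_weights,
                                   config.angle_wrap, gsmax_params)
            loss_sum += float(loss.data) * len(chunk)
            for i, item in enumerate(chunk):
                dets = decode_detections(_slice_heads(heads, i),
                                         top_k=config.top_k,
                                         score_threshold=config.score_threshold)
                counts = counts + match_detections(
                    dets, item.annotations.boxes, config.iou_threshold)
                ann = item.annotations
                rec = measure_image(dets, ann.image_width_px,
                                    ann.image_height_px, ann.pixel_scale,
                                    gsmax_params)
                g_pred.append(rec.gsmax_mol_m2_s)
                lengths = [b.length * ann.pixel_scale for b in ann.boxes]
                widths = [b.width * ann.pixel_scale for b in ann.boxes]
                g_true.append(gsmax(float(np.mean(lengths)),
                                    float(np.mean(widths)),
                                    item.targets.density_per_mm2,
                                    gsmax_params) if ann.boxes else 0.0)
    p, r, f1 = precision_recall_f1(counts)
    if len(g_true) >= 2 and np.ptp(g_true) > 0:
        mse, _ = regression_metrics(g_pred, g_true)
    else:
        mse = float(np.mean((np.asarray(g_pred) - np.asarray(g_true)) ** 2)) \
            if g_true else float("nan")
    model.train()
    return {"val_precision": p, "val_recall": r, "val_f1": f1,
            "val_gsmax_mse": mse, "val_total": loss_sum / max(1, len(items)),
            "tp": counts.tp, "fp": counts.fp, "fn": counts.fn}


# -- checkpointing ----------------------------------------------------------


def save_checkpoint(model: RotatedStomataNet, path: str | os.PathLike) -> None:
    meta = json.dumps(asdict(model.config))
    state = {"__config__": np.frombuffer(meta.encode(), dtype=np.uint8)}
    state.update(model.state_dict())
    np.savez(path, **state)


def load_checkpoint(path: str | os.PathLike) -> RotatedStomataNet:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__config__"]).decode())
        state = {k: archive[k] for k in archive.files if k != "__config__"}
    for key in ("stage_depths", "stage_channels", "stem_channels"):
        if meta.get(key) is not None:
            meta[key] = tuple(meta[key])
    model = RotatedStomataNet(NetConfig(**meta), seed=0)
    model.load_state_dict(state)
    return model


# -- the loop ---------------------------------------------------------------


@dataclass
class TrainResult:
    model: RotatedStomataNet
    history: list[dict]
    best_f1: float
    best_epoch: int
    checkpoint_path: str | None


def train(data_dir: str | os.PathLike, config: TrainConfig = TrainConfig(),
          out_dir: str | os.PathLike | None = None,
          gsmax_params: ConductanceParams = ConductanceParams(),
          log=None) -> TrainResult:
    """Train on a generated dataset directory; return the best-F1 model.

    Writes ``metrics.csv`` (one row per epoch) and ``best.npz`` under
    ``out_dir`` when given.  A non-finite loss aborts with a diagnostic
    identifying the offending epoch/batch.
    """
    net_cfg = config.net.resolved()
    train_items, val_items = load_dataset(data_dir, net_cfg.output_stride,
                                          gsmax_params)
    if not train_items:
        raise ValueError(f"no training images under {data_dir!r}")
    shapes = {item.image.shape for item in train_items + val_items}
    if len(shapes) != 1:
        raise ValueError(f"images must share one size, got {sorted(shapes)}")

    model = RotatedStomataNet(net_cfg, seed=config.seed)
    optimizer = AdamW(model.parameters(), config.lr0, config.weight_decay)
    shuffle_rng = np.random.default_rng(config.seed + 1)

    best_f1, best_epoch, best_state = -1.0, -1, None
    history: list[dict] = []
    for epoch in range(config.epochs):
        optimizer.lr = lr_schedule(config.lr0, config.gamma, epoch)
        order = shuffle_rng.permutation(len(train_items))
        epoch_loss, epoch_break = 0.0, {}
        n_batches = 0
        for start in range(0, len(order), config.batch_size):
            batch = [train_items[i] for i in order[start:start + config.batch_size]]
            images = np.stack([b.image for b in batch])
            heads = model(images)
            loss, breakdown = batch_losses(heads, batch, config.loss_weights,
                                           config.angle_wrap, gsmax_params)
            if not math.isfinite(breakdown["total"]):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}: "
                    f"{breakdown}")
            optimizer.zero_grad()
            loss.backward()
            clip_gradients(optimizer.params, config.grad_clip)
            optimizer.step()
            epoch_loss += breakdown["total"]
            for key, value in breakdown.items():
                epoch_break[key] = epoch_break.get(key, 0.0) + value
            n_batches += 1

        run_eval = val_items and (
            (epoch + 1) % max(1, config.eval_every) == 0
            or epoch == config.epochs - 1)
        metrics = evaluate_model(model, val_items, config, gsmax_params) \
            if run_eval else {"val_precision": float("nan"),
                              "val_recall": float("nan"),
                              "val_f1": float("nan"),
                              "val_gsmax_mse": float("nan"),
                              "val_total": float("nan")}
        row = {
            "epoch": epoch, "lr": optimizer.lr,
            "train_total": epoch_loss / max(1, n_batches),
            "val_total": metrics["val_total"],
            "LH": epoch_break.get("heatmap", 0.0) / max(1, n_batches),
            "Loff": epoch_break.get("offset", 0.0) / max(1, n_batches),
            "Lsize": epoch_break.get("size", 0.0) / max(1, n_batches),
            "Lang": epoch_break.get("angle", 0.0) / max(1, n_batches),
            "Lcon": epoch_break.get("conductance", 0.0) / max(1, n_batches),
            "val_precision": metrics["val_precision"],
            "val_recall": metrics["val_recall"],
            "val_f1": metrics["val_f1"],
            "val_gsmax_mse": metrics["val_gsmax_mse"],
        }
        history.append(row)
        if log is not None:
            log(f"epoch {epoch}: total={row['train_total']:.4f} "
                f"val_f1={row['val_f1']:.3f}")
        if row["val_f1"] >= best_f1:
            best_f1, best_epoch = row["val_f1"], epoch
            best_state = {k: v.copy() for k, v in model.state_dict().items()}

    if best_state is not None:
        model.load_state_dict(best_state)
    checkpoint_path = None
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        checkpoint_path = os.path.join(os.fspath(out_dir), "best.npz")
        save_checkpoint(model, checkpoint_path)
        with open(os.path.join(os.fspath(out_dir), "metrics.csv"), "w") as fh:
            fh.write(",".join(_METRIC_COLUMNS) + "\n")
            for row in history:
                fh.write(",".join(str(row[c]) for c in _METRIC_COLUMNS) + "\n")
    return TrainResult(model, history, best_f1, best_epoch, checkpoint_path)
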
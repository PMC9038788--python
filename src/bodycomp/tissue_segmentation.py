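"""Four-class 2D tissue segmentation with a competitive dense network.

The segmenter is a small encoder-decoder in which dense-block and skip
junctions merge feature maps by element-wise maximum ("maxout" / competitive
feature selection) instead of concatenation; setting ``use_maxout=False``
switches every junction to concatenation (with 1x1 transitions restoring the
channel width) for a controlled ablation with identical output shape.

Classes: 0 background, 1 skeletal muscle (SM), 2 visceral adipose tissue
(VAT), 3 subcutaneous adipose tissue (SAT). Intermuscular fat belongs to SM
in the ground-truth convention.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .imaging import (BACKGROUND, SAT, SM, VAT, CTSlice, CompartmentMask,
                      ProbabilityMap)
from . import nets

__all__ = [
    "CDFNetConfig",
    "SegmentationResult",
    "SegmenterEnsemble",
    "maxout_merge",
    "train_segmenter",
    "segment_slice",
    "dice",
]


def maxout_merge(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Competitive merge: element-wise maximum of two equal-shape feature grids."""
    return nets.maxout(np.asarray(a), np.asarray(b))


@dataclass
class CDFNetConfig:
    """Configuration of the competitive dense segmentation network."""

    input_size: tuple[int, int] = (96, 96)
    n_classes: int = 4
    levels: int = 3                     # resolution levels (levels - 1 poolings)
    block_layers: int = 2
    growth: int = 8                     # channel width at the top level
    use_maxout: bool = True             # False -> concatenation ablation
    epochs: int = 34
    lr: float = 3e-3
    lr_decay: float = 0.3
    batch_size: int = 8
    augment: dict = field(default_factory=lambda: {"flip_x": True, "noise_hu": 15.0})
    clip_hu: tuple[float, float] = (-250.0, 250.0)  # soft-tissue window
    folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_classes != 4:
            raise ValueError("the tissue task has exactly 4 classes")

    def widths(self):
        return [self.growth * 2 ** i for i in range(self.levels)]


@dataclass
class SegmentationResult:
    """Mask, per-class probabilities and pixel counts for one slice."""

    mask: CompartmentMask
    prob: ProbabilityMap
    pixel_counts: dict

    @classmethod
    def from_probs(cls, probs: np.ndarray, spacing) -> "SegmentationResult":
        labels = np.argmax(probs, axis=0).astype(np.int16)  # ties -> lowest code
        counts = {c: int((labels == c).sum()) for c in (BACKGROUND, SM, VAT, SAT)}
        return cls(mask=CompartmentMask(labels=labels, spacing=spacing),
                   prob=ProbabilityMap(probs=probs), pixel_counts=counts)


def _prep_slice(pixels: np.ndarray, clip):
    v = np.clip(pixels, clip[0], clip[1]).astype(np.float32)
    sd = float(v.std())
    if sd < 1e-3:
        sd = 1.0
    return (v - float(v.mean())) / sd, sd


def _new_net(config: CDFNetConfig, rng):
    merge = "maxout" if config.use_maxout else "concat"
    return nets.SegNet(nd=2, in_ch=1, n_classes=config.n_classes,
                       widths=config.widths(), rng=rng,
                       block_style="dense", merge=merge,
                       block_layers=config.block_layers)


@dataclass
class SegmenterEnsemble:
    """Cross-validated fold models plus per-case validation predictions."""

    models: list
    config: CDFNetConfig
    fold_of_case: list[int] = field(default_factory=list)
    val_records: list[dict] = field(default_factory=list)

    def save(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        meta = {"config": asdict(self.config), "n_models": len(self.models),
                "fold_of_case": self.fold_of_case,
                "val_records": [
                    {k: v for k, v in r.items() if k != "prob"}
                    for r in self.val_records
                ]}
        with open(os.path.join(outdir, "segmenter.json"), "w") as f:
            json.dump(meta, f, indent=1)
        for i, net in enumerate(self.models):
            arrays = {}
            for j, c in enumerate(net.convs()):
                arrays[f"W{j}"] = c.W
                arrays[f"b{j}"] = c.b
            np.savez(os.path.join(outdir, f"segmenter_fold{i}.npz"), **arrays)

    @classmethod
    def load(cls, outdir: str) -> "SegmenterEnsemble":
        with open(os.path.join(outdir, "segmenter.json")) as f:
            meta = json.load(f)
        cfg = meta["config"]
        for k in ("input_size", "clip_hu"):
            cfg[k] = tuple(cfg[k])
        config = CDFNetConfig(**cfg)
        models = []
        for i in range(meta["n_models"]):
            net = _new_net(config, np.random.default_rng(0))
            data = np.load(os.path.join(outdir, f"segmenter_fold{i}.npz"))
            for j, c in enumerate(net.convs()):
                c.W = data[f"W{j}"].astype(np.float32)
                c.b = data[f"b{j}"].astype(np.float32)
            models.append(net)
        return cls(models=models, config=config,
                   fold_of_case=meta["fold_of_case"], val_records=meta["val_records"])


def train_segmenter(samples, config: CDFNetConfig) -> SegmenterEnsemble:
    """Train one fold model per cross-validation split.

    Parameters
    ----------
    samples : list of (CTSlice, CompartmentMask)
    config : CDFNetConfig

    Returns
    -------
    SegmenterEnsemble
        Fold models plus validation records: for every case, the softmax
        probability map and per-class Dice under its held-out fold model —
        the raw material for the entropy-based quality-control regressor.
    """
    from sklearn.model_selection import KFold

    if len(samples) < config.folds:
        raise ValueError(f"need at least {config.folds} cases for {config.folds}-fold CV")
    for _sl, mask in samples:
        if not isinstance(mask, CompartmentMask):
            raise TypeError("each sample needs a CompartmentMask")

    prepped = []
    for sl, mask in samples:
        x, hu_sd = _prep_slice(sl.pixels, config.clip_hu)
        prepped.append({"x": x, "y": mask.labels.astype(np.int64), "hu_sd": hu_sd,
                        "spacing": mask.spacing})

    kf = KFold(n_splits=config.folds, shuffle=True, random_state=config.seed)
    fold_of_case = [-1] * len(samples)
    models, val_records = [], []
    for fold, (train_idx, val_idx) in enumerate(kf.split(np.arange(len(samples)))):
        rng = np.random.default_rng(config.seed * 1000 + 500 + fold)
        net = _new_net(config, rng)
        opt = nets.Adam(net, lr=config.lr)
        decay_at = max(1, int(config.epochs * 2 / 3))
        for epoch in range(config.epochs):
            if epoch == decay_at:
                opt.lr *= config.lr_decay
            order = rng.permutation(train_idx)
            for b0 in range(0, len(order), config.batch_size):
                xs, ys = [], []
                for i in order[b0:b0 + config.batch_size]:
                    p = prepped[i]
                    x, y = p["x"], p["y"]
                    if config.augment.get("flip_x") and rng.random() < 0.5:
                        x, y = x[:, ::-1].copy(), y[:, ::-1].copy()
                    noise = config.augment.get("noise_hu", 0.0)
                    if noise > 0:
                        x = x + rng.normal(0, noise / p["hu_sd"],
                                           size=x.shape).astype(np.float32)
                    xs.append(x)
                    ys.append(y)
                xb = np.stack(xs)[:, None]
                yb = np.stack(ys)
                logits = net.forward(xb, train=True)
                _loss, g = nets.ce_dice_loss(logits, yb, dice_classes=[SM, VAT, SAT])
                net.zero_grad()
                net.backward(g)
                opt.step()
        models.append(net)
        for i in val_idx:
            fold_of_case[i] = fold
            p = prepped[i]
            probs = net.predict_probs(p["x"][None, None])[0]
            probs = probs / probs.sum(axis=0, keepdims=True)
            pred = np.argmax(probs, axis=0).astype(np.int16)
            rec = {"case": int(i), "fold": fold,
                   "prob": probs.astype(np.float32)}
            for c, name in ((SM, "sm"), (VAT, "vat"), (SAT, "sat")):
                rec[f"dice_{name}"] = dice(
                    CompartmentMask(pred, p["spacing"]),
                    CompartmentMask(p["y"].astype(np.int16), p["spacing"]), c)
            val_records.append(rec)
    return SegmenterEnsemble(models=models, config=config,
                             fold_of_case=fold_of_case, val_records=val_records)


def segment_slice(ensemble: SegmenterEnsemble, sl: CTSlice) -> SegmentationResult:
    """Segment one slice with the cross-validated ensemble.

    The per-pixel class probability is the mean of the fold softmax outputs;
    the mask is its argmax with ties broken toward the lower class code.
    """
    x, _ = _prep_slice(sl.pixels, ensemble.config.clip_hu)
    acc = None
    for net in ensemble.models:
        probs = net.predict_probs(x[None, None])[0]
        acc = probs if acc is None else acc + probs
    mean = acc / len(ensemble.models)
    mean = mean / mean.sum(axis=0, keepdims=True)
    return SegmentationResult.from_probs(mean.astype(np.float32), sl.spacing)


def dice(a: CompartmentMask, b: CompartmentMask, class_code: int) -> float:
    """Dice overlap ``2|A∩B| / (|A| + |B|)`` for one class; 1.0 if both empty."""
    if class_code not in (BACKGROUND, SM, VAT, SAT):
        raise ValueError(f"unknown class code {class_code}")
    if a.labels.shape != b.labels.shape:
        raise ValueError("masks must have the same shape")
    am = a.labels == class_code
    bm = b.labels == class_code
    denom = int(am.sum()) + int(bm.sum())
    if denom == 0:
        return 1.0
    return float(2.0 * (am & bm).sum() / denom)
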
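"""L3/L4 localization as 3D segmentation of a Gaussian-derived disk blob.

The single annotated disk-center coordinate is turned into a spherical
training target: an isotropic Gaussian is placed at the center in physical
(mm) space and binarized at a fraction of its peak, giving a ball-shaped
foreground. A small 3D encoder-decoder is trained per cross-validation fold
with foreground-biased patch sampling; inference averages the fold softmax
outputs under sliding windows with Gaussian-weighted fusion, thresholds the
mean foreground probability at 0.5, and reduces the blob to a single slice by
rounding its foreground centroid (ties toward the inferior slice).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .imaging import BinaryVolume, CTVolume, DiskAnnotation, ProbabilityMap
from . import nets

__all__ = [
    "NoDetection",
    "LabelMapSpec",
    "ExtractorConfig",
    "SliceExtractionResult",
    "ExtractorEnsemble",
    "make_disk_label_map",
    "train_extractor",
    "predict_disk",
    "largest_component",
    "blob_to_z",
    "delta_z",
    "DeltaZResult",
]


class NoDetection(Exception):
    """Raised when a predicted blob is empty (no L3/L4 level found)."""


@dataclass(frozen=True)
class LabelMapSpec:
    """Gaussian-blob label construction parameters.

    ``sigma_mm`` is the isotropic standard deviation of the Gaussian placed at
    the annotated disk center; voxels where the (peak-normalized) Gaussian is
    at least ``binarize_threshold`` become foreground. With the defaults the
    foreground is a ball of radius sqrt(2 sigma^2 ln 2) ~ 9.4 mm.
    """

    sigma_mm: float = 8.0
    binarize_threshold: float = 0.5

    def __post_init__(self):
        if self.sigma_mm <= 0:
            raise ValueError("sigma_mm must be > 0")
        if not (0 < self.binarize_threshold < 1):
            raise ValueError("binarize_threshold must be in (0, 1)")

    @property
    def radius_mm(self) -> float:
        return float(np.sqrt(-2.0 * self.sigma_mm ** 2 * np.log(self.binarize_threshold)))


@dataclass
class ExtractorConfig:
    """Training configuration of the 3D disk-blob extractor.

    The network is an explicit, fixed-architecture substitute for an
    auto-configured framework: fixed resampling to ``target_spacing``,
    patch-based training with foreground-biased sampling, and sliding-window
    inference with overlap 0.5 and Gaussian-weighted fusion. In-plane
    resolution is coarsened aggressively while native z resolution is kept,
    since the task only needs z precision.
    """

    target_spacing: tuple[float, float, float] = (3.0, 6.0, 6.0)
    patch_size: tuple[int, int, int] = (32, 16, 16)
    base_channels: int = 4
    depth: int = 3                      # resolution levels (depth - 1 poolings)
    epochs: int = 28
    lr: float = 8e-3
    lr_decay: float = 0.3               # multiplicative, at 2/3 of the epochs
    batch_size: int = 8
    patches_per_volume: int = 2
    fg_bias: float = 0.6                # fraction of patches forced to contain the blob
    fg_ce_weight: float = 50.0          # CE weight of the (tiny) foreground class
    fg_ce_weight_late: float = 1.0      # after the lr decay point (precision phase)
    augment: dict = field(default_factory=lambda: {"flip_x": True, "noise_hu": 20.0})
    clip_hu: tuple[float, float] = (-1024.0, 1024.0)
    folds: int = 5
    seed: int = 0

    def widths(self):
        return [self.base_channels * 2 ** i for i in range(self.depth)]


@dataclass
class SliceExtractionResult:
    """Output of :func:`predict_disk` for one volume."""

    z_index: int | None
    z_mm: float | None
    blob: BinaryVolume
    blob_volume_ml: float
    prob: ProbabilityMap
    fold_volumes_ml: list[float] = field(default_factory=list)

    @property
    def detected(self) -> bool:
        return self.z_index is not None


@dataclass
class DeltaZResult:
    delta_mm: float | None
    hit_0mm: bool
    hit_5mm: bool
    hit_10mm: bool
    detected: bool


# ---------------------------------------------------------------------------
# label construction
# ---------------------------------------------------------------------------

def _grid_mm(shape, spacing):
    return [np.arange(n) * s for n, s in zip(shape, spacing)]


def make_disk_label_map(annotation: DiskAnnotation, volume: CTVolume,
                        spec: LabelMapSpec) -> BinaryVolume:
    """Binarized Gaussian blob around the annotated disk center.

    A voxel is foreground iff ``exp(-d^2 / (2 sigma^2)) >= threshold`` with
    ``d`` the physical distance (mm) to the center.
    """
    if annotation.frame_shape != volume.shape:
        raise ValueError("annotation frame does not match the volume")
    cz, cy, cx = annotation.center
    dz, dy, dx = volume.spacing
    zz, yy, xx = _grid_mm(volume.shape, volume.spacing)
    d2 = ((zz - cz * dz) ** 2)[:, None, None] \
        + ((yy - cy * dy) ** 2)[None, :, None] \
        + ((xx - cx * dx) ** 2)[None, None, :]
    r2 = -2.0 * spec.sigma_mm ** 2 * np.log(spec.binarize_threshold)
    return BinaryVolume(mask=d2 <= r2, spacing=volume.spacing, origin=volume.origin)


def _label_on_grid(center_mm, shape, spacing, spec: LabelMapSpec) -> np.ndarray:
    """Foreground mask of the Gaussian blob on an arbitrary (resampled) grid."""
    zz, yy, xx = _grid_mm(shape, spacing)
    d2 = ((zz - center_mm[0]) ** 2)[:, None, None] \
        + ((yy - center_mm[1]) ** 2)[None, :, None] \
        + ((xx - center_mm[2]) ** 2)[None, None, :]
    r2 = -2.0 * spec.sigma_mm ** 2 * np.log(spec.binarize_threshold)
    return d2 <= r2


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def _resample(voxels: np.ndarray, spacing, target_spacing):
    factors = [s / t for s, t in zip(spacing, target_spacing)]
    out = ndimage.zoom(voxels.astype(np.float32), factors, order=1)
    new_spacing = tuple(s * n0 / n1 for s, n0, n1 in
                        zip(spacing, voxels.shape, out.shape))
    return out, new_spacing


def _normalize(voxels: np.ndarray, clip):
    v = np.clip(voxels, clip[0], clip[1])
    mu, sd = float(v.mean()), float(v.std())
    if sd < 1e-3:
        sd = 1.0
    return ((v - mu) / sd).astype(np.float32), sd


def _prep_case(volume: CTVolume, config: ExtractorConfig):
    vox, spc = _resample(volume.voxels, volume.spacing, config.target_spacing)
    norm, hu_sd = _normalize(vox, config.clip_hu)
    return norm, spc, hu_sd


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _sample_patch(rng, vol, lab, patch, fg_center, fg_bias):
    shape = vol.shape
    pads = [(0, max(0, p - s)) for p, s in zip(patch, shape)]
    if any(p[1] for p in pads):
        vol = np.pad(vol, pads, constant_values=float(vol.min()))
        lab = np.pad(lab, pads)
        shape = vol.shape
    starts = []
    force_fg = fg_center is not None and rng.random() < fg_bias
    for ax in range(3):
        hi = shape[ax] - patch[ax]
        if force_fg:
            c = fg_center[ax]
            lo = int(np.clip(c - patch[ax] + patch[ax] // 4, 0, hi))
            hi2 = int(np.clip(c - patch[ax] // 4, lo, hi))
            starts.append(int(rng.integers(lo, hi2 + 1)))
        else:
            starts.append(int(rng.integers(0, hi + 1)))
    sl = tuple(slice(s, s + p) for s, p in zip(starts, patch))
    return vol[sl], lab[sl]


def _augment_patch(rng, x, y, augment, hu_sd):
    if augment.get("flip_x") and rng.random() < 0.5:
        x = x[..., ::-1].copy()
        y = y[..., ::-1].copy()
    noise = augment.get("noise_hu", 0.0)
    if noise > 0:
        x = x + rng.normal(0.0, noise / hu_sd, size=x.shape).astype(np.float32)
    return x, y


@dataclass
class ExtractorEnsemble:
    """Cross-validated fold models plus the bookkeeping QC fitting needs."""

    models: list
    config: ExtractorConfig
    label_spec: LabelMapSpec
    fold_of_case: list[int] = field(default_factory=list)
    val_records: list[dict] = field(default_factory=list)

    def save(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        meta = {"config": asdict(self.config), "label_spec": asdict(self.label_spec),
                "n_models": len(self.models), "fold_of_case": self.fold_of_case,
                "val_records": self.val_records}
        with open(os.path.join(outdir, "extractor.json"), "w") as f:
            json.dump(meta, f, indent=1)
        for i, net in enumerate(self.models):
            arrays = {}
            for j, c in enumerate(net.convs()):
                arrays[f"W{j}"] = c.W
                arrays[f"b{j}"] = c.b
            np.savez(os.path.join(outdir, f"extractor_fold{i}.npz"), **arrays)

    @classmethod
    def load(cls, outdir: str) -> "ExtractorEnsemble":
        with open(os.path.join(outdir, "extractor.json")) as f:
            meta = json.load(f)
        cfg = meta["config"]
        for k in ("target_spacing", "patch_size", "clip_hu"):
            cfg[k] = tuple(cfg[k])
        config = ExtractorConfig(**cfg)
        label_spec = LabelMapSpec(**meta["label_spec"])
        models = []
        for i in range(meta["n_models"]):
            net = _new_net(config, np.random.default_rng(0))
            data = np.load(os.path.join(outdir, f"extractor_fold{i}.npz"))
            for j, c in enumerate(net.convs()):
                c.W = data[f"W{j}"].astype(np.float32)
                c.b = data[f"b{j}"].astype(np.float32)
            models.append(net)
        return cls(models=models, config=config, label_spec=label_spec,
                   fold_of_case=meta["fold_of_case"], val_records=meta["val_records"])


def _new_net(config: ExtractorConfig, rng):
    return nets.SegNet(nd=3, in_ch=1, n_classes=2, widths=config.widths(),
                       rng=rng, block_style="chain", merge="concat")


def _center_on_grid(annotation: DiskAnnotation, volume: CTVolume, spc):
    """Annotated center in mm and in voxel indices of the resampled grid."""
    c_mm = tuple(ci * si for ci, si in zip(annotation.center, volume.spacing))
    c_idx = tuple(int(round(m / s)) for m, s in zip(c_mm, spc))
    return c_mm, c_idx


def train_extractor(cases, config: ExtractorConfig, spec: LabelMapSpec):
    """Train one 3D blob-segmentation model per cross-validation fold.

    Parameters
    ----------
    cases : list of (CTVolume, DiskAnnotation)
    config : ExtractorConfig
    spec : LabelMapSpec

    Returns
    -------
    ExtractorEnsemble
        Fold models, the fold index of every training case, and per-fold
        validation records (blob volume and foreground Dice of each held-out
        case under its fold model) for quality-control fitting.
    """
    from sklearn.model_selection import KFold

    if len(cases) < config.folds:
        raise ValueError(f"need at least {config.folds} cases for {config.folds}-fold CV")

    prepped = []
    for volume, ann in cases:
        norm, spc, hu_sd = _prep_case(volume, config)
        c_mm, c_idx = _center_on_grid(ann, volume, spc)
        lab = _label_on_grid(c_mm, norm.shape, spc, spec).astype(np.int64)
        prepped.append({"x": norm, "y": lab, "spc": spc, "hu_sd": hu_sd,
                        "center_idx": c_idx})

    kf = KFold(n_splits=config.folds, shuffle=True, random_state=config.seed)
    fold_of_case = [-1] * len(cases)
    models, val_records = [], []
    patch = tuple(config.patch_size)
    for fold, (train_idx, val_idx) in enumerate(kf.split(np.arange(len(cases)))):
        # a tiny net on a tiny foreground can occasionally collapse to the
        # all-background solution; such folds are detected on their own
        # training split and retrained from a different initialization
        for attempt in range(3):
            rng = np.random.default_rng(config.seed * 1000 + fold + attempt * 7919)
            net = _new_net(config, rng)
            opt = nets.Adam(net, lr=config.lr)
            decay_at = max(1, int(config.epochs * 2 / 3))
            fg_w = config.fg_ce_weight
            for epoch in range(config.epochs):
                if epoch == decay_at:
                    # late phase: lower lr and drop the foreground emphasis so
                    # the soft-Dice term calibrates the predicted blob size
                    opt.lr *= config.lr_decay
                    fg_w = config.fg_ce_weight_late
                draws = [(i, k) for i in train_idx for k in range(config.patches_per_volume)]
                order = rng.permutation(len(draws))
                for b0 in range(0, len(draws), config.batch_size):
                    xs, ys = [], []
                    for oi in order[b0:b0 + config.batch_size]:
                        i, _k = draws[oi]
                        p = prepped[i]
                        x, y = _sample_patch(rng, p["x"], p["y"], patch,
                                             p["center_idx"], config.fg_bias)
                        x, y = _augment_patch(rng, x, y, config.augment, p["hu_sd"])
                        xs.append(x)
                        ys.append(y)
                    xb = np.stack(xs)[:, None]
                    yb = np.stack(ys)
                    logits = net.forward(xb, train=True)
                    _loss, g = nets.ce_dice_loss(
                        logits, yb, dice_classes=[1],
                        class_weights=np.array([1.0, fg_w], dtype=np.float32))
                    net.zero_grad()
                    net.backward(g)
                    opt.step()
            collapsed = True
            for i in train_idx[:4]:
                probs = nets.sliding_window_probs(net, prepped[i]["x"], patch)
                if (probs[1] >= 0.5).any():
                    collapsed = False
                    break
            if not collapsed:
                break
        models.append(net)
        for i in val_idx:
            fold_of_case[i] = fold
            p = prepped[i]
            probs = nets.sliding_window_probs(net, p["x"], patch)
            blob = largest_component(probs[1] >= 0.5)
            vol_ml = float(blob.sum() * np.prod(p["spc"]) / 1000.0)
            inter = float((blob & (p["y"] > 0)).sum())
            denom = float(blob.sum() + (p["y"] > 0).sum())
            fg_dice = 1.0 if denom == 0 else 2.0 * inter / denom
            val_records.append({"case": int(i), "fold": fold,
                                "blob_volume_ml": vol_ml, "fg_dice": fg_dice})
    return ExtractorEnsemble(models=models, config=config, label_spec=spec,
                             fold_of_case=fold_of_case, val_records=val_records)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def predict_disk(ensemble: ExtractorEnsemble, volume: CTVolume) -> SliceExtractionResult:
    """Ensemble prediction of the disk blob for one volume.

    Per-voxel foreground probability is the mean of the fold-model softmax
    outputs; the blob is the largest connected component of the mean
    probability thresholded at 0.5. An empty blob is a valid result (it
    feeds the presence QC).
    """
    config = ensemble.config
    norm, spc, _ = _prep_case(volume, config)
    patch = tuple(config.patch_size)
    acc = None
    fold_volumes = []
    for net in ensemble.models:
        probs = nets.sliding_window_probs(net, norm, patch)
        fold_volumes.append(float(
            largest_component(probs[1] >= 0.5).sum() * np.prod(spc) / 1000.0))
        acc = probs if acc is None else acc + probs
    mean = acc / len(ensemble.models)

    # map foreground probability back to the native grid
    factors = [n1 / n0 for n1, n0 in zip(volume.shape, mean.shape[1:])]
    fg = ndimage.zoom(mean[1], factors, order=1)
    # zoom can be off by a voxel; fix by crop/pad
    fg = _fit_shape(fg, volume.shape)
    fg = np.clip(fg, 0.0, 1.0).astype(np.float32)
    prob = ProbabilityMap(probs=np.stack([1.0 - fg, fg]))
    blob = BinaryVolume(mask=largest_component(fg >= 0.5),
                        spacing=volume.spacing, origin=volume.origin)
    vol_ml = blob.volume_ml()
    if blob.mask.any():
        z_index = blob_to_z(blob)
        z_mm = volume.z_mm(z_index)
    else:
        z_index, z_mm = None, None
    return SliceExtractionResult(z_index=z_index, z_mm=z_mm, blob=blob,
                                 blob_volume_ml=vol_ml, prob=prob,
                                 fold_volumes_ml=fold_volumes)


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Largest 26-connected foreground component (empty in -> empty out).

    Standard blob post-processing: the Gaussian-ball target is a single
    connected region, so stray false-positive islands are discarded before
    volume and centroid are computed.
    """
    if not mask.any():
        return mask
    structure = np.ones((3,) * mask.ndim, dtype=bool)
    labeled, n = ndimage.label(mask, structure=structure)
    if n == 1:
        return mask
    sizes = ndimage.sum_labels(mask, labeled, index=np.arange(1, n + 1))
    return labeled == (1 + int(np.argmax(sizes)))


def _fit_shape(arr, shape):
    sl = tuple(slice(0, min(a, s)) for a, s in zip(arr.shape, shape))
    out = np.zeros(shape, dtype=arr.dtype)
    out[sl] = arr[sl]
    return out


def blob_to_z(blob: BinaryVolume) -> int:
    """Reduce a blob to a slice index: rounded foreground centroid along z.

    Ties at exactly .5 round toward the inferior slice. Raises
    :class:`NoDetection` for an empty blob.
    """
    counts = blob.mask.sum(axis=(1, 2))
    total = counts.sum()
    if total == 0:
        raise NoDetection("empty blob: no L3/L4 level detected")
    centroid = float((np.arange(len(counts)) * counts).sum() / total)
    return int(np.ceil(centroid - 0.5))


def delta_z(pred: SliceExtractionResult | None, truth: DiskAnnotation,
            volume: CTVolume) -> DeltaZResult:
    """Absolute z deviation (mm) and hit indicators at 0/5/10 mm tolerances.

    The ground-truth slice is the annotated center rounded with the same
    inferior tie rule as :func:`blob_to_z`; an undefined prediction counts as
    a miss at every tolerance.
    """
    truth_idx = int(np.ceil(truth.center[0] - 0.5))
    truth_mm = volume.z_mm(truth_idx)
    if pred is None or pred.z_index is None:
        return DeltaZResult(delta_mm=None, hit_0mm=False, hit_5mm=False,
                            hit_10mm=False, detected=False)
    d = abs(pred.z_mm - truth_mm)
    eps = 1e-9
    return DeltaZResult(delta_mm=float(d), hit_0mm=d <= eps, hit_5mm=d <= 5 + eps,
                        hit_10mm=d <= 10 + eps, detected=True)
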
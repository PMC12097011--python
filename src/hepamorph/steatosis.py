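"""Steatotic-region semantic segmentation at desk scale.

A shallow trainable voxel classifier on hand-crafted multi-scale features
stands in for a cloud-trained U-Net: the quantities of interest are the
analysis-chain outputs — loss/accuracy/IoU training curves, binary masks,
and volume fractions — not specific network weights.  The classifier is a
one-hidden-layer network on per-voxel features (Gaussian-smoothed
intensity and local standard deviation at each scale, plus local
intensity range), trained by full-batch gradient descent on sparsely
annotated voxels only, which mirrors brush-annotation sparsity: unlabeled
voxels never enter the loss.  A hidden layer is needed because steatotic
regions occupy an *intermediate* gray band — brighter than parenchyma,
darker than lumens — which no linear decision boundary can isolate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .grid import VoxelGrid

__all__ = [
    "TrainingCurves",
    "VoxelClassifier",
    "extract_features",
    "train",
    "predict",
    "evaluate_overlap",
    "apply_mask",
]

# annotation label codes (0 = unlabeled, mirroring sparse brush annotation)
UNLABELED, TARGET, BACKGROUND = 0, 1, 2


@dataclass
class TrainingCurves:
    """Per-logged-iteration training and validation metrics."""

    iteration: list[int] = field(default_factory=list)
    loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    train_iou: list[float] = field(default_factory=list)
    val_iou: list[float] = field(default_factory=list)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "iteration": self.iteration,
                "loss": self.loss,
                "train_accuracy": self.train_accuracy,
                "val_accuracy": self.val_accuracy,
                "train_iou": self.train_iou,
                "val_iou": self.val_iou,
            }
        )

    @property
    def final_val_accuracy(self) -> float:
        return self.val_accuracy[-1]

    @property
    def final_val_iou(self) -> float:
        return self.val_iou[-1]


@dataclass
class VoxelClassifier:
    """One-hidden-layer voxel classifier over a fixed feature specification.

    ``scores`` is σ(tanh(z W1 + b1) · w2 + b2) on standardized features;
    prediction is deterministic given the stored parameters and
    threshold.
    """

    scales_um: tuple[float, ...]
    w1: np.ndarray  # (n_features, n_hidden)
    b1: np.ndarray  # (n_hidden,)
    w2: np.ndarray  # (n_hidden,)
    b2: float
    feature_means: np.ndarray
    feature_sds: np.ndarray
    training_seed: int = 0
    decision_threshold: float = 0.5

    @property
    def n_features(self) -> int:
        return self.w1.shape[0]

    def scores(self, features: np.ndarray) -> np.ndarray:
        """Per-voxel target probability; deterministic given parameters."""
        if features.shape[-1] != self.n_features:
            raise ValueError(
                f"feature specification mismatch: classifier expects "
                f"{self.n_features} features, got {features.shape[-1]}"
            )
        z = (features - self.feature_means) / self.feature_sds
        hidden = np.tanh(z @ self.w1 + self.b1)
        logits = hidden @ self.w2 + self.b2
        return 1.0 / (1.0 + np.exp(-logits))

    def save(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "scales_um": list(self.scales_um),
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2,
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "training_seed": self.training_seed,
            "decision_threshold": self.decision_threshold,
        }
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def load(cls, path) -> "VoxelClassifier":
        d = json.loads(Path(path).read_text())
        return cls(
            scales_um=tuple(d["scales_um"]),
            w1=np.asarray(d["w1"], dtype=float),
            b1=np.asarray(d["b1"], dtype=float),
            w2=np.asarray(d["w2"], dtype=float),
            b2=float(d["b2"]),
            feature_means=np.asarray(d["feature_means"], dtype=float),
            feature_sds=np.asarray(d["feature_sds"], dtype=float),
            training_seed=int(d["training_seed"]),
            decision_threshold=float(d["decision_threshold"]),
        )


# -- features ---------------------------------------------------------------


def extract_features(gray: VoxelGrid, scales_um=(2.0, 5.0)) -> np.ndarray:
    """Per-voxel multi-scale features, shape = volume shape + (2·|scales| + 1,).

    For each scale: Gaussian-smoothed intensity and local standard
    deviation (from smoothed first and second moments); plus one local
    intensity range (max − min over a small neighbourhood).  The feature
    set targets the steatotic phenotype — vacuolated bright regions with
    interspersed small dark cells, i.e. locally bright *and* locally
    heterogeneous texture.
    """
    scales_um = tuple(scales_um)
    if not scales_um:
        raise ValueError("scales must be nonempty")
    if any(s < min(gray.spacing) for s in scales_um):
        raise ValueError(f"scales {scales_um} must be >= the voxel spacing {gray.spacing}")
    data = np.asarray(gray.data, dtype=np.float32)
    feats = []
    for s in scales_um:
        sigma = [s / sp for sp in gray.spacing]
        mu = ndimage.gaussian_filter(data, sigma=sigma, mode="nearest")
        mu2 = ndimage.gaussian_filter(data**2, sigma=sigma, mode="nearest")
        var = np.maximum(mu2 - mu**2, 0.0)
        feats.append(mu)
        feats.append(np.sqrt(var))
    size = max(3, 2 * int(round(min(scales_um) / min(gray.spacing))) + 1)
    rng_feat = ndimage.maximum_filter(data, size=size) - ndimage.minimum_filter(data, size=size)
    feats.append(rng_feat)
    return np.stack(feats, axis=-1)


# -- training ---------------------------------------------------------------


def _metrics(prob: np.ndarray, y: np.ndarray, threshold: float = 0.5):
    pred = prob >= threshold
    acc = float((pred == y).mean())
    inter = float(np.logical_and(pred, y).sum())
    union = float(np.logical_or(pred, y).sum())
    iou = inter / union if union > 0 else 1.0
    return acc, iou


def train(
    features: np.ndarray,
    labels: VoxelGrid,
    iterations: int = 600,
    val_fraction: float = 0.2,
    seed: int = 0,
    learning_rate: float = 0.5,
    log_interval: int = 50,
    decision_threshold: float = 0.5,
    n_hidden: int = 8,
    scales_um: tuple[float, ...] = (),
) -> tuple[VoxelClassifier, TrainingCurves]:
    """Fit the voxel classifier on annotated voxels only.

    ``labels`` uses codes 0 = unlabeled, 1 = target, 2 = background.
    Annotated voxels are split into train/validation; full-batch gradient
    descent on the logistic loss runs for ``iterations`` steps with
    metrics logged every ``log_interval`` iterations (and at the final
    step).  Reproducible given ``seed``.
    """
    if iterations <= 0:
        raise ValueError("iterations must be >= 1")
    if not 0 < val_fraction < 1:
        raise ValueError("val_fraction must be in (0, 1)")
    lab = np.asarray(labels.data)
    annotated = lab != UNLABELED
    y_all = lab[annotated] == TARGET
    if not y_all.any() or y_all.all():
        raise ValueError("training requires annotations of both target and background")
    X_all = features[annotated].astype(np.float64)

    rng = np.random.default_rng(seed)
    n = len(y_all)
    order = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n)))
    val_idx, train_idx = order[:n_val], order[n_val:]
    Xt, yt = X_all[train_idx], y_all[train_idx]
    Xv, yv = X_all[val_idx], y_all[val_idx]

    means = Xt.mean(axis=0)
    sds = Xt.std(axis=0)
    sds[sds == 0] = 1.0
    Zt = (Xt - means) / sds
    Zv = (Xv - means) / sds

    nf = Zt.shape[1]
    w1 = rng.normal(0.0, 1.0 / np.sqrt(nf), size=(nf, n_hidden))
    b1 = np.zeros(n_hidden)
    w2 = rng.normal(0.0, 0.5 / np.sqrt(n_hidden), size=n_hidden)
    b2 = 0.0
    curves = TrainingCurves()

    def forward(Z):
        hidden = np.tanh(Z @ w1 + b1)
        return hidden, 1.0 / (1.0 + np.exp(-(hidden @ w2 + b2)))

    def log(it):
        _, pt = forward(Zt)
        _, pv = forward(Zv)
        eps = 1e-12
        loss = float(-np.mean(yt * np.log(pt + eps) + (~yt) * np.log(1 - pt + eps)))
        acc_t, iou_t = _metrics(pt, yt, decision_threshold)
        acc_v, iou_v = _metrics(pv, yv, decision_threshold)
        curves.iteration.append(it)
        curves.loss.append(loss)
        curves.train_accuracy.append(acc_t)
        curves.val_accuracy.append(acc_v)
        curves.train_iou.append(iou_t)
        curves.val_iou.append(iou_v)

    log(0)
    m = len(yt)
    for it in range(1, iterations + 1):
        hidden, p = forward(Zt)
        err = (p - yt) / m  # d loss / d logits
        grad_w2 = hidden.T @ err
        grad_b2 = float(err.sum())
        back = np.outer(err, w2) * (1.0 - hidden**2)
        grad_w1 = Zt.T @ back
        grad_b1 = back.sum(axis=0)
        w2 -= learning_rate * grad_w2
        b2 -= learning_rate * grad_b2
        w1 -= learning_rate * grad_w1
        b1 -= learning_rate * grad_b1
        if it % log_interval == 0 or it == iterations:
            log(it)

    clf = VoxelClassifier(
        scales_um=tuple(scales_um), w1=w1, b1=b1, w2=w2, b2=b2,
        feature_means=means, feature_sds=sds,
        training_seed=seed, decision_threshold=decision_threshold,
    )
    return clf, curves


# -- prediction -------------------------------------------------------------


def predict(
    classifier: VoxelClassifier,
    features: np.ndarray,
    grid: VoxelGrid,
    closing_radius_um: float = 0.0,
    min_component_um3: float = 0.0,
) -> VoxelGrid:
    """Threshold classifier scores, then post-process.

    Post-processing: morphological closing with a ball of the given
    radius, then removal of connected components smaller than
    ``min_component_um3`` (26-connectivity).
    """
    prob = classifier.scores(features.reshape(-1, features.shape[-1]))
    mask = (prob >= classifier.decision_threshold).reshape(features.shape[:-1])
    if closing_radius_um > 0:
        from skimage.morphology import ball

        r_vox = max(1, int(round(closing_radius_um / min(grid.spacing))))
        mask = ndimage.binary_closing(mask, structure=ball(r_vox))
    if min_component_um3 > 0 and mask.any():
        comp, _ = ndimage.label(mask, structure=np.ones((3, 3, 3), bool))
        counts = np.bincount(comp.ravel())
        small = np.flatnonzero(counts < min_component_um3 / grid.voxel_volume)
        mask &= ~np.isin(comp, small[small > 0])
    return grid.with_data(mask.astype(np.int8), kind="labels")


# -- evaluation and extraction ----------------------------------------------


def evaluate_overlap(pred: VoxelGrid, truth: VoxelGrid) -> dict[str, float]:
    """Voxelwise accuracy, IoU and Dice of two masks on the same grid.

    IoU is defined as 1 when both masks are empty.  Symmetric in its
    arguments for IoU and Dice.
    """
    pred.require_same_grid(truth, "truth mask")
    p = np.asarray(pred.data) > 0
    t = np.asarray(truth.data) > 0
    inter = float(np.logical_and(p, t).sum())
    union = float(np.logical_or(p, t).sum())
    total = float(p.size)
    iou = inter / union if union > 0 else 1.0
    dice = 2 * inter / (p.sum() + t.sum()) if (p.sum() + t.sum()) > 0 else 1.0
    accuracy = float((p == t).sum()) / total
    return {"accuracy": accuracy, "iou": iou, "dice": float(dice)}


def apply_mask(gray: VoxelGrid, mask: VoxelGrid) -> VoxelGrid:
    """Multiply the grayscale volume by a binary mask (0 outside)."""
    gray.require_same_grid(mask, "mask")
    m = np.asarray(mask.data) > 0
    return gray.with_data(np.where(m, gray.data, 0).astype(gray.data.dtype))
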
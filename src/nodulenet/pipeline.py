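"""End-to-end orchestration: train / predict / evaluate.

Training follows the reference protocol: SGD with learning rate 0.01,
momentum 0.9, weight decay 1e-4, batch size 4, 200 epochs, constant
learning rate, optimizing the compound segmentation + classification
loss on lesion-centered patches with on-the-fly augmentation. Scaled-down
overrides (patch size, channel widths, epochs, step cap) make the same
loop runnable at desk scale on one CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as nio
from .losses import LossBreakdown, total_loss
from .metrics import (
    aggregate_report,
    classification_metrics,
    confusion_counts,
    dice_coefficient,
    iou,
)
from .network import MultiTaskNoduleNet, NetworkConfig, build_model
from .nn import SGD, Tensor, softmax
from .phantom import load_manifest
from .preprocess import (
    AugmentConfig,
    CTVolume,
    LabeledPatch,
    MaskVolume,
    augment_patch,
    clip_normalize_hu,
    extract_patch,
    resample_isotropic,
)


@dataclass
class TrainConfig:
    manifest: str = ""
    val_manifest: Optional[str] = None
    out_dir: str = "runs/default"
    lr: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 1e-4
    batch_size: int = 4
    epochs: int = 200
    max_steps: Optional[int] = None       # scaled-down override: cap total steps
    patch_size: int = 64                  # scaled-down override: e.g. 32
    val_every: int = 1                    # epochs between validation passes
    seed: int = 0
    target_spacing_mm: float = 1.0
    network: NetworkConfig = field(default_factory=NetworkConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.patch_size % 32:
            raise ValueError("patch_size must be a multiple of 32")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "manifest", "val_manifest", "out_dir", "lr", "momentum", "weight_decay",
            "batch_size", "epochs", "max_steps", "patch_size", "val_every",
            "seed", "target_spacing_mm",
        )}
        d["network"] = self.network.to_dict()
        d["augment"] = self.augment.__dict__.copy()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        if "network" in d and isinstance(d["network"], dict):
            d["network"] = NetworkConfig.from_dict(d["network"])
        if "augment" in d and isinstance(d["augment"], dict):
            d["augment"] = AugmentConfig(**d["augment"])
        return cls(**d)


@dataclass
class RunRecord:
    epochs: List[Dict[str, float]]
    checkpoint_last: str
    checkpoint_best: Optional[str]
    config: TrainConfig
    val_history: List[Dict[str, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# data loading
# ---------------------------------------------------------------------------

def load_case_patch(row, patch_size: int, target_mm: float = 1.0) -> LabeledPatch:
    """Manifest row -> normalized lesion-centered patch."""
    vol = nio.load_volume(row["image_path"], "HU")
    mask = nio.load_mask(row["mask_path"])
    center = (int(row["center_z"]), int(row["center_y"]), int(row["center_x"]))
    if any(abs(s - target_mm) > 1e-6 for s in vol.spacing_mm):
        scale = np.array(vol.spacing_mm) / target_mm
        center = tuple(int(round(c * f)) for c, f in zip(center, scale))
        vol, mask = resample_isotropic(vol, mask, target_mm)
    vol = clip_normalize_hu(vol)
    return extract_patch(
        vol, mask, center,
        label=int(row["label"]), case_id=str(row["case_id"]), size=patch_size,
    )


def load_patches(manifest: pd.DataFrame, patch_size: int, target_mm: float = 1.0) -> List[LabeledPatch]:
    return [load_case_patch(row, patch_size, target_mm) for _, row in manifest.iterrows()]


def _batch_arrays(patches: Sequence[LabeledPatch]):
    imgs = np.stack([p.image for p in patches])[:, None].astype(np.float32)
    masks = np.stack([p.mask for p in patches])
    labels = np.array([p.label for p in patches])
    return imgs, masks, labels


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: MultiTaskNoduleNet, config: TrainConfig, path: Path) -> None:
    """Single-file archive of weights + config + seed (npz)."""
    payload = {f"param/{k}": v for k, v in model.state_dict().items()}
    payload["config_json"] = np.frombuffer(
        json.dumps(config.to_dict()).encode(), dtype=np.uint8
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **payload)


def load_checkpoint(path: Path) -> Tuple[MultiTaskNoduleNet, TrainConfig]:
    with np.load(path) as data:
        cfg = TrainConfig.from_dict(json.loads(bytes(data["config_json"]).decode()))
        state = {k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")}
    model = build_model(cfg.network)
    model.load_state_dict(state)
    return model, cfg


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _forward_losses(model, imgs, masks, labels):
    seg_logits, cls_logits = model(Tensor(imgs))
    seg_probs = softmax(seg_logits, axis=1)
    cls_probs = softmax(cls_logits, axis=1)
    return total_loss(seg_probs, masks, cls_probs, labels)


def train(config: TrainConfig) -> RunRecord:
    """Run the training loop; returns the run record with checkpoints."""
    manifest = load_manifest(Path(config.manifest))
    if len(manifest) == 0:
        raise ValueError(f"empty manifest: {config.manifest}")
    patches = load_patches(manifest, config.patch_size, config.target_spacing_mm)
    val_patches = None
    if config.val_manifest:
        val_patches = load_patches(
            load_manifest(Path(config.val_manifest)), config.patch_size,
            config.target_spacing_mm,
        )

    model = build_model(config.network)
    opt = SGD(model.parameters(), lr=config.lr, momentum=config.momentum,
              weight_decay=config.weight_decay)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    step_log = open(out_dir / "steps.jsonl", "w")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 10]))
    epoch_rows: List[Dict[str, float]] = []
    val_history: List[Dict[str, float]] = []
    best_score, best_path = -np.inf, None
    step = 0
    done = False
    for epoch in range(config.epochs):
        order = rng.permutation(len(patches))
        losses: List[LossBreakdown] = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = [
                augment_patch(
                    patches[i], config.augment,
                    seed=int(np.random.SeedSequence(
                        [config.seed, 11, epoch, int(i)]).generate_state(1)[0] % (2**31)),
                )
                for i in idx
            ]
            imgs, masks, labels = _batch_arrays(batch)
            loss, bd = _forward_losses(model, imgs, masks, labels)
            if not np.isfinite(bd.l_total):
                step_log.close()
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} step {step}: {bd.as_dict()}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(bd)
            step_log.write(json.dumps({"step": step, "epoch": epoch, **bd.as_dict()}) + "\n")
            step += 1
            if config.max_steps is not None and step >= config.max_steps:
                done = True
                break
        mean_bd = {
            k: float(np.mean([bd.as_dict()[k] for bd in losses]))
            for k in ("l_total", "l_seg", "l_ce", "l_dice", "l_cls")
        }
        epoch_rows.append({"epoch": epoch, **mean_bd})
        if val_patches and (epoch % max(1, config.val_every) == 0 or done
                            or epoch == config.epochs - 1):
            val = _evaluate_patches(model, val_patches)
            val_history.append({"epoch": epoch, **val})
            score = val["dice"] + val["acc"]
            if score > best_score:
                best_score = score
                best_path = out_dir / "checkpoint_best.npz"
                save_checkpoint(model, config, best_path)
        if done:
            break
    step_log.close()
    pd.DataFrame(epoch_rows).to_csv(out_dir / "training_log.csv", index=False)
    last_path = out_dir / "checkpoint_last.npz"
    save_checkpoint(model, config, last_path)
    return RunRecord(
        epochs=epoch_rows,
        checkpoint_last=str(last_path),
        checkpoint_best=str(best_path) if best_path else None,
        config=config,
        val_history=val_history,
    )


def _evaluate_patches(model, patches: Sequence[LabeledPatch]) -> Dict[str, float]:
    """Mean Dice and classification accuracy over patches (eval mode)."""
    dices, correct = [], 0
    for p in patches:
        seg, prob = predict_patch(model, p)
        dices.append(dice_coefficient(seg, p.mask))
        correct += int((prob >= 0.5) == bool(p.label))
    return {"dice": float(np.mean(dices)), "acc": correct / len(patches)}


# ---------------------------------------------------------------------------
# prediction / evaluation
# ---------------------------------------------------------------------------

def predict_patch(model: MultiTaskNoduleNet, patch: LabeledPatch) -> Tuple[np.ndarray, float]:
    """Binary mask (argmax over the 2-channel softmax) + malignancy probability."""
    seg_logits, cls_logits = model(Tensor(patch.image[None, None]))
    seg = np.argmax(seg_logits.data[0], axis=0).astype(np.uint8)
    probs = softmax(cls_logits, axis=1).data[0]
    return seg, float(probs[1])


def predict(checkpoint: Path, manifest_path: Path, out_dir: Path) -> pd.DataFrame:
    """Per case: predicted mask patch as NIfTI + malignancy probability row."""
    model, cfg = load_checkpoint(checkpoint)
    manifest = load_manifest(Path(manifest_path))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for _, row in manifest.iterrows():
        patch = load_case_patch(row, cfg.patch_size, cfg.target_spacing_mm)
        seg, prob = predict_patch(model, patch)
        mask_path = f"{patch.case_id}_pred.nii.gz"
        nio.save_mask(MaskVolume(seg), (cfg.target_spacing_mm,) * 3, out_dir / mask_path)
        rows.append({
            "case_id": patch.case_id,
            "prob_malignant": round(prob, 6),
            "label": patch.label,
            "pred_mask_path": mask_path,
        })
    preds = pd.DataFrame(rows)
    preds.to_csv(out_dir / "predictions.csv", index=False)
    return preds


def evaluate(
    predictions_dir: Path,
    manifest_path: Path,
    out_dir: Optional[Path] = None,
    group_key: Optional[str] = None,
    patch_size: Optional[int] = None,
) -> Dict[str, pd.DataFrame]:
    """Score predictions against ground truth; write per-case + summary CSVs.

    Segmentation: per-case Dice / IoU / sensitivity / precision on the
    patch geometry. Classification: case-level confusion at probability
    threshold 0.5. `group_key` (a manifest column, e.g. a center id)
    stratifies the summaries; missing cases are reported explicitly.
    """
    predictions_dir = Path(predictions_dir)
    out_dir = Path(out_dir) if out_dir is not None else predictions_dir
    preds = pd.read_csv(predictions_dir / "predictions.csv")
    manifest = load_manifest(Path(manifest_path))
    missing = set(manifest["case_id"]) - set(preds["case_id"])
    if missing:
        raise ValueError(f"predictions missing for cases: {sorted(missing)}")
    preds = preds.set_index("case_id")

    if patch_size is None:
        sample = nio.load_mask(predictions_dir / preds.iloc[0]["pred_mask_path"])
        patch_size = sample.shape[0]

    rows = []
    for _, row in manifest.iterrows():
        cid = row["case_id"]
        gt_patch = load_case_patch(row, patch_size)
        pred_mask = nio.load_mask(predictions_dir / preds.loc[cid, "pred_mask_path"]).data
        cc = confusion_counts(pred_mask, gt_patch.mask)
        rec = {
            "case_id": cid,
            "label": int(row["label"]),
            "prob_malignant": float(preds.loc[cid, "prob_malignant"]),
            "DICE": dice_coefficient(pred_mask, gt_patch.mask),
            "mIoU": iou(pred_mask, gt_patch.mask),
            "SEN": cc.tp / (cc.tp + cc.fn) if cc.tp + cc.fn else np.nan,
            "PRE": cc.tp / (cc.tp + cc.fp) if cc.tp + cc.fp else np.nan,
        }
        if group_key is not None:
            rec[group_key] = row[group_key]
        rows.append(rec)
    per_case = pd.DataFrame(rows)
    per_case["pred_label"] = (per_case["prob_malignant"] >= 0.5).astype(int)

    seg_summary = aggregate_report(
        per_case[["DICE", "SEN", "PRE", "mIoU"] + ([group_key] if group_key else [])],
        group_key=group_key,
    )

    def cls_row(df: pd.DataFrame, label: str) -> dict:
        counts = confusion_counts(df["pred_label"].to_numpy(), df["label"].to_numpy())
        m = classification_metrics(counts)
        out = {"group": label, "n": len(df)}
        out.update({
            k: (round(100.0 * v, 2) if v is not None else np.nan) for k, v in m.items()
        })
        return out

    cls_rows = []
    if group_key is not None:
        for name, df in per_case.groupby(group_key, sort=True):
            cls_rows.append(cls_row(df, str(name)))
    cls_rows.append(cls_row(per_case, "overall"))
    cls_summary = pd.DataFrame(cls_rows)

    out_dir.mkdir(parents=True, exist_ok=True)
    per_case.to_csv(out_dir / "metrics_per_case.csv", index=False, float_format="%.6f")
    seg_summary.to_csv(out_dir / "metrics_segmentation.csv", index=False)
    cls_summary.to_csv(out_dir / "metrics_classification.csv", index=False)
    return {"per_case": per_case, "segmentation": seg_summary, "classification": cls_summary}


# ---------------------------------------------------------------------------
# cohort split
# ---------------------------------------------------------------------------

def split_manifest(
    manifest: pd.DataFrame, seed: int, ratios=(0.8, 0.1, 0.1)
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Seeded 8:1:1 train/val/test shuffle-split of a cohort manifest."""
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 20]))
    order = rng.permutation(len(manifest))
    n = len(manifest)
    n_train = int(round(ratios[0] * n))
    n_val = int(round(ratios[1] * n))
    idx_train = order[:n_train]
    idx_val = order[n_train : n_train + n_val]
    idx_test = order[n_train + n_val :]
    parts = tuple(manifest.iloc[i].reset_index(drop=True) for i in (idx_train, idx_val, idx_test))
    return parts
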
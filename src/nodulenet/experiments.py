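"""Reference desk-scale experiments: overfitting probe, held-out
generalization, and a reproducibility check of the full smoke chain.

These encapsulate the package's standard CPU-scale study conditions so the
test suite and reporting scripts run exactly the same procedures:

* ``overfit``: train on 8 fixed phantom patches and verify the multi-task
  model can memorize them (training Dice and classification accuracy) —
  a capacity/optimization sanity probe.
* ``generalization``: a 40-phantom cohort split 8:1:1; train on the 32
  training cases with augmentation, select the checkpoint by validation
  score, and report held-out Dice and accuracy — verifies both branches
  learn transferable signal.
* ``reproducibility``: run the make-phantoms → train → predict → evaluate
  chain twice with one seed and compare the metric CSVs byte for byte.

Problem sizes (reduced widths 8/16/32/64, 32³ patches, step caps) are
chosen so each experiment completes in minutes on a single CPU core.
"""

from __future__ import annotations

import filecmp
from dataclasses import dataclass
from pathlib import Path
from typing import Dict

import numpy as np

from .network import scaled_down_config
from .nn import SGD
from .phantom import generate_cohort, load_manifest
from .pipeline import (
    TrainConfig,
    _batch_arrays,
    _evaluate_patches,
    _forward_losses,
    evaluate,
    load_checkpoint,
    load_patches,
    predict,
    split_manifest,
    train,
)
from .preprocess import AugmentConfig

SCALED_CHANNELS = (8, 16, 32, 64)
OVERFIT_N_PATCHES = 8
OVERFIT_MAX_STEPS = 150
GENERALIZATION_N = 40
GENERALIZATION_MAX_STEPS = 700

GEN_AUGMENT = AugmentConfig(
    p_rotate=0.3, p_flip=0.5, p_elastic=0.5, p_noise=0.2, elastic_alpha=3.0
)


@dataclass
class ExperimentResult:
    dice: float
    accuracy: float
    n_cases: int
    steps: int


def overfit(
    model_seed: int,
    cohort_dir: Path,
    cohort_seed: int = 42,
    max_steps: int = OVERFIT_MAX_STEPS,
    check_every: int = 25,
    target_dice: float = 0.8,
) -> ExperimentResult:
    """Memorization probe: train on 8 fixed phantom patches, no augmentation.

    Stops early once training Dice >= `target_dice` and training accuracy
    is perfect; otherwise runs to `max_steps`.
    """
    cohort_dir = Path(cohort_dir)
    if not (cohort_dir / "manifest.csv").exists():
        generate_cohort(OVERFIT_N_PATCHES, 0.5, seed=cohort_seed, out_dir=cohort_dir)
    manifest = load_manifest(cohort_dir / "manifest.csv")
    patches = load_patches(manifest, patch_size=32)
    cfg = TrainConfig(
        manifest=str(cohort_dir / "manifest.csv"),
        out_dir=str(cohort_dir / f"run_seed{model_seed}"),
        patch_size=32,
        seed=model_seed,
        epochs=1,
        network=scaled_down_config(stage_channels=SCALED_CHANNELS, seed=model_seed),
        augment=AugmentConfig.identity(),
    )
    from .network import build_model

    model = build_model(cfg.network)
    opt = SGD(model.parameters(), lr=cfg.lr, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(np.random.SeedSequence([model_seed, 10]))
    step = 0
    result = None
    while step < max_steps:
        order = rng.permutation(len(patches))
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            imgs, masks, labels = _batch_arrays([patches[i] for i in idx])
            loss, bd = _forward_losses(model, imgs, masks, labels)
            if not np.isfinite(bd.l_total):
                raise FloatingPointError(f"non-finite loss at step {step}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            step += 1
            if step % check_every == 0 or step >= max_steps:
                probe = _evaluate_patches(model, patches)
                result = ExperimentResult(
                    probe["dice"], probe["acc"], len(patches), step)
                if probe["dice"] >= target_dice and probe["acc"] == 1.0:
                    return result
            if step >= max_steps:
                break
    return result


def generalization(
    seed: int,
    work_dir: Path,
    n_cases: int = GENERALIZATION_N,
    max_steps: int = GENERALIZATION_MAX_STEPS,
) -> ExperimentResult:
    """Held-out performance on a phantom cohort split 8:1:1."""
    work_dir = Path(work_dir)
    data_dir = work_dir / "data"
    if not (data_dir / "manifest.csv").exists():
        generate_cohort(n_cases, 0.5, seed=seed, out_dir=data_dir)
    manifest = load_manifest(data_dir / "manifest.csv")
    tr, va, te = split_manifest(manifest, seed=seed)
    for name, df in (("train", tr), ("val", va), ("test", te)):
        df.to_csv(work_dir / f"{name}.csv", index=False)
    cfg = TrainConfig(
        manifest=str(work_dir / "train.csv"),
        val_manifest=str(work_dir / "val.csv"),
        out_dir=str(work_dir / "run"),
        epochs=max(1, int(np.ceil(max_steps / max(1, len(tr) // 4)))),
        max_steps=max_steps,
        patch_size=32,
        val_every=3,
        seed=seed,
        network=scaled_down_config(stage_channels=SCALED_CHANNELS, seed=seed),
        augment=GEN_AUGMENT,
    )
    record = train(cfg)
    model, _ = load_checkpoint(record.checkpoint_best or record.checkpoint_last)
    test_patches = load_patches(te, patch_size=32)
    probe = _evaluate_patches(model, test_patches)
    return ExperimentResult(probe["dice"], probe["acc"], len(test_patches),
                            min(max_steps, len(record.epochs) * max(1, len(tr) // 4)))


def reproducibility(seed: int, work_dir: Path, n_cases: int = 6) -> Dict[str, bool]:
    """Run the full smoke chain twice with one seed; compare metric CSVs."""
    work_dir = Path(work_dir)
    outputs = []
    for run in ("a", "b"):
        base = work_dir / run
        data = base / "data"
        generate_cohort(n_cases, 0.5, seed=seed, out_dir=data)
        cfg = TrainConfig(
            manifest=str(data / "manifest.csv"),
            out_dir=str(base / "run"),
            epochs=2,
            patch_size=32,
            seed=seed,
            network=scaled_down_config(stage_channels=(4, 8, 8, 16), seed=seed),
            augment=AugmentConfig.identity(),
        )
        record = train(cfg)
        predict(record.checkpoint_last, data / "manifest.csv", base / "preds")
        evaluate(base / "preds", data / "manifest.csv", base / "eval")
        outputs.append(base)
    a, b = outputs
    return {
        name: filecmp.cmp(a / "eval" / name, b / "eval" / name, shallow=False)
        for name in ("metrics_per_case.csv", "metrics_segmentation.csv",
                     "metrics_classification.csv")
    }
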
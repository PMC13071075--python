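"""Seven-metric evaluation harness.

Segmentation is scored per case with DICE(A,B) = 2|A∩B| / (|A|+|B|) and
mean IoU over cases (foreground IoU = TP / (TP+FP+FN)); classification is
scored case-wise from the confusion table with

    ACC = (TP+TN)/(TP+TN+FP+FN),  SEN = TP/(TP+FN),  SPE = TN/(FP+TN),
    PRE = TP/(TP+FP),             F1  = 2TP/(2TP+FP+FN).

Reports aggregate per-case values as mean ± sample standard deviation,
formatted as percentages with two decimals. A ratio with a zero
denominator is reported as absent (None / NaN), never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

SEG_METRICS = ("DICE", "SEN", "PRE", "mIoU")
CLS_METRICS = ("ACC", "SEN", "SPE", "PRE", "F1")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Voxel-wise (masks) or case-wise (label vectors) confusion counts."""
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    for arr, name in ((pred, "pred"), (gt, "gt")):
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"{name} must be binary, found values {vals}")
    p = pred.astype(bool)
    g = gt.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & g)),
        fp=int(np.count_nonzero(p & ~g)),
        fn=int(np.count_nonzero(~p & g)),
        tn=int(np.count_nonzero(~p & ~g)),
    )


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric overlap 2|A∩B|/(|A|+|B|); both-empty defined as 1.0."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    size = int(a.sum()) + int(b.sum())
    if size == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / size


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Foreground intersection-over-union; both-empty defined as 1.0."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return int((a & b).sum()) / union


def miou(
    cases: Sequence[Tuple[np.ndarray, np.ndarray]],
    per_class: bool = False,
) -> float:
    """Mean over cases of foreground IoU = TP/(TP+FP+FN).

    The default (foreground-only) reading is the one consistent with the
    per-case identity IoU = DICE/(2-DICE); `per_class=True` instead
    averages foreground and background IoU within each case.
    """
    if len(cases) == 0:
        raise ValueError("miou requires at least one case")
    if not per_class:
        return float(np.mean([iou(pred, gt) for pred, gt in cases]))
    vals = [
        0.5 * (iou(pred, gt) + iou(1 - np.asarray(pred), 1 - np.asarray(gt)))
        for pred, gt in cases
    ]
    return float(np.mean(vals))


def classification_metrics(counts: ConfusionCounts) -> Dict[str, Optional[float]]:
    """ACC/SEN/SPE/PRE/F1 from a confusion table; zero-denominator -> None."""
    if counts.total <= 0:
        raise ValueError("empty confusion table")

    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None

    return {
        "ACC": ratio(counts.tp + counts.tn, counts.total),
        "SEN": ratio(counts.tp, counts.tp + counts.fn),
        "SPE": ratio(counts.tn, counts.fp + counts.tn),
        "PRE": ratio(counts.tp, counts.tp + counts.fp),
        "F1": ratio(2 * counts.tp, 2 * counts.tp + counts.fp + counts.fn),
    }


def aggregate_report(
    per_case: pd.DataFrame,
    group_key: Optional[str] = None,
) -> pd.DataFrame:
    """Mean ± sample sd per metric column, in percent with two decimals.

    `per_case` holds one row per case with metric columns on the [0, 1]
    scale; `group_key` optionally stratifies (one output row per group plus
    an "overall" row). A single-case group reports sd 0.00.
    """
    metric_cols = [c for c in per_case.columns if per_case[c].dtype.kind == "f"]

    def summarize(df: pd.DataFrame, label: str) -> dict:
        row = {"group": label, "n": len(df)}
        for c in metric_cols:
            vals = df[c].dropna().to_numpy()
            if vals.size == 0:
                row[f"{c}_mean"], row[f"{c}_sd"] = np.nan, np.nan
                continue
            mean = 100.0 * vals.mean()
            sd = 100.0 * (vals.std(ddof=1) if vals.size > 1 else 0.0)
            row[f"{c}_mean"] = round(float(mean), 2)
            row[f"{c}_sd"] = round(float(sd), 2)
        return row

    rows: List[dict] = []
    if group_key is not None:
        for name, df in per_case.groupby(group_key, sort=True):
            rows.append(summarize(df, str(name)))
    rows.append(summarize(per_case, "overall"))
    return pd.DataFrame(rows)


def format_report(report: pd.DataFrame) -> str:
    """Human-readable `mean ± sd` table mirroring the standard column order."""
    is_cls = any(c in report.columns for c in ("ACC", "ACC_mean"))
    order = CLS_METRICS if is_cls else SEG_METRICS
    out_rows = []
    for _, row in report.iterrows():
        cells = {"group": row["group"], "n": int(row["n"])}
        for c in order:
            mk, sk = f"{c}_mean", f"{c}_sd"
            if mk in row.index and not pd.isna(row[mk]):
                cells[c] = f"{row[mk]:.2f} ± {row[sk]:.2f}"
            elif c in row.index and not pd.isna(row[c]):
                cells[c] = f"{row[c]:.2f}"
        out_rows.append(cells)
    return pd.DataFrame(out_rows).to_string(index=False)
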
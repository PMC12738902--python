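"""Detection and counting quality metrics.

Detection metrics are the usual P/R/F1/AP family:

    P = TP / (TP + FP),  R = TP / (TP + FN),  F1 = 2PR / (P + R)
    AP = area under the precision-recall curve (all-point interpolation with
         the monotone precision envelope), mAP = unweighted mean over classes.

Counting metrics compare a per-video, per-category table of manual counts
y-hat against algorithm counts y:

    RMSE = sqrt(mean((y - y_hat)^2)),  MAE = mean(|y - y_hat|)
    MCA  = 100 * min(y, y_hat) / max(y, y_hat)   (per cell; symmetric)

with per-video RMSE taken over the categories of that video, per-category
MAE/RMSE taken over videos, per-category MCA the mean of the defined
per-video cell MCAs, and the overall average MCA the mean of the per-video
total-count MCAs. A cell with manual = predicted = 0 has no defined MCA and
is excluded from the means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .formats import BoundingBox, TransplantState, iou


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")


def precision(c: ConfusionCounts) -> float | None:
    if c.TP + c.FP == 0:
        return None
    return c.TP / (c.TP + c.FP)


def recall(c: ConfusionCounts) -> float | None:
    if c.TP + c.FN == 0:
        return None
    return c.TP / (c.TP + c.FN)


def f1(c: ConfusionCounts) -> float | None:
    p, r = precision(c), recall(c)
    if p is None or r is None or p + r == 0:
        return None
    return 2 * p * r / (p + r)


def average_precision(
    predictions: Sequence[tuple[int, BoundingBox, float]],
    ground_truth: Sequence[tuple[int, BoundingBox]],
    iou_cut: float = 0.5,
) -> float | None:
    """Single-class AP with greedy confidence-ordered matching.

    ``predictions`` are (image_id, box, confidence); ``ground_truth`` are
    (image_id, box). Each ground-truth box can absorb at most one prediction;
    predictions are visited highest-confidence first and match the
    highest-IoU unmatched ground truth in their image at IoU >= ``iou_cut``.
    Returns ``None`` when there is no ground truth.
    """
    if not ground_truth:
        return None
    order = sorted(range(len(predictions)),
                   key=lambda i: (-predictions[i][2], i))
    gt_by_image: dict[int, list[int]] = {}
    for gi, (img, _) in enumerate(ground_truth):
        gt_by_image.setdefault(img, []).append(gi)
    matched_gt: set[int] = set()
    tp = np.zeros(len(predictions))
    for rank, i in enumerate(order):
        img, box, _ = predictions[i]
        best_iou, best_gi = 0.0, None
        for gi in gt_by_image.get(img, []):
            if gi in matched_gt:
                continue
            v = iou(box, ground_truth[gi][1])
            if v > best_iou:
                best_iou, best_gi = v, gi
        if best_gi is not None and best_iou >= iou_cut:
            matched_gt.add(best_gi)
            tp[rank] = 1.0
    cum_tp = np.cumsum(tp)
    prec = cum_tp / (np.arange(len(predictions)) + 1)
    rec = cum_tp / len(ground_truth)
    # monotone precision envelope, then sum over recall increments
    prec_env = np.maximum.accumulate(prec[::-1])[::-1]
    ap, prev_r = 0.0, 0.0
    for p, r in zip(prec_env, rec):
        ap += p * (r - prev_r)
        prev_r = r
    return float(ap)


def mean_ap(per_class_aps: Iterable[float]) -> float:
    aps = [a for a in per_class_aps]
    if not aps:
        raise ValueError("mean_ap needs at least one class AP")
    return float(np.mean(aps))


def rmse(errors: Sequence[float]) -> float:
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise ValueError("rmse of an empty error vector")
    return float(np.sqrt(np.mean(np.square(e))))


def mae(errors: Sequence[float]) -> float:
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise ValueError("mae of an empty error vector")
    return float(np.mean(np.abs(e)))


def mca(manual: int, predicted: int) -> float | None:
    """Counting accuracy of one cell: 100 * min/max, symmetric; None for 0/0."""
    if manual < 0 or predicted < 0:
        raise ValueError("counts must be non-negative")
    if manual == 0 and predicted == 0:
        return None
    return 100.0 * min(manual, predicted) / max(manual, predicted)


@dataclass
class CountTable:
    """Manual vs predicted counts per video and transplant state."""

    # {video_id: {state: (manual, predicted)}}
    data: dict[str, dict[TransplantState, tuple[int, int]]]

    def __post_init__(self) -> None:
        if not self.data:
            raise ValueError("empty count table")
        for vid, row in self.data.items():
            for state, (m, p) in row.items():
                if m < 0 or p < 0:
                    raise ValueError(f"negative count in video {vid}, {state}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CountTable":
        """Read ``video,cname,manual,predicted`` rows (with header)."""
        df = pd.read_csv(path, dtype={"video": str})
        data: dict[str, dict[TransplantState, tuple[int, int]]] = {}
        for _, row in df.iterrows():
            data.setdefault(str(row["video"]), {})[
                TransplantState.parse(row["cname"])
            ] = (int(row["manual"]), int(row["predicted"]))
        return cls(data)

    def videos(self) -> list[str]:
        return list(self.data)


@dataclass
class EvalReport:
    per_video_rmse: dict[str, float]
    per_video_total_mca: dict[str, float | None]
    per_category_mca: dict[TransplantState, float | None]
    per_category_mae: dict[TransplantState, float]
    per_category_rmse: dict[TransplantState, float]
    overall_average_mca: float
    flags: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for state in TransplantState:
            rows.append({
                "category": str(state),
                "MCA_pct": self.per_category_mca[state],
                "MAE": self.per_category_mae[state],
                "RMSE": self.per_category_rmse[state],
            })
        return pd.DataFrame(rows)


def evaluate_count_table(table: CountTable) -> EvalReport:
    """Full counting evaluation of a manual-vs-predicted count table."""
    states = list(TransplantState)
    per_video_rmse: dict[str, float] = {}
    per_video_total_mca: dict[str, float | None] = {}
    for vid, row in table.data.items():
        errors = [row[s][1] - row[s][0] for s in states if s in row]
        per_video_rmse[vid] = rmse(errors)
        manual_total = sum(row[s][0] for s in states if s in row)
        pred_total = sum(row[s][1] for s in states if s in row)
        per_video_total_mca[vid] = mca(manual_total, pred_total)

    per_category_mca: dict[TransplantState, float | None] = {}
    per_category_mae: dict[TransplantState, float] = {}
    per_category_rmse: dict[TransplantState, float] = {}
    for s in states:
        cells = [table.data[v][s] for v in table.data if s in table.data[v]]
        if not cells:
            per_category_mca[s] = None
            per_category_mae[s] = float("nan")
            per_category_rmse[s] = float("nan")
            continue
        cell_mcas = [mca(m, p) for m, p in cells]
        defined = [x for x in cell_mcas if x is not None]
        per_category_mca[s] = float(np.mean(defined)) if defined else None
        errs = [p - m for m, p in cells]
        per_category_mae[s] = mae(errs)
        per_category_rmse[s] = rmse(errs)

    totals = [x for x in per_video_total_mca.values() if x is not None]
    overall = float(np.mean(totals)) if totals else float("nan")
    return EvalReport(
        per_video_rmse=per_video_rmse,
        per_video_total_mca=per_video_total_mca,
        per_category_mca=per_category_mca,
        per_category_mae=per_category_mae,
        per_category_rmse=per_category_rmse,
        overall_average_mca=overall,
    )


def count_id_switches(
    truth: Sequence, tracks: Sequence, iou_cut: float = 0.5
) -> int:
    """Identity switches of tracker output against ground-truth trajectories.

    Both arguments are sequences of :class:`~cabtrack.formats.AnnotationRecord`.
    Per frame, ground-truth boxes are greedily matched to track boxes at
    IoU >= ``iou_cut`` (best IoU first); a switch is counted whenever the
    track id matched to a ground-truth identity differs from the one matched
    at its previous matched frame.
    """
    frames = sorted({r.frame for r in truth} | {r.frame for r in tracks})
    truth_by_frame: dict[int, list] = {}
    for r in truth:
        truth_by_frame.setdefault(r.frame, []).append(r)
    trk_by_frame: dict[int, list] = {}
    for r in tracks:
        trk_by_frame.setdefault(r.frame, []).append(r)

    last_match: dict[int, int] = {}
    switches = 0
    for f in frames:
        gts = truth_by_frame.get(f, [])
        trs = trk_by_frame.get(f, [])
        pairs = []
        for gi, g in enumerate(gts):
            for ti, t in enumerate(trs):
                v = iou(g.box, t.box)
                if v >= iou_cut:
                    pairs.append((v, gi, ti))
        pairs.sort(key=lambda x: -x[0])
        used_g, used_t = set(), set()
        for v, gi, ti in pairs:
            if gi in used_g or ti in used_t:
                continue
            used_g.add(gi)
            used_t.add(ti)
            gt_id, tr_id = gts[gi].id, trs[ti].id
            if gt_id in last_match and last_match[gt_id] != tr_id:
                switches += 1
            last_match[gt_id] = tr_id
    return switches
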
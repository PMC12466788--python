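"""Evaluation of predicted nuclear segmentation against ground truth.

Predicted nuclei are matched to annotated nuclei one-to-one: a candidate
pair must share the same canonical cell type and overlap with IoU > 0.5;
candidates are accepted greedily by descending IoU (ties break on ids), so
each nucleus is used at most once.  For well-separated instances at this
cutoff a ground-truth nucleus can overlap at most one prediction above 0.5,
which makes the greedy result the optimal assignment.

Alongside the type-constrained matching, a type-agnostic IoU alignment
builds the confusion matrix over canonical classes: aligned pairs count as
(gt class -> predicted class), missed ground truth as (gt class -> none)
and spurious predictions as (none -> predicted class).  Per-class one-vs-all
accuracy, sensitivity, precision and F1 are reported after aggregating the
sparsely represented classes (dead, epithelial, unknown) into "Others".
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Polygon

from .morphometry import DegenerateContourError, _polygon
from .segmentation_io import CellType, NucleusRecord

#: Classes aggregated into "Others" for the per-class metrics.
OTHERS = ("dead", "epithelial", "unknown")
_NONE = "none"


def map_types(label: str, table: Mapping[str, CellType | str]) -> CellType:
    """Case-insensitive exact lookup of a label string; default unknown."""
    value = table.get(str(label).strip().lower())
    if value is None:
        return CellType.UNKNOWN
    return value if isinstance(value, CellType) else CellType(str(value).lower())


@dataclass
class TypeMap:
    """Ground-truth and prediction label tables onto the canonical classes."""

    ground_truth: dict[str, CellType]
    prediction: dict[str, CellType]

    @classmethod
    def from_dict(cls, data: Mapping) -> "TypeMap":
        def norm(table: Mapping) -> dict[str, CellType]:
            return {
                str(k).strip().lower(): CellType(str(v).lower())
                for k, v in table.items()
            }

        return cls(
            ground_truth=norm(data.get("ground_truth", {})),
            prediction=norm(data.get("prediction", {})),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TypeMap":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def default(cls) -> "TypeMap":
        text = (
            importlib.resources.files("nucmorph.data")
            .joinpath("type_map.yaml")
            .read_text()
        )
        return cls.from_dict(yaml.safe_load(text))

    def map_gt(self, label: str) -> CellType:
        return map_types(label, self.ground_truth)

    def map_pred(self, label: str) -> CellType:
        return map_types(label, self.prediction)


def polygon_iou(a, b) -> float:
    """Intersection over union of two simple polygons by exact clipping."""
    pa, pb = _polygon(a), _polygon(b)
    inter = pa.intersection(pb).area
    if inter == 0.0:
        return 0.0
    return float(inter / pa.union(pb).area)


@dataclass
class MatchReport:
    """Result of matching predicted against ground-truth nuclei."""

    matches: list[tuple[int, int, float]]  # (gt_id, pred_id, IoU)
    unmatched_gt: list[int]
    unmatched_pred: list[int]
    confusion: pd.DataFrame  # rows = gt class (+none), cols = pred class (+none)
    n_gt: int
    n_pred: int


def _candidate_pairs(
    gt: Sequence[NucleusRecord],
    pred: Sequence[NucleusRecord],
    iou_cut: float,
) -> list[tuple[float, int, int]]:
    """All (iou, gt index, pred index) pairs above the cutoff."""
    pred_polys = [_polygon(p.contour) for p in pred]
    pred_bounds = [p.bounds for p in pred_polys]
    pairs = []
    for i, g in enumerate(gt):
        gp = _polygon(g.contour)
        gx0, gy0, gx1, gy1 = gp.bounds
        for j, pp in enumerate(pred_polys):
            px0, py0, px1, py1 = pred_bounds[j]
            if px0 > gx1 or gx0 > px1 or py0 > gy1 or gy0 > py1:
                continue
            inter = gp.intersection(pp).area
            if inter == 0.0:
                continue
            iou = inter / gp.union(pp).area
            if iou > iou_cut:
                pairs.append((float(iou), i, j))
    return pairs


def _greedy(pairs: list[tuple[float, int, int]]) -> list[tuple[int, int, float]]:
    """Accept pairs by descending IoU, ids as deterministic tie-break."""
    taken_gt: set[int] = set()
    taken_pred: set[int] = set()
    accepted = []
    for iou, i, j in sorted(pairs, key=lambda t: (-t[0], t[1], t[2])):
        if i in taken_gt or j in taken_pred:
            continue
        taken_gt.add(i)
        taken_pred.add(j)
        accepted.append((i, j, iou))
    return accepted


def match_nuclei(
    gt: Sequence[NucleusRecord],
    pred: Sequence[NucleusRecord],
    iou_cut: float = 0.5,
) -> MatchReport:
    """Match predictions to ground truth and build the confusion matrix.

    Inputs carry canonical cell types already (apply a :class:`TypeMap`
    while reading).  The reported ``matches`` require identical type and
    IoU > ``iou_cut``; the confusion matrix comes from a type-agnostic
    alignment at the same cutoff.
    """
    pairs = _candidate_pairs(gt, pred, iou_cut)
    same_type = [
        (iou, i, j) for iou, i, j in pairs if gt[i].cell_type == pred[j].cell_type
    ]
    strict = _greedy(same_type)
    matched_gt = {i for i, _, _ in strict}
    matched_pred = {j for _, j, _ in strict}

    aligned = _greedy(pairs)
    classes = [c.value for c in CellType]
    confusion = pd.DataFrame(
        0, index=classes + [_NONE], columns=classes + [_NONE], dtype=int
    )
    aligned_gt = set()
    aligned_pred = set()
    for i, j, _ in aligned:
        confusion.loc[gt[i].cell_type.value, pred[j].cell_type.value] += 1
        aligned_gt.add(i)
        aligned_pred.add(j)
    for i, g in enumerate(gt):
        if i not in aligned_gt:
            confusion.loc[g.cell_type.value, _NONE] += 1
    for j, p in enumerate(pred):
        if j not in aligned_pred:
            confusion.loc[_NONE, p.cell_type.value] += 1

    return MatchReport(
        matches=[(gt[i].nucleus_id, pred[j].nucleus_id, iou) for i, j, iou in strict],
        unmatched_gt=[g.nucleus_id for i, g in enumerate(gt) if i not in matched_gt],
        unmatched_pred=[
            p.nucleus_id for j, p in enumerate(pred) if j not in matched_pred
        ],
        confusion=confusion,
        n_gt=len(gt),
        n_pred=len(pred),
    )


def merge_confusions(reports: Sequence[MatchReport]) -> pd.DataFrame:
    """Sum confusion matrices across tiles/ROIs."""
    total = reports[0].confusion.copy()
    for r in reports[1:]:
        total = total.add(r.confusion, fill_value=0).astype(int)
    return total


def _aggregate_others(confusion: pd.DataFrame) -> pd.DataFrame:
    keep = [c for c in confusion.index if c not in OTHERS and c != _NONE]
    order = keep + ["Others", _NONE]
    out = pd.DataFrame(0, index=order, columns=order, dtype=int)
    for r in confusion.index:
        rr = r if r in keep or r == _NONE else "Others"
        for c in confusion.columns:
            cc = c if c in keep or c == _NONE else "Others"
            out.loc[rr, cc] += int(confusion.loc[r, c])
    return out


def classification_metrics(
    confusion: pd.DataFrame, aggregate: bool = True
) -> pd.DataFrame:
    """One-vs-all accuracy, sensitivity, precision and F1 per class.

    Operates on a confusion matrix whose last row/column ``none`` holds
    spurious predictions / missed ground truth.  Classes with no ground
    truth get NaN metrics (flagged undefined) rather than zeros, as does
    precision when a class is never predicted.
    """
    matrix = _aggregate_others(confusion) if aggregate else confusion
    classes = [c for c in matrix.index if c != _NONE]
    total = int(matrix.values.sum())
    rows = []
    for c in classes:
        tp = int(matrix.loc[c, c])
        fn = int(matrix.loc[c].sum()) - tp
        fp = int(matrix[c].sum()) - tp
        tn = total - tp - fn - fp
        support = tp + fn
        sens = tp / support if support > 0 else np.nan
        prec = tp / (tp + fp) if (tp + fp) > 0 else np.nan
        acc = (tp + tn) / total if total > 0 and support > 0 else np.nan
        f1 = (
            2 * prec * sens / (prec + sens)
            if support > 0 and (tp + fp) > 0 and (prec + sens) > 0
            else np.nan
        )
        rows.append(
            {
                "class": c,
                "support": support,
                "accuracy": acc,
                "sensitivity": sens,
                "precision": prec,
                "f1": f1,
            }
        )
    return pd.DataFrame(rows).set_index("class")


def overall_accuracy(confusion: pd.DataFrame) -> float:
    """Fraction of all instances (gt + spurious predictions) on the diagonal."""
    classes = [c for c in confusion.index if c != _NONE]
    diag = sum(int(confusion.loc[c, c]) for c in classes)
    return diag / int(confusion.values.sum())
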
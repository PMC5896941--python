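"""Two-reader consensus ground truth and pixel-level scoring.

Two pathologists independently correct the machine's decision boundaries;
their masks are combined into consensus ground truth in one of two ways:

* **C1** (intersection / logical AND): a pixel enters the ground truth only
  where both readers assign the same label; disagreement pixels are
  excluded from scoring entirely.
* **C2** (union / logical OR): every pixel is labelled; since "union" is
  directional for a two-class labelling, both variants are available — the
  tumor-favouring union (a pixel is tumor if either reader called it tumor)
  and the non-tumor-favouring union.

Predicted masks are scored against the consensus with a 2x2 pixel-count
confusion matrix, from which sensitivity, specificity, PPV, NPV and overall
accuracy are derived; displayed percentages round half-up to one decimal.
Class imbalance (tumor pixels far outnumber non-tumor) can be neutralized
by seeded subsampling of the majority class without replacement, or by
upsampling the minority class with replacement.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

from .formats_io import LABEL_TUMOR, LABEL_NON_TUMOR

__all__ = [
    "ConsensusGT",
    "ConfusionMatrix",
    "MetricsReport",
    "RocPoint",
    "build_consensus",
    "confusion",
    "metrics",
    "balanced_subsample",
    "roc_curve",
    "roc_auc",
    "reader_agreement",
    "percent_display",
]

CONSENSUS_MODES = ("C1", "C2_tumor_favouring", "C2_non_tumor_favouring")


@dataclass
class ConsensusGT:
    """Per-pixel consensus ground truth with an excluded-pixel mask."""

    labels: np.ndarray  # H x W in {1=tumor, 2=non_tumor}; excluded pixels arbitrary
    excluded: np.ndarray  # H x W bool; non-empty only under C1
    mode: str

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        if self.labels.shape != self.excluded.shape:
            raise ValueError("labels and excluded shapes differ")
        if self.mode not in CONSENSUS_MODES:
            raise ValueError(f"mode must be one of {CONSENSUS_MODES}")
        if self.mode != "C1" and self.excluded.any():
            raise ValueError("C2 consensus has no exclusions")

    @property
    def scored(self) -> np.ndarray:
        return ~self.excluded

    @property
    def tumor(self) -> np.ndarray:
        """Boolean actual-tumor map over scored pixels."""
        return (self.labels == LABEL_TUMOR) & self.scored


@dataclass
class ConfusionMatrix:
    """2x2 pixel counts: predicted (rows) x actual (columns)."""

    tp: int  # predicted tumor, actual tumor
    fp: int  # predicted tumor, actual non-tumor
    fn: int  # predicted non-tumor, actual tumor
    tn: int  # predicted non-tumor, actual non-tumor

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer")
            setattr(self, name, int(v))

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn}


def percent_display(value: float | None) -> str | None:
    """Render a proportion as a percentage, half-up to one decimal (e.g. 0.9780 -> '97.8')."""
    if value is None:
        return None
    return str(Decimal(repr(value * 100)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class MetricsReport:
    """Derived pixel metrics; a metric with a zero denominator is ``None``."""

    cm: ConfusionMatrix
    sensitivity: float | None  # actual-tumor column accuracy, tp/(tp+fn)
    specificity: float | None  # actual-non-tumor column accuracy, tn/(fp+tn)
    ppv: float | None  # predicted-tumor row accuracy, tp/(tp+fp)
    npv: float | None  # predicted-non-tumor row accuracy, tn/(fn+tn)
    overall_accuracy: float | None

    def to_dict(self) -> dict:
        out = {"confusion": self.cm.to_dict()}
        for name in ("sensitivity", "specificity", "ppv", "npv", "overall_accuracy"):
            value = getattr(self, name)
            out[name] = value
            out[name + "_percent"] = percent_display(value)
        return out


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Derive sensitivity/specificity/PPV/NPV/overall accuracy from counts.

    A metric whose denominator is zero is reported as undefined (``None``),
    never as 0.
    """

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return MetricsReport(
        cm=cm,
        sensitivity=ratio(cm.tp, cm.tp + cm.fn),
        specificity=ratio(cm.tn, cm.fp + cm.tn),
        ppv=ratio(cm.tp, cm.tp + cm.fp),
        npv=ratio(cm.tn, cm.fn + cm.tn),
        overall_accuracy=ratio(cm.tp + cm.tn, cm.total),
    )


def _reader_labels(reader) -> np.ndarray:
    labels = np.asarray(getattr(reader, "labels", reader))
    if not np.isin(labels, (LABEL_TUMOR, LABEL_NON_TUMOR)).all():
        raise ValueError("reader masks must be fully labelled with {1, 2}")
    return labels


def build_consensus(reader_a, reader_b, mode: str = "C1") -> ConsensusGT:
    """Combine two fully-labelled reader masks into consensus ground truth."""
    a = _reader_labels(reader_a)
    b = _reader_labels(reader_b)
    if a.shape != b.shape:
        raise ValueError("reader masks have different shapes")
    if mode == "C1":
        agree = a == b
        labels = np.where(agree, a, 0).astype(np.uint8)
        return ConsensusGT(labels=labels, excluded=~agree, mode=mode)
    if mode == "C2_tumor_favouring":
        labels = np.where((a == LABEL_TUMOR) | (b == LABEL_TUMOR), LABEL_TUMOR, LABEL_NON_TUMOR)
    elif mode == "C2_non_tumor_favouring":
        labels = np.where(
            (a == LABEL_NON_TUMOR) | (b == LABEL_NON_TUMOR), LABEL_NON_TUMOR, LABEL_TUMOR
        )
    else:
        raise ValueError(f"unknown consensus mode {mode!r}")
    return ConsensusGT(labels=labels.astype(np.uint8), excluded=np.zeros_like(labels, bool), mode=mode)


def confusion(pred_tumor_mask: np.ndarray, gt: ConsensusGT) -> ConfusionMatrix:
    """Pixel-count confusion matrix over the non-excluded pixels."""
    pred = np.asarray(pred_tumor_mask, dtype=bool)
    if pred.shape != gt.labels.shape:
        raise ValueError("prediction and ground-truth shapes differ")
    scored = gt.scored
    actual_tumor = gt.labels == LABEL_TUMOR
    return ConfusionMatrix(
        tp=int((scored & pred & actual_tumor).sum()),
        fp=int((scored & pred & ~actual_tumor).sum()),
        fn=int((scored & ~pred & actual_tumor).sum()),
        tn=int((scored & ~pred & ~actual_tumor).sum()),
    )


def balanced_subsample(
    pred_tumor_mask: np.ndarray,
    gt: ConsensusGT,
    seed: int = 0,
    mode: str = "subsample",
) -> ConfusionMatrix:
    """Confusion matrix on a class-balanced pixel set.

    ``subsample`` (default): pixels of the majority ground-truth class are
    drawn uniformly without replacement down to the minority count.
    ``upsample``: minority-class pixels are drawn with replacement up to
    the majority count.  Either way the balanced matrix has equal
    actual-class totals.  Deterministic per seed.
    """
    pred = np.asarray(pred_tumor_mask, dtype=bool).ravel()
    scored = gt.scored.ravel()
    actual_tumor = (gt.labels == LABEL_TUMOR).ravel()
    tumor_idx = np.flatnonzero(scored & actual_tumor)
    non_idx = np.flatnonzero(scored & ~actual_tumor)
    if len(tumor_idx) == 0 or len(non_idx) == 0:
        raise ValueError("both classes must be present in the ground truth")
    rng = np.random.default_rng(seed)
    if mode == "subsample":
        n = min(len(tumor_idx), len(non_idx))
        if len(tumor_idx) > n:
            tumor_idx = rng.choice(tumor_idx, size=n, replace=False)
        if len(non_idx) > n:
            non_idx = rng.choice(non_idx, size=n, replace=False)
    elif mode == "upsample":
        n = max(len(tumor_idx), len(non_idx))
        if len(tumor_idx) < n:
            tumor_idx = rng.choice(tumor_idx, size=n, replace=True)
        if len(non_idx) < n:
            non_idx = rng.choice(non_idx, size=n, replace=True)
    else:
        raise ValueError("mode must be 'subsample' or 'upsample'")
    return ConfusionMatrix(
        tp=int(pred[tumor_idx].sum()),
        fn=int((~pred[tumor_idx]).sum()),
        fp=int(pred[non_idx].sum()),
        tn=int((~pred[non_idx]).sum()),
    )


@dataclass(frozen=True)
class RocPoint:
    threshold: float
    fpr: float
    tpr: float


def roc_curve(avg_tumor_map: np.ndarray, gt: ConsensusGT, thresholds=None) -> list[RocPoint]:
    """ROC points from the averaged tumor-probability map.

    At each threshold ``t`` a pixel is predicted tumor when
    ``avg_tumor >= t``; TPR is the sensitivity and FPR is one minus the
    specificity over non-excluded pixels.  Includes thresholds 0 (all
    tumor, the (1, 1) corner) and just above 1 (none, the (0, 0) corner)
    by default.
    """
    if thresholds is None:
        thresholds = np.concatenate([[0.0], np.linspace(0.05, 1.0, 20), [1.0 + 1e-9]])
    avg = np.asarray(avg_tumor_map, dtype=float).ravel()
    scored = gt.scored.ravel()
    actual = (gt.labels == LABEL_TUMOR).ravel()
    pos = scored & actual
    neg = scored & ~actual
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    points = []
    for t in thresholds:
        pred = avg >= t
        tpr = float((pred & pos).sum() / n_pos) if n_pos else 0.0
        fpr = float((pred & neg).sum() / n_neg) if n_neg else 0.0
        points.append(RocPoint(threshold=float(t), fpr=fpr, tpr=tpr))
    return points


def roc_auc(points: list[RocPoint]) -> float:
    """Area under the ROC curve by trapezoidal integration over FPR."""
    fpr = np.array([p.fpr for p in points])
    tpr = np.array([p.tpr for p in points])
    order = np.lexsort((tpr, fpr))  # ties in FPR ordered by ascending TPR
    return float(np.trapezoid(tpr[order], fpr[order]))


def reader_agreement(reader_a, reader_b, class_label: int | str) -> float | None:
    """Per-class agreement: |both label class| / |either labels class|.

    Returns ``None`` (undefined) when neither reader labels any pixel with
    the class.
    """
    a = _reader_labels(reader_a)
    b = _reader_labels(reader_b)
    if a.shape != b.shape:
        raise ValueError("reader masks have different shapes")
    if isinstance(class_label, str):
        class_label = {"tumor": LABEL_TUMOR, "non_tumor": LABEL_NON_TUMOR}[class_label]
    in_a = a == class_label
    in_b = b == class_label
    union = int((in_a | in_b).sum())
    if union == 0:
        return None
    return float((in_a & in_b).sum() / union)
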
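"""Frame-level agreement statistics between two label tracks.

All frame-wise statistics are computed over frames labeled in *both* tracks;
unlabeled frames are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve

from .annotations import BEHAVIOR, Ethogram

__all__ = [
    "FrameComparison",
    "frame_metrics",
    "cohen_kappa",
    "roc_metrics",
    "venn_fractions",
    "behavior_density",
]


@dataclass
class FrameComparison:
    """Confusion counts and derived rates between a reference and a prediction."""

    TP: int
    TN: int
    FP: int
    FN: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    kappa: float
    n_compared: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _comparable(a: Ethogram, b: Ethogram) -> tuple[np.ndarray, np.ndarray]:
    if a.n_frames != b.n_frames:
        raise ValueError(f"track lengths differ: {a.n_frames} vs {b.n_frames}")
    both = a.labeled_mask() & b.labeled_mask()
    if not both.any():
        raise ValueError("no mutually labeled frames to compare")
    return (a.labels[both] == BEHAVIOR), (b.labels[both] == BEHAVIOR)


def _kappa(x: np.ndarray, y: np.ndarray) -> float:
    n = x.size
    p_o = float((x == y).mean())
    px, py = x.mean(), y.mean()
    p_e = px * py + (1 - px) * (1 - py)
    if p_e == 1.0:
        # both tracks constant on the same class: perfect (vacuous) agreement
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def frame_metrics(reference: Ethogram, predicted: Ethogram) -> FrameComparison:
    """Confusion counts, accuracy/precision/recall/F1 and kappa.

    F1 (and precision/recall) follow the 0/0 -> 0 convention.
    """
    ref, pred = _comparable(reference, predicted)
    tp = int((ref & pred).sum())
    tn = int((~ref & ~pred).sum())
    fp = int((~ref & pred).sum())
    fn = int((ref & ~pred).sum())
    n = tp + tn + fp + fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return FrameComparison(
        TP=tp,
        TN=tn,
        FP=fp,
        FN=fn,
        accuracy=(tp + tn) / n,
        precision=precision,
        recall=recall,
        f1=f1,
        kappa=_kappa(ref, pred),
        n_compared=n,
    )


def cohen_kappa(a: Ethogram, b: Ethogram) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e) over mutual frames."""
    x, y = _comparable(a, b)
    return _kappa(x, y)


def roc_metrics(scores: np.ndarray, labels: Ethogram, fpr_target: float = 0.05) -> dict:
    """AUROC (trapezoidal) and the best TPR with FPR at most ``fpr_target``.

    Tied scores cross thresholds simultaneously, which is the behavior of the
    underlying ROC construction.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.shape != (labels.n_frames,):
        raise ValueError("scores length must match the label track")
    keep = labels.labeled_mask() & np.isfinite(scores)
    y = (labels.labels[keep] == BEHAVIOR).astype(int)
    s = scores[keep]
    if y.min() == y.max():
        raise ValueError("ROC metrics require both classes in the labels")
    fpr, tpr, thresholds = roc_curve(y, s, drop_intermediate=False)
    auroc = float(np.trapezoid(tpr, fpr))
    ok = fpr <= fpr_target
    tpr_at = float(tpr[ok].max()) if ok.any() else 0.0
    return {
        "auroc": auroc,
        "tpr_at_fpr": tpr_at,
        "fpr_target": fpr_target,
        "curve": {"fpr": fpr, "tpr": tpr, "thresholds": thresholds},
    }


def venn_fractions(a: Ethogram, b: Ethogram) -> dict:
    """Counts/fractions of behavior frames unique to each track and shared.

    Fractions are relative to the union of behavior frames; an empty union
    yields zero fractions.
    """
    if a.n_frames != b.n_frames:
        raise ValueError(f"track lengths differ: {a.n_frames} vs {b.n_frames}")
    ma, mb = a.behavior_mask(), b.behavior_mask()
    only_a = int((ma & ~mb).sum())
    only_b = int((mb & ~ma).sum())
    both = int((ma & mb).sum())
    union = only_a + only_b + both
    frac = (lambda c: c / union if union else 0.0)
    return {
        "only_a": only_a,
        "only_b": only_b,
        "both": both,
        "only_a_fraction": frac(only_a),
        "only_b_fraction": frac(only_b),
        "both_fraction": frac(both),
    }


def behavior_density(e: Ethogram) -> float:
    """Percentage of frames labeled behavior (0-100)."""
    return 100.0 * float(e.behavior_mask().mean())
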
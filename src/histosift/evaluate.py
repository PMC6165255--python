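"""Evaluation protocol: weighted metrics, t-test, majority vote, recognition rate.

Tile-level performance is summarized by the confusion matrix and by
precision, recall and F-measure weighted by class support.  Whole-section
labels are obtained by majority vote over the section's sub-image
predictions, and patient-level performance by the recognition rate

    PatientScore_P = Nrec_P / NP,
    RecognitionRate = mean_P(PatientScore_P),

where ``NP`` is the number of images of patient P and ``Nrec_P`` the
number of those classified correctly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "PatientRecord",
    "confusion_and_weighted_metrics",
    "paired_ttest",
    "majority_vote",
    "recognition_rate",
]


@dataclass
class ConfusionMatrix:
    """Square count matrix; rows are actual labels, columns predicted."""

    classes: list
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


@dataclass
class EvaluationReport:
    confusion: ConfusionMatrix
    per_class: pd.DataFrame  # columns precision/recall/f_measure/support
    weighted_precision: float
    weighted_recall: float
    weighted_f_measure: float
    trials: list[float] = field(default_factory=list)

    @property
    def accuracy(self) -> float:
        c = self.confusion.counts
        return float(np.trace(c) / c.sum())

    def to_text(self) -> str:
        lines = ["per-class metrics:", self.per_class.to_string()]
        lines.append(
            f"weighted precision {self.weighted_precision:.4f}  "
            f"recall {self.weighted_recall:.4f}  "
            f"F-measure {self.weighted_f_measure:.4f}"
        )
        if self.trials:
            t = np.asarray(self.trials)
            lines.append(
                f"trials: n={t.size} F-measure {t.mean():.4f} +/- {t.std(ddof=1):.4f}"
            )
        return "\n".join(lines)


@dataclass(frozen=True)
class PatientRecord:
    """Per-patient image tally used by the recognition rate."""

    patient_id: str
    n_images: int
    n_correct: int

    def __post_init__(self) -> None:
        if self.n_images < 1:
            raise ValueError(f"patient {self.patient_id}: NP must be >= 1")
        if not 0 <= self.n_correct <= self.n_images:
            raise ValueError(
                f"patient {self.patient_id}: Nrec={self.n_correct} outside "
                f"[0, NP={self.n_images}]"
            )


def confusion_and_weighted_metrics(
    actual, predicted, classes: list | None = None
) -> EvaluationReport:
    """Confusion matrix plus per-class and support-weighted P/R/F.

    Per-class precision = TP/(TP+FP), recall = TP/(TP+FN), F the harmonic
    mean; a class never predicted gets precision 0 by convention (logged).
    Weighted versions weight by actual-class support, so weighted recall
    equals overall accuracy.
    """
    actual = list(actual)
    predicted = list(predicted)
    if len(actual) != len(predicted) or len(actual) == 0:
        raise ValueError(
            f"need equal-length nonempty label lists, got {len(actual)} vs {len(predicted)}"
        )
    observed = sorted(set(actual) | set(predicted))
    if classes is None:
        classes = observed
    else:
        extra = set(observed) - set(classes)
        if extra:
            raise ValueError(f"labels {sorted(extra)} outside declared class set {classes}")
        classes = list(classes)
    counts = _sk_confusion(actual, predicted, labels=classes)
    prec, rec, f1, support = precision_recall_fscore_support(
        actual, predicted, labels=classes, average=None, zero_division=0
    )
    never_predicted = [c for c, col in zip(classes, counts.sum(axis=0)) if col == 0]
    if never_predicted:
        logger.warning(
            "class(es) %s never predicted; precision set to 0 by convention",
            never_predicted,
        )
    wprec, wrec, wf1, _ = precision_recall_fscore_support(
        actual, predicted, labels=classes, average="weighted", zero_division=0
    )
    per_class = pd.DataFrame(
        {"precision": prec, "recall": rec, "f_measure": f1, "support": support},
        index=classes,
    )
    return EvaluationReport(
        confusion=ConfusionMatrix(classes=classes, counts=counts),
        per_class=per_class,
        weighted_precision=float(wprec),
        weighted_recall=float(wrec),
        weighted_f_measure=float(wf1),
    )


def paired_ttest(
    fmeasures_a, fmeasures_b, alpha: float = 0.05
) -> tuple[float, float, bool]:
    """Two-sided paired t-test on per-trial F-measures.

    Returns (t, p, significant at alpha).  Zero variance of the paired
    differences is degenerate for the t distribution: p is reported as 0
    when the means differ and 1 when they are identical, with a warning.
    """
    a = np.asarray(fmeasures_a, dtype=float)
    b = np.asarray(fmeasures_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError(
            f"need two equal-length lists with >= 2 trials, got {a.size} vs {b.size}"
        )
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        p = 0.0 if abs(diff.mean()) > 0 else 1.0
        logger.warning("zero variance of paired differences; p set to %g", p)
        t = np.inf * np.sign(diff.mean()) if p == 0.0 else 0.0
        return float(t), float(p), bool(p < alpha)
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p), bool(p < alpha)


def majority_vote(
    sub_image_labels, sub_image_scores=None
) -> tuple[object, int]:
    """Plurality label over a section's sub-image predictions.

    Ties are broken by the larger summed per-class decision score when
    ``sub_image_scores`` (one mapping/array of per-class scores per
    sub-image) is given, then by lexicographic label order (logged).
    Returns (winning label, its vote count).
    """
    labels = list(sub_image_labels)
    if not labels:
        raise ValueError("majority vote needs at least one sub-image label")
    values, counts = np.unique(labels, return_counts=True)
    top = counts.max()
    tied = sorted(values[counts == top])
    if len(tied) == 1:
        return tied[0], int(top)
    if sub_image_scores is not None:
        totals: dict = {}
        for scores in sub_image_scores:
            for cls, v in dict(scores).items():
                totals[cls] = totals.get(cls, 0.0) + float(v)
        best = max(tied, key=lambda c: (totals.get(c, -np.inf), ))
        others = [c for c in tied if c != best]
        logger.info("vote tie among %s broken by decision score -> %r", tied, best)
        if others and all(
            np.isclose(totals.get(best, 0), totals.get(c, 0)) for c in others
        ):
            best = tied[0]
            logger.info("score tie as well; lexicographic order -> %r", best)
        return best, int(top)
    logger.info("vote tie among %s broken lexicographically -> %r", tied, tied[0])
    return tied[0], int(top)


def recognition_rate(records) -> float:
    """Mean over patients of the per-patient fraction of correct images."""
    records = list(records)
    if not records:
        raise ValueError("recognition rate needs at least one patient")
    scores = [r.n_correct / r.n_images for r in records]
    return float(np.mean(scores))
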
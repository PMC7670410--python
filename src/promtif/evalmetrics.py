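"""Class-weighted evaluation metrics and per-class sequence composition.

The sorted-library classes are strongly imbalanced (middle bins hold orders
of magnitude more sequences than the extremes), so headline metrics are
macro-averaged over classes: weighted accuracy is macro recall and weighted
MAE is the unweighted mean of per-class mean absolute errors.  On balanced
data both collapse to their plain counterparts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from .seqdata import ALPHABET, BASE_INDEX

N_CLASSES = 11


def _check(pred, truth):
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.size == 0 or truth.size == 0:
        raise ValueError("empty input")
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    return pred, truth


def weighted_accuracy(pred, truth) -> float:
    """Macro recall: mean over classes present of within-class accuracy."""
    pred, truth = _check(pred, truth)
    accs = [np.mean(pred[truth == c] == c) for c in np.unique(truth)]
    return float(np.mean(accs))


def per_class_mae(pred, truth, n_classes: int = N_CLASSES) -> np.ndarray:
    """Mean |pred - c| per true class c; NaN for classes absent from truth."""
    pred, truth = _check(pred, truth)
    out = np.full(n_classes, np.nan)
    for c in range(n_classes):
        mask = truth == c
        if mask.any():
            out[c] = np.abs(pred[mask] - c).mean()
    return out


def weighted_mae(pred, truth, n_classes: int = N_CLASSES) -> tuple[float, np.ndarray]:
    """Macro MAE (mean of per-class MAEs over classes present) + the vector."""
    pcm = per_class_mae(pred, truth, n_classes)
    present = ~np.isnan(pcm)
    if present.sum() < n_classes:
        warnings.warn("classes absent from truth are skipped in the macro average")
    return float(np.nanmean(pcm)), pcm


def spearman_rank(a, b) -> float:
    """Spearman rank correlation with average-rank tie handling."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size != b.size or a.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant vector: Spearman rho undefined")
    rho, _ = sps.spearmanr(a, b)
    return float(rho)


def roc_auc_binary(scores, labels) -> float:
    """Rank-based AUC: P(positive outscores negative), ties counted half."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("both labels must be present")
    return float(roc_auc_score(labels, scores))


def prediction_distribution(pred, truth, n_classes: int = N_CLASSES) -> np.ndarray:
    """Row-stochastic matrix: row c = distribution of predictions for true c.

    Rows for classes absent from truth are left as NaN rather than
    fabricated.
    """
    pred, truth = _check(pred, truth)
    mat = np.full((n_classes, n_classes), np.nan)
    for c in range(n_classes):
        mask = truth == c
        if mask.any():
            mat[c] = np.bincount(pred[mask].astype(int), minlength=n_classes) / mask.sum()
    return mat


def position_frequency_matrix(sequences) -> np.ndarray:
    """4 x L per-position base frequencies (rows A,C,G,T), columns sum to 1."""
    sequences = list(sequences)
    if not sequences:
        raise ValueError("empty sequence list")
    L = len(sequences[0])
    if any(len(s) != L for s in sequences):
        raise ValueError("length mismatch")
    counts = np.zeros((4, L))
    for s in sequences:
        for j, base in enumerate(s):
            counts[BASE_INDEX[base], j] += 1
    return counts / len(sequences)


def write_pfm(pfm: np.ndarray, path) -> None:
    """Write a PFM in a plain matrix text format (rows labelled A,C,G,T)."""
    with open(path, "w") as fh:
        fh.write("base\t" + "\t".join(str(j) for j in range(pfm.shape[1])) + "\n")
        for i, base in enumerate(ALPHABET):
            fh.write(base + "\t" + "\t".join(f"{v:.6f}" for v in pfm[i]) + "\n")


def gc_content(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def gc_content_correlation(sequences, labels) -> dict:
    """Mean GC per class and the Pearson correlation of class index vs GC.

    A flat GC profile across TIF classes argues against GC content being a
    simple linear determinant of promoter strength.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need >= 2 classes")
    gc = np.array([gc_content(s) for s in sequences])
    gc_by_class = np.array([gc[labels == c].mean() for c in classes])
    if np.ptp(gc_by_class) == 0:
        return {"classes": classes, "gc_by_class": gc_by_class, "r": 0.0, "p_value": 1.0}
    r, p = sps.pearsonr(classes.astype(float), gc_by_class)
    return {"classes": classes, "gc_by_class": gc_by_class, "r": float(r), "p_value": float(p)}


@dataclass
class EvalReport:
    """Test-set performance of one fitted TIF model."""

    weighted_acc: float
    weighted_mae: float
    per_class_mae: np.ndarray
    spearman_rho: float
    prediction_distribution: np.ndarray
    n_samples: int
    roc_auc: float | None = None
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_predictions(cls, pred, truth, n_classes: int = N_CLASSES) -> "EvalReport":
        wmae, pcm = weighted_mae(pred, truth, n_classes)
        return cls(
            weighted_acc=weighted_accuracy(pred, truth),
            weighted_mae=wmae,
            per_class_mae=pcm,
            spearman_rho=spearman_rank(pred, truth),
            prediction_distribution=prediction_distribution(pred, truth, n_classes),
            n_samples=len(np.asarray(pred)),
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"n_samples\t{self.n_samples}\n")
            fh.write(f"weighted_acc\t{self.weighted_acc:.6f}\n")
            fh.write(f"weighted_mae\t{self.weighted_mae:.6f}\n")
            fh.write(f"spearman_rho\t{self.spearman_rho:.6f}\n")
            if self.roc_auc is not None:
                fh.write(f"roc_auc\t{self.roc_auc:.6f}\n")
            for c, v in enumerate(self.per_class_mae):
                fh.write(f"mae_class_{c}\t{v:.6f}\n")
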
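"""Performance metrics for scored, labeled rankings.

All scores are oriented lower-is-better (the aggregation convention); labels
are 1 for experimentally validated interactions, 0 otherwise.  The module
computes:

* the ROC curve with trapezoidal AUC (equal to the Mann-Whitney probability
  that a random positive outscores a random negative, ties half-credited),
* the partial ROC AUC over the high-specificity band (specificity >= 90%
  by default) and the sensitivity at that specificity,
* the precision-recall curve with average-precision AUC,
* the cumulative F-score curve over all rank cutoffs, F at selected top
  fractions of the list, and the mean F over the whole curve.

Tied scores are always swept as a single threshold step, so the order of
tied items never changes ROC or PR metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LabeledRanking",
    "RocCurve",
    "PrCurve",
    "EvalSummary",
    "roc_curve",
    "partial_auc",
    "sensitivity_at_specificity",
    "pr_curve",
    "cumulative_fscore",
    "evaluate",
    "DEFAULT_FRACTIONS",
]

DEFAULT_FRACTIONS = (0.05, 0.10, 0.20, 1.0)


@dataclass
class LabeledRanking:
    """A scored list with binary validation labels (lower score = better)."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.scores.shape != self.labels.shape or self.scores.ndim != 1:
            raise ValueError("scores and labels must be 1-d arrays of equal length")
        if not np.all(np.isin(self.labels, (0, 1))):
            raise ValueError("labels must be 0/1")

    @property
    def prevalence(self) -> float:
        return float(self.labels.mean())

    @classmethod
    def from_frames(cls, predictions: pd.DataFrame, labels: pd.DataFrame) -> "LabeledRanking":
        """Join a scored table (mirna, gene, score) with validated pairs."""
        pairs = set(zip(labels["mirna"], labels["gene"]))
        lab = np.fromiter(
            (int((m, g) in pairs) for m, g in zip(predictions["mirna"], predictions["gene"])),
            dtype=int,
            count=len(predictions),
        )
        return cls(scores=np.asarray(predictions["score"], dtype=float), labels=lab)


@dataclass
class RocCurve:
    specificity: np.ndarray
    sensitivity: np.ndarray
    auc: float
    pauc_90: float
    sens_at_90: float
    spec_min: float = 0.9

    @property
    def fpr(self) -> np.ndarray:
        return 1.0 - self.specificity


@dataclass
class PrCurve:
    recall: np.ndarray
    precision: np.ndarray
    pr_auc: float
    f_curve: np.ndarray
    f_at_fraction: dict[float, float]
    mean_f: float


@dataclass
class EvalSummary:
    auc: float
    pauc_90: float
    sens_at_90: float
    pr_auc: float
    f_at_fraction: dict[float, float]
    mean_f: float
    n: int
    prevalence: float

    def to_dict(self) -> dict:
        d = {
            "auc": self.auc,
            "pauc_90": self.pauc_90,
            "sens_at_90": self.sens_at_90,
            "pr_auc": self.pr_auc,
            "mean_f": self.mean_f,
            "n": self.n,
            "prevalence": self.prevalence,
        }
        for frac, f in self.f_at_fraction.items():
            d[f"f_at_{frac:g}"] = f
        return d


def _as_arrays(scores, labels):
    if isinstance(scores, LabeledRanking):
        return scores.scores, scores.labels
    data = LabeledRanking(scores, labels)  # reuse validation
    return data.scores, data.labels


def _roc_points(scores: np.ndarray, labels: np.ndarray):
    """FPR/TPR at each distinct-score threshold, starting at (0, 0)."""
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires at least one positive and one negative")
    order = np.argsort(scores, kind="mergesort")
    s = scores[order]
    y = labels[order]
    ends = np.r_[np.flatnonzero(np.diff(s) != 0), len(s) - 1]
    tp = np.cumsum(y)[ends]
    fp = (ends + 1) - tp
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    return fpr, tpr


def _band_area(fpr: np.ndarray, tpr: np.ndarray, fpr_max: float) -> float:
    sens_at = np.interp(fpr_max, fpr, tpr)
    mask = fpr <= fpr_max
    x = np.r_[fpr[mask], fpr_max]
    y = np.r_[tpr[mask], sens_at]
    return float(np.trapezoid(y, x))


def roc_curve(scores, labels=None, spec_min: float = 0.9) -> RocCurve:
    """ROC analysis of a lower-is-better scored ranking.

    Thresholds sweep the distinct score values; the AUC is the trapezoidal
    area, which equals the Mann-Whitney probability P(score_pos < score_neg)
    plus half the tie probability.  ``pauc_90`` is the raw (unstandardized)
    area of the curve restricted to specificity in [``spec_min``, 1], with
    linear interpolation at the band boundary, so a perfect classifier
    reaches ``1 - spec_min`` and the chance diagonal ``(1 - spec_min)^2 / 2``.
    """
    if not (0 <= spec_min < 1):
        raise ValueError("spec_min must be in [0, 1)")
    scores, labels = _as_arrays(scores, labels)
    fpr, tpr = _roc_points(scores, labels)
    auc = float(np.trapezoid(tpr, fpr))
    fmax = 1.0 - spec_min
    pauc = _band_area(fpr, tpr, fmax)
    below = tpr[fpr <= fmax]
    sens_at = max(float(np.interp(fmax, fpr, tpr)), float(below.max(initial=0.0)))
    return RocCurve(
        specificity=1.0 - fpr,
        sensitivity=tpr,
        auc=auc,
        pauc_90=pauc,
        sens_at_90=sens_at,
        spec_min=spec_min,
    )


def partial_auc(curve: RocCurve, spec_min: float = 0.9, standardize: bool = False) -> float:
    """Area under the ROC over specificity in [``spec_min``, 1].

    Raw by default (bounded by ``1 - spec_min``); with ``standardize=True``
    the value is mapped onto [0.5, 1] relative to the chance and perfect
    areas of the band (McClish transformation).
    """
    if not (0 <= spec_min < 1):
        raise ValueError("spec_min must be in [0, 1)")
    fmax = 1.0 - spec_min
    raw = _band_area(curve.fpr, curve.sensitivity, fmax)
    if not standardize:
        return raw
    amin, amax = fmax**2 / 2.0, fmax
    return 0.5 * (1.0 + (raw - amin) / (amax - amin))


def sensitivity_at_specificity(curve: RocCurve, spec: float = 0.9) -> float:
    """Sensitivity of the curve at the given specificity (interpolated)."""
    fmax = 1.0 - spec
    below = curve.sensitivity[curve.fpr <= fmax]
    return max(
        float(np.interp(fmax, curve.fpr, curve.sensitivity)),
        float(below.max(initial=0.0)),
    )


def pr_curve(scores, labels=None, fractions=DEFAULT_FRACTIONS) -> PrCurve:
    """Precision-recall analysis of a lower-is-better scored ranking.

    Walking down the ranking, precision(i) = TP(i)/i and recall(i) = TP(i)/P.
    The PR AUC is the average-precision summation sum_i precision(i) *
    delta-recall(i) over distinct-score steps; no linear interpolation is
    applied between PR points.  The cumulative F-score curve and its
    summaries come from :func:`cumulative_fscore`.
    """
    scores, labels = _as_arrays(scores, labels)
    n = len(scores)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("PR analysis requires at least one positive")
    order = np.argsort(scores, kind="mergesort")
    s = scores[order]
    y = labels[order]
    tp = np.cumsum(y)
    ranks = np.arange(1, n + 1)
    precision = tp / ranks
    recall = tp / n_pos

    ends = np.r_[np.flatnonzero(np.diff(s) != 0), n - 1]
    rec_steps = recall[ends]
    prec_steps = precision[ends]
    pr_auc = float(np.sum(prec_steps * np.diff(np.r_[0.0, rec_steps])))

    f = _f_curve(precision, recall, tp)
    f_at = _f_at_fractions(f, fractions)
    return PrCurve(
        recall=rec_steps,
        precision=prec_steps,
        pr_auc=pr_auc,
        f_curve=f,
        f_at_fraction=f_at,
        mean_f=float(f.mean()),
    )


def _f_curve(precision, recall, tp):
    with np.errstate(divide="ignore", invalid="ignore"):
        f = 2 * precision * recall / (precision + recall)
    f[tp == 0] = 0.0  # no true positives yet: F defined as 0
    return f


def _f_at_fractions(f: np.ndarray, fractions) -> dict[float, float]:
    n = len(f)
    out = {}
    for frac in fractions:
        cutoff = max(1, int(round(frac * n)))
        out[float(frac)] = float(f[min(cutoff, n) - 1])
    return out


def cumulative_fscore(scores, labels=None) -> np.ndarray:
    """F-score 2PR/(P+R) at every rank cutoff of the ranking (F=0 while TP=0)."""
    scores, labels = _as_arrays(scores, labels)
    if labels.sum() == 0:
        raise ValueError("F-score requires at least one positive")
    order = np.argsort(scores, kind="mergesort")
    y = labels[order]
    tp = np.cumsum(y)
    ranks = np.arange(1, len(y) + 1)
    return _f_curve(tp / ranks, tp / labels.sum(), tp)


def evaluate(
    scores,
    labels=None,
    fractions=DEFAULT_FRACTIONS,
    spec_min: float = 0.9,
) -> EvalSummary:
    """Bundle ROC, partial-ROC, PR and F-score metrics for one ranking."""
    scores, labels = _as_arrays(scores, labels)
    roc = roc_curve(scores, labels, spec_min=spec_min)
    pr = pr_curve(scores, labels, fractions=fractions)
    return EvalSummary(
        auc=roc.auc,
        pauc_90=roc.pauc_90,
        sens_at_90=roc.sens_at_90,
        pr_auc=pr.pr_auc,
        f_at_fraction=pr.f_at_fraction,
        mean_f=pr.mean_f,
        n=len(scores),
        prevalence=float(labels.mean()),
    )


def plot_curves(roc: RocCurve, pr: PrCurve, prefix: str) -> list[str]:
    """Write ROC, PR and F-curve plots as ``<prefix>_{roc,pr,f}.png``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    fig, ax = plt.subplots()
    ax.plot(1 - roc.specificity, roc.sensitivity)
    ax.plot([0, 1], [0, 1], "--", color="grey")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"ROC (AUC = {roc.auc:.4f})")
    fig.savefig(f"{prefix}_roc.png", dpi=120)
    plt.close(fig)
    written.append(f"{prefix}_roc.png")

    fig, ax = plt.subplots()
    ax.plot(pr.recall, pr.precision)
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.set_title(f"PR (AUC = {pr.pr_auc:.4f})")
    fig.savefig(f"{prefix}_pr.png", dpi=120)
    plt.close(fig)
    written.append(f"{prefix}_pr.png")

    fig, ax = plt.subplots()
    ax.plot(np.arange(1, len(pr.f_curve) + 1), pr.f_curve)
    ax.set_xlabel("rank cutoff")
    ax.set_ylabel("F-score")
    ax.set_title("Cumulative F-score")
    fig.savefig(f"{prefix}_f.png", dpi=120)
    plt.close(fig)
    written.append(f"{prefix}_f.png")
    return written
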
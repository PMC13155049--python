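"""Classification evaluation: confusion counts, headline metrics, ROC/AUC,
and McNemar's paired comparison.

Positive class is malignant (label 1).  Metrics whose denominator is zero
are *absent* from the summary rather than reported as 0.  Percentages are
kept at full precision; round only at presentation time.

McNemar's test compares two classifiers on the same samples through the
discordant counts b (first correct, second wrong) and c (second correct,
first wrong).  The asymptotic chi-square statistic (b-c)^2/(b+c) is
unreliable when b+c is small, so the exact binomial version is the default
for b+c < 25; both are always reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(pred_labels, true_labels) -> ConfusionCounts:
    pred = np.asarray(pred_labels, dtype=int)
    true = np.asarray(true_labels, dtype=int)
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {true.shape}")
    if not (np.isin(pred, (0, 1)).all() and np.isin(true, (0, 1)).all()):
        raise ValueError("labels must be 0 (benign) or 1 (malignant)")
    return ConfusionCounts(
        tp=int(((pred == 1) & (true == 1)).sum()),
        fp=int(((pred == 1) & (true == 0)).sum()),
        tn=int(((pred == 0) & (true == 0)).sum()),
        fn=int(((pred == 0) & (true == 1)).sum()))


def summary_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, recall/sensitivity, specificity and F1 as
    percentages; undefined metrics (zero denominator) are omitted."""
    if c.total == 0:
        raise ValueError("cannot compute metrics on zero samples")
    out = {"accuracy": 100.0 * (c.tp + c.tn) / c.total}
    if c.tp + c.fp > 0:
        out["precision"] = 100.0 * c.tp / (c.tp + c.fp)
    if c.tp + c.fn > 0:
        out["recall"] = 100.0 * c.tp / (c.tp + c.fn)
    if c.tn + c.fp > 0:
        out["specificity"] = 100.0 * c.tn / (c.tn + c.fp)
    if "precision" in out and "recall" in out and out["precision"] + out["recall"] > 0:
        out["f1"] = 2 * out["precision"] * out["recall"] / (out["precision"] + out["recall"])
    return out


@dataclass
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores, true_labels) -> RocCurve:
    """ROC by threshold sweep over the unique scores (equal scores grouped
    into one step) and AUC by the trapezoid rule."""
    scores = np.asarray(scores, dtype=float)
    true = np.asarray(true_labels, dtype=int)
    if len(np.unique(true)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = _sk_roc_curve(true, scores, drop_intermediate=False)
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=float(_sk_auc(fpr, tpr)))


@dataclass
class McNemarResult:
    b: int
    c: int
    chi2: float           # asymptotic statistic (corrected or not)
    p_chi2: float
    p_exact: float        # two-sided exact binomial
    corrected: bool
    method: str           # which p-value `p` reports
    p: float


def mcnemar(b: int, c: int, corrected: bool = False,
            exact: bool | None = None) -> McNemarResult:
    """McNemar's test from discordant counts.

    ``exact=None`` auto-selects the exact binomial p-value when b + c < 25.
    ``corrected`` applies the continuity correction to the chi-square form.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be nonnegative")
    n = b + c
    if n == 0:
        raise ValueError("McNemar's test is undefined with no discordant pairs")
    if corrected:
        chi2 = (abs(b - c) - 1) ** 2 / n
    else:
        chi2 = (b - c) ** 2 / n
    p_chi2 = float(sps.chi2.sf(chi2, df=1))
    p_exact = float(sps.binomtest(b, n, 0.5).pvalue)
    use_exact = (n < 25) if exact is None else exact
    method = "exact-binomial" if use_exact else ("chi2-corrected" if corrected else "chi2")
    return McNemarResult(b=b, c=c, chi2=float(chi2), p_chi2=p_chi2, p_exact=p_exact,
                         corrected=corrected, method=method,
                         p=p_exact if use_exact else p_chi2)


def discordant_counts(pred_a, pred_b, true_labels) -> tuple[int, int]:
    """(b, c): samples where classifier A is correct and B wrong, and vice
    versa — the McNemar contingency off-diagonal."""
    a_ok = np.asarray(pred_a) == np.asarray(true_labels)
    b_ok = np.asarray(pred_b) == np.asarray(true_labels)
    return int((a_ok & ~b_ok).sum()), int((~a_ok & b_ok).sum())
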
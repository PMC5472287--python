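"""ROC curves, AUC with DeLong variance, AUC comparison, threshold metrics.

AUC is the Mann–Whitney U statistic divided by n_case·n_ctrl with ties
counted one half — the probability a random case outscores a random
control. Its variance (and, for two scores on the same subjects, the
covariance) comes from DeLong's placement-value estimator, enabling a
z-test of correlated AUCs; disjoint cohorts are compared with the same
z-statistic at zero covariance. Classification thresholds follow the
"predict positive iff score ≥ t" convention with candidate thresholds at
midpoints between adjacent distinct scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.stats import rankdata


@dataclass
class RocResult:
    """An empirical ROC curve with its DeLong-variance AUC."""

    fpr: np.ndarray = field(repr=False)
    tpr: np.ndarray = field(repr=False)
    thresholds: np.ndarray = field(repr=False)
    auc: float = 0.0
    var_auc: float = 0.0
    n_case: int = 0
    n_ctrl: int = 0

    @property
    def se_auc(self) -> float:
        return float(np.sqrt(self.var_auc))


@dataclass(frozen=True)
class AucComparison:
    """Result of a DeLong z-test between two AUCs."""

    auc_a: float
    auc_b: float
    delta: float
    z: float
    p: float
    paired: bool
    cov: float


@dataclass(frozen=True)
class ConfusionMetrics:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    undefined: tuple[str, ...] = ()


def _placements(case_scores: np.ndarray, ctrl_scores: np.ndarray):
    """DeLong placement values (V10 per case, V01 per control) and AUC."""
    case = np.asarray(case_scores, dtype=float)
    ctrl = np.asarray(ctrl_scores, dtype=float)
    m, n = case.size, ctrl.size
    if m == 0 or n == 0:
        raise ValueError("both classes must be non-empty")
    allr = rankdata(np.concatenate([case, ctrl]))
    v10 = (allr[:m] - rankdata(case)) / n
    v01 = 1.0 - (allr[m:] - rankdata(ctrl)) / m
    auc = float(v10.mean())
    return v10, v01, auc


def auc(case_scores, ctrl_scores) -> RocResult:
    """ROC curve and tie-aware AUC with DeLong variance.

    Candidate thresholds sweep from above the maximum score (nothing
    positive) down through midpoints between adjacent distinct scores to
    below the minimum (everything positive); the trapezoidal area of the
    resulting points equals the U-statistic AUC.
    """
    case = np.asarray(case_scores, dtype=float)
    ctrl = np.asarray(ctrl_scores, dtype=float)
    v10, v01, auc_hat = _placements(case, ctrl)
    m, n = case.size, ctrl.size
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    var = s10 / m + s01 / n

    u = np.unique(np.concatenate([case, ctrl]))
    thresholds = np.concatenate([[u[0] - 1.0], (u[:-1] + u[1:]) / 2.0, [u[-1] + 1.0]])[::-1]
    case_sorted = np.sort(case)
    ctrl_sorted = np.sort(ctrl)
    tpr = (m - np.searchsorted(case_sorted, thresholds, side="left")) / m
    fpr = (n - np.searchsorted(ctrl_sorted, thresholds, side="left")) / n
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc_hat,
                     var_auc=var, n_case=m, n_ctrl=n)


def compare_auc(scores_a, scores_b, labels, paired: bool = True,
                labels_b=None) -> AucComparison:
    """DeLong z-test between the AUCs of two score vectors.

    Paired mode: `scores_a` and `scores_b` are two scores on the *same*
    subjects (`labels` gives case status once); the covariance of the AUCs
    is estimated from shared placement values. Unpaired mode: the scores
    come from disjoint cohorts labelled by `labels` and `labels_b`;
    covariance is zero.
    """
    la = np.asarray(labels).astype(bool)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if paired:
        if labels_b is not None:
            raise ValueError("paired comparison takes a single label vector")
        if a.shape != b.shape or a.shape != la.shape:
            raise ValueError("paired comparison requires aligned score/label vectors")
        v10a, v01a, auc_a = _placements(a[la], a[~la])
        v10b, v01b, auc_b = _placements(b[la], b[~la])
        m, n = int(la.sum()), int((~la).sum())
        cov = 0.0
        if m > 1:
            cov += float(np.cov(v10a, v10b, ddof=1)[0, 1]) / m
        if n > 1:
            cov += float(np.cov(v01a, v01b, ddof=1)[0, 1]) / n
        var_a = (np.var(v10a, ddof=1) / m if m > 1 else 0.0) + \
                (np.var(v01a, ddof=1) / n if n > 1 else 0.0)
        var_b = (np.var(v10b, ddof=1) / m if m > 1 else 0.0) + \
                (np.var(v01b, ddof=1) / n if n > 1 else 0.0)
    else:
        if labels_b is None:
            raise ValueError("unpaired comparison requires labels_b")
        lb = np.asarray(labels_b).astype(bool)
        ra = auc(a[la], a[~la])
        rb = auc(b[lb], b[~lb])
        auc_a, auc_b = ra.auc, rb.auc
        var_a, var_b, cov = ra.var_auc, rb.var_auc, 0.0

    delta = auc_a - auc_b
    var_delta = var_a + var_b - 2.0 * cov
    if var_delta <= 0:
        z = 0.0
        p = 1.0 if delta == 0 else 0.0
    else:
        z = float(delta / np.sqrt(var_delta))
        p = float(2.0 * stats.norm.sf(abs(z)))
    return AucComparison(auc_a=float(auc_a), auc_b=float(auc_b), delta=float(delta),
                         z=z, p=p, paired=paired, cov=float(cov))


def confusion_metrics(scores, labels, threshold: float) -> ConfusionMetrics:
    """Sensitivity/specificity/PPV/NPV/accuracy at ``score >= threshold``.

    Ratios with an empty denominator are reported as NaN and named in
    ``undefined``.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    pred = s >= threshold
    tp = int((pred & y).sum())
    tn = int((~pred & ~y).sum())
    fp = int((pred & ~y).sum())
    fn = int((~pred & y).sum())

    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    return ConfusionMetrics(
        sensitivity=ratio(tp, tp + fn, "sensitivity"),
        specificity=ratio(tn, tn + fp, "specificity"),
        ppv=ratio(tp, tp + fp, "ppv"),
        npv=ratio(tn, tn + fn, "npv"),
        accuracy=ratio(tp + tn, tp + tn + fp + fn, "accuracy"),
        undefined=tuple(undefined),
    )


def youden_threshold(roc: RocResult) -> float:
    """Threshold maximising Youden's J = sensitivity + specificity − 1.

    Ties resolve to the lowest qualifying threshold.
    """
    if roc.thresholds.size == 0:
        raise ValueError("ROC result has no thresholds")
    j = roc.tpr - roc.fpr
    best = np.flatnonzero(j == j.max())
    return float(roc.thresholds[best].min())


def plot_roc(rocs: dict[str, RocResult], ax=None):
    """Overlay ROC curves (one per label) on a matplotlib axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for label, r in rocs.items():
        ax.plot(r.fpr, r.tpr, label=f"{label} (AUC={r.auc:.3f})")
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    return ax
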
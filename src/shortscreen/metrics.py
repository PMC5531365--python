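"""Agreement, association and ROC statistics for binary screening validation.

Everything here works on either a 2x2 :class:`ConfusionTable` (truth in rows,
screen classification in columns) or on raw score/label vectors.  Percent
quantities (sensitivity, specificity, percent agreement) are on the 0-100
scale; kappa, AUC and correlations on their conventional unit scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionTable",
    "RocResult",
    "round_half_away",
    "table_from_counts",
    "sensitivity_specificity",
    "cohens_kappa",
    "pearson_chi2",
    "percent_agreement",
    "roc_analysis",
    "cronbach_alpha",
    "spearman_rho",
    "oneway_anova_eta2",
]


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of printed reports)."""
    scale = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 classification counts: rows = diagnosis truth, columns = screen."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.n == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.fp + self.tn


def table_from_counts(
    n: int, n_pos: int, pos_screen_pos: int, neg_screen_neg: int
) -> ConfusionTable:
    """Reconstruct a 2x2 table from the counts a report typically prints.

    ``n`` persons, ``n_pos`` diagnosed positive, ``pos_screen_pos`` of the
    positives at/above the cut, ``neg_screen_neg`` of the negatives below it.
    """
    tp = pos_screen_pos
    fn = n_pos - tp
    tn = neg_screen_neg
    fp = n - n_pos - tn
    if min(tp, fn, fp, tn) < 0:
        raise ValueError("inconsistent counts produce a negative cell")
    return ConfusionTable(tp=tp, fn=fn, fp=fp, tn=tn)


def sensitivity_specificity(t: ConfusionTable) -> tuple[float, float]:
    """(sensitivity %, specificity %): true positive / true negative rates."""
    if t.n_pos == 0 or t.n_neg == 0:
        raise ValueError("sensitivity/specificity undefined for an empty margin")
    return 100.0 * t.tp / t.n_pos, 100.0 * t.tn / t.n_neg


def cohens_kappa(t: ConfusionTable) -> float:
    """Unweighted Cohen's kappa, (Po - Pe)/(1 - Pe), marginal-product Pe."""
    n = t.n
    po = (t.tp + t.tn) / n
    pe = (t.n_pos * (t.tp + t.fp) + t.n_neg * (t.fn + t.tn)) / (n * n)
    if pe >= 1.0:
        raise ValueError("kappa undefined: degenerate margins (Pe = 1)")
    return (po - pe) / (1.0 - pe)


def pearson_chi2(t: ConfusionTable) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) and its df=1 p-value."""
    r1, r2 = t.n_pos, t.n_neg
    c1, c2 = t.tp + t.fp, t.fn + t.tn
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("chi-square undefined with a zero margin")
    chi2 = t.n * (t.tp * t.tn - t.fn * t.fp) ** 2 / (r1 * r2 * c1 * c2)
    return chi2, float(stats.chi2.sf(chi2, df=1))


def percent_agreement(t_or_pair) -> float:
    """Percent agreement: 100*(tp+tn)/n, or between two paired 0/1 vectors."""
    if isinstance(t_or_pair, ConfusionTable):
        t = t_or_pair
        return 100.0 * (t.tp + t.tn) / t.n
    a, b = (np.asarray(v) for v in t_or_pair)
    if a.size == 0 or a.shape != b.shape:
        raise ValueError("need two equal-length non-empty classifications")
    return 100.0 * float(np.mean(a == b))


@dataclass
class RocResult:
    """Empirical ROC over integer cut scores (positive = score >= cut)."""

    cuts: np.ndarray
    se: np.ndarray  # percent, per cut
    sp: np.ndarray  # percent, per cut
    auc: float
    auc_ci: tuple[float, float]
    optimal_cut: float
    youden_j: float

    def at_cut(self, cut: float) -> tuple[float, float]:
        idx = int(np.argwhere(self.cuts == cut)[0, 0])
        return float(self.se[idx]), float(self.sp[idx])


def _hanley_mcneil_ci(auc: float, n_pos: int, n_neg: int) -> tuple[float, float]:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2) + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    half = 1.959963984540054 * math.sqrt(max(var, 0.0))
    return max(0.0, auc - half), min(1.0, auc + half)


def roc_analysis(scores, labels) -> RocResult:
    """Empirical ROC analysis of a score against a binary diagnosis.

    Candidate cuts are all distinct observed scores plus a sentinel above the
    maximum (at which nobody screens positive); screen-positive means
    ``score >= cut``.  AUC is the trapezoidal area of the empirical curve
    (equal to the two-sample rank statistic with ties counted 1/2); the 95%
    CI uses the Hanley-McNeil variance.  The optimal cut maximizes Youden's
    J = se + sp - 100, ties resolved to the lowest cut.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length vectors")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")

    uniq = np.unique(scores)
    cuts = np.concatenate([uniq, [uniq[-1] + 1.0]])
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    se = np.array([100.0 * np.mean(pos >= c) for c in cuts])
    sp = np.array([100.0 * np.mean(neg < c) for c in cuts])

    # trapezoid over the empirical (FPR, TPR) staircase
    fpr = 1.0 - sp / 100.0
    tpr = se / 100.0
    order = np.lexsort((tpr, fpr))  # ties in FPR traversed upward in TPR
    auc = float(np.trapezoid(tpr[order], fpr[order]))

    j = se + sp - 100.0
    best = int(np.flatnonzero(j == j.max())[0])  # lowest cut on ties
    return RocResult(
        cuts=cuts,
        se=se,
        sp=sp,
        auc=auc,
        auc_ci=_hanley_mcneil_ci(auc, n_pos, n_neg),
        optimal_cut=float(cuts[best]),
        youden_j=float(j[best]),
    )


def cronbach_alpha(items) -> float:
    """Cronbach's alpha of a persons x items score matrix (complete rows only).

    alpha = k/(k-1) * (1 - sum(item variances)/variance(total)), with
    unbiased (n-1) variances; rows with any missing value are dropped first.
    """
    x = np.asarray(items, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 items")
    x = x[~np.isnan(x).any(axis=1)]
    if x.shape[0] < 2:
        raise ValueError("need at least 2 complete rows")
    k = x.shape[1]
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("alpha undefined: zero total-score variance")
    return k / (k - 1.0) * (1.0 - x.var(axis=0, ddof=1).sum() / total_var)


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (mid-ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("spearman undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


def oneway_anova_eta2(values, groups):
    """One-way ANOVA with eta-squared effect size and group descriptives.

    Returns ``(F, (df_between, df_within), eta2, descriptives)`` where
    ``descriptives`` maps group label -> (n, mean, sd).  eta2 = SSB/SST.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = [g for g in dict.fromkeys(groups.tolist())]
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    grand = values.mean()
    sst = float(((values - grand) ** 2).sum())
    if sst == 0:
        raise ValueError("F undefined: all values identical")
    ssb = 0.0
    desc = {}
    for g in labels:
        v = values[groups == g]
        ssb += v.size * (v.mean() - grand) ** 2
        desc[g] = (int(v.size), float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else float("nan"))
    ssw = sst - ssb
    df_b = len(labels) - 1
    df_w = values.size - len(labels)
    if df_w <= 0:
        raise ValueError("no within-group degrees of freedom")
    f = (ssb / df_b) / (ssw / df_w) if ssw > 0 else float("inf")
    return float(f), (df_b, df_w), float(ssb / sst), desc
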
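"""Clinical model-comparison statistics.

The evaluation battery used to compare risk-score vectors on a shared test
set: AUC with a DeLong confidence interval, DeLong's paired test for two
correlated ROC curves, the category-free (continuous) net reclassification
improvement (NRI), the integrated discrimination improvement (IDI),
Benjamini-Hochberg FDR adjustment, Wilson-score confidence intervals for the
thresholded confusion metrics, decision-curve net benefit, and stratified
K-fold cross-validation.

All functions operate on plain score/label vectors and are agnostic to how
the scores were produced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ScoreSet", "MetricReport", "PairedComparison", "NetBenefitCurve",
    "auc_delong", "delong_paired", "continuous_nri", "idi", "bh_fdr",
    "wilson_ci", "confusion_report", "report_from_counts", "compare_scores",
    "decision_curve", "kfold_cv", "youden_threshold", "proportion",
]


@dataclass
class ScoreSet:
    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.scores.shape != self.labels.shape:
            raise ValueError("scores and labels must have equal length")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0/1")


@dataclass
class ProportionCI:
    value: float
    numerator: int
    denominator: int
    lo: float
    hi: float


@dataclass
class MetricReport:
    auc: float | None
    auc_ci: tuple[float, float] | None
    threshold: float
    acc: ProportionCI
    sens: ProportionCI
    spec: ProportionCI
    ppv: ProportionCI | None     # absent when no positive predictions
    npv: ProportionCI | None
    tp: int
    fp: int
    tn: int
    fn: int


@dataclass
class PairedComparison:
    delong_z: float
    delong_p: float
    nri: float
    nri_z: float
    nri_p: float
    idi_value: float
    idi_z: float
    idi_p: float
    delong_p_fdr: float = np.nan
    nri_p_fdr: float = np.nan
    idi_p_fdr: float = np.nan


@dataclass
class NetBenefitCurve:
    thresholds: np.ndarray
    model: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray


# -- DeLong machinery ------------------------------------------------------

def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-case and per-control placement values (ties counted 1/2)."""
    x = scores[labels == 1]
    y = scores[labels == 0]
    m, n = len(x), len(y)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    # midrank formulation
    all_s = np.concatenate([x, y])
    r_all = stats.rankdata(all_s)
    r_x = stats.rankdata(x)
    r_y = stats.rankdata(y)
    v10 = (r_all[:m] - r_x) / n          # P(score_case > random control)
    v01 = 1.0 - (r_all[m:] - r_y) / m
    auc = v10.mean()
    return v10, v01, auc


def auc_delong(ss: ScoreSet, alpha: float = 0.05) -> tuple[float, float, tuple[float, float]]:
    """AUC (Mann-Whitney, ties = 1/2) with DeLong variance and normal CI."""
    v10, v01, auc = _placements(ss.scores, ss.labels)
    m, n = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    z = stats.norm.ppf(1 - alpha / 2)
    se = np.sqrt(var)
    ci = (max(auc - z * se, 0.0), min(auc + z * se, 1.0))
    return float(auc), float(var), ci


def delong_paired(s1, s2, labels) -> tuple[float, float]:
    """DeLong's test for two correlated AUCs on the same labels."""
    s1 = np.asarray(s1, dtype=np.float64)
    s2 = np.asarray(s2, dtype=np.float64)
    labels = np.asarray(labels)
    v10_1, v01_1, a1 = _placements(s1, labels)
    v10_2, v01_2, a2 = _placements(s2, labels)
    m, n = len(v10_1), len(v01_1)
    if m > 1:
        s10 = np.cov(np.stack([v10_1, v10_2]), ddof=1)
    else:
        s10 = np.zeros((2, 2))
    if n > 1:
        s01 = np.cov(np.stack([v01_1, v01_2]), ddof=1)
    else:
        s01 = np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + \
          (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = a1 - a2
    if var <= 0:
        if abs(diff) < 1e-12:
            return 0.0, 1.0
        raise ValueError("zero variance with unequal AUCs")
    z = diff / np.sqrt(var)
    return float(z), float(2 * stats.norm.sf(abs(z)))


# -- reclassification statistics ------------------------------------------

def _check_probs(p_old, p_new, labels):
    p_old = np.asarray(p_old, dtype=np.float64)
    p_new = np.asarray(p_new, dtype=np.float64)
    labels = np.asarray(labels)
    if ((p_old < 0) | (p_old > 1) | (p_new < 0) | (p_new > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    ev = labels == 1
    if ev.all() or (~ev).all():
        raise ValueError("both events and nonevents required")
    return p_old, p_new, ev


def continuous_nri(p_old, p_new, labels) -> tuple[float, float, float]:
    """Category-free NRI; ties count neither up nor down."""
    p_old, p_new, ev = _check_probs(p_old, p_new, labels)
    up = p_new > p_old
    down = p_new < p_old
    pe_up, pe_down = up[ev].mean(), down[ev].mean()
    pn_up, pn_down = up[~ev].mean(), down[~ev].mean()
    nri = (pe_up - pe_down) + (pn_down - pn_up)
    ne, nn = int(ev.sum()), int((~ev).sum())
    var = (pe_up + pe_down - (pe_up - pe_down) ** 2) / ne + \
          (pn_up + pn_down - (pn_down - pn_up) ** 2) / nn
    if var <= 0:
        z = 0.0 if abs(nri) < 1e-12 else np.inf * np.sign(nri)
    else:
        z = nri / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else 0.0
    return float(nri), float(z), float(p)


def idi(p_old, p_new, labels) -> tuple[float, float, float]:
    """Integrated discrimination improvement with paired-difference SE."""
    p_old, p_new, ev = _check_probs(p_old, p_new, labels)
    d = p_new - p_old
    value = d[ev].mean() - d[~ev].mean()
    ne, nn = int(ev.sum()), int((~ev).sum())
    var = (np.var(d[ev], ddof=1) / ne if ne > 1 else 0.0) + \
          (np.var(d[~ev], ddof=1) / nn if nn > 1 else 0.0)
    if var <= 0:
        z = 0.0 if abs(value) < 1e-12 else np.inf * np.sign(value)
    else:
        z = value / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else 0.0
    return float(value), float(z), float(p)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(pvals, dtype=np.float64)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_scores(s_ref, s_other, labels) -> PairedComparison:
    """Full head-to-head comparison of two score vectors (ref vs other):
    DeLong z/p, continuous NRI, IDI, with BH-FDR over the three p-values."""
    dz, dp = delong_paired(s_ref, s_other, labels)
    nri, nz, np_ = continuous_nri(s_other, s_ref, labels)
    iv, iz, ip = idi(s_other, s_ref, labels)
    fdr = bh_fdr([dp, np_, ip])
    return PairedComparison(dz, dp, nri, nz, np_, iv, iz, ip,
                            delong_p_fdr=float(fdr[0]), nri_p_fdr=float(fdr[1]),
                            idi_p_fdr=float(fdr[2]))


# -- thresholded confusion metrics ----------------------------------------

def wilson_ci(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score interval without continuity correction."""
    if n < 1 or not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n and n >= 1")
    lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
    lo = 0.0 if k == 0 else float(lo)       # boundary cases are exact
    hi = 1.0 if k == n else float(hi)
    return lo, hi


def proportion(k: int, n: int, alpha: float = 0.05) -> ProportionCI:
    """A k/n proportion with its Wilson confidence interval."""
    lo, hi = wilson_ci(k, n, alpha)
    return ProportionCI(k / n, k, n, lo, hi)


def _prop(k: int, n: int, alpha: float) -> ProportionCI | None:
    return None if n == 0 else proportion(k, n, alpha)


def report_from_counts(tp: int, fp: int, tn: int, fn: int,
                       threshold: float = 0.5, alpha: float = 0.05,
                       auc: float | None = None,
                       auc_ci: tuple[float, float] | None = None) -> MetricReport:
    n = tp + fp + tn + fn
    return MetricReport(
        auc=auc, auc_ci=auc_ci, threshold=threshold,
        acc=_prop(tp + tn, n, alpha),
        sens=_prop(tp, tp + fn, alpha),
        spec=_prop(tn, tn + fp, alpha),
        ppv=_prop(tp, tp + fp, alpha),
        npv=_prop(tn, tn + fn, alpha),
        tp=tp, fp=fp, tn=tn, fn=fn,
    )


def confusion_report(ss: ScoreSet, threshold: float, alpha: float = 0.05) -> MetricReport:
    """Threshold the scores (positive iff score >= threshold) and report all
    confusion metrics with Wilson CIs; PPV/NPV are absent when undefined."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    pred = ss.scores >= threshold
    y = ss.labels == 1
    tp = int((pred & y).sum())
    fp = int((pred & ~y).sum())
    tn = int((~pred & ~y).sum())
    fn = int((~pred & y).sum())
    if y.any() and (~y).any():
        auc, _, ci = auc_delong(ss, alpha)
    else:
        auc, ci = None, None
    return report_from_counts(tp, fp, tn, fn, threshold, alpha, auc=auc, auc_ci=ci)


def youden_threshold(ss: ScoreSet) -> float:
    """Threshold maximizing sensitivity + specificity - 1 on these scores.

    Candidate cuts are midpoints between adjacent distinct scores; ties break
    toward the lower threshold."""
    order = np.argsort(ss.scores, kind="stable")
    s, y = ss.scores[order], ss.labels[order]
    distinct = np.unique(s)
    if len(distinct) == 1:
        return float(distinct[0])
    cuts = (distinct[:-1] + distinct[1:]) / 2
    n_pos, n_neg = (ss.labels == 1).sum(), (ss.labels == 0).sum()
    if n_pos == 0 or n_neg == 0:        # degenerate: no trade-off to optimize
        return float(np.median(cuts))
    best_t, best_j = cuts[0], -np.inf
    for t in cuts:
        pred = s >= t
        sens = (pred & (y == 1)).sum() / n_pos
        spec = (~pred & (y == 0)).sum() / n_neg
        j = sens + spec - 1
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return float(best_t)


# -- decision curves -------------------------------------------------------

def decision_curve(ss: ScoreSet, grid) -> NetBenefitCurve:
    """Net benefit NB(t) = TP/n - FP/n * t/(1-t), against treat-all/none."""
    t = np.asarray(grid, dtype=np.float64)
    if ((t <= 0) | (t >= 1)).any():
        raise ValueError("threshold grid must lie strictly inside (0, 1)")
    n = len(ss.labels)
    pi = (ss.labels == 1).mean()
    odds = t / (1 - t)
    nb = np.empty_like(t)
    for i, ti in enumerate(t):
        pred = ss.scores >= ti
        tp = (pred & (ss.labels == 1)).sum()
        fp = (pred & (ss.labels == 0)).sum()
        nb[i] = tp / n - fp / n * odds[i]
    return NetBenefitCurve(thresholds=t, model=nb,
                           treat_all=pi - (1 - pi) * odds,
                           treat_none=np.zeros_like(t))


# -- cross-validation ------------------------------------------------------

def kfold_cv(X, y, pipeline, k: int = 5, seed: int = 0) -> tuple[float, float, np.ndarray]:
    """Stratified K-fold; ``pipeline(X_tr, y_tr, X_te) -> scores``.

    Returns (mean AUC, std of fold AUCs, per-fold AUCs).
    """
    y = np.asarray(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = np.bincount(y, minlength=2)
    if (counts < k).any():
        raise ValueError("each class needs at least k members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(np.zeros(len(y)), y):
        scores = np.asarray(pipeline(X[tr], y[tr], X[te]), dtype=np.float64)
        auc, _, _ = auc_delong(ScoreSet(scores, y[te]))
        aucs.append(auc)
    aucs = np.array(aucs)
    return float(aucs.mean()), float(aucs.std(ddof=1)), aucs
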
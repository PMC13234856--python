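"""Discrimination, calibration and clinical-utility metrics for binary risk models.

AUC and its variance follow DeLong's nonparametric placement-value construction,
which also yields the paired test for correlated ROC curves. Calibration is
assessed with equal-count reliability bins and the Hosmer-Lemeshow C statistic
on deciles of predicted risk. Decision-curve analysis reports the net benefit

    NB(p_t) = TP/n - FP/n * p_t / (1 - p_t)

against the treat-all and treat-none policies over a grid of threshold
probabilities p_t. Confusion metrics use a fixed classification threshold
(default 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "RocResult",
    "auc",
    "delong_test",
    "hosmer_lemeshow",
    "decision_curve",
    "confusion_metrics",
    "calibration_curve",
    "evaluate_models",
]


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if not np.all(np.isin(uniq, [0, 1])):
        raise ValueError(f"labels must be binary 0/1, got values {uniq}")
    if uniq.size < 2:
        raise ValueError("both classes must be present")
    return labels.astype(int)


def _placements(scores: np.ndarray, labels: np.ndarray):
    """Mid-rank placement values V10 (per case) and V01 (per control).

    V10[i] = fraction of controls scored below case i (ties count 1/2);
    their mean is the AUC. These are the structural components of DeLong's
    variance estimator.
    """
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    order = np.argsort(neg, kind="mergesort")
    sneg = neg[order]
    # for each case: (#controls <) + 0.5 * (#controls ==)
    lo = np.searchsorted(sneg, pos, side="left")
    hi = np.searchsorted(sneg, pos, side="right")
    v10 = (lo + 0.5 * (hi - lo)) / n
    spos = np.sort(pos)
    lo = np.searchsorted(spos, neg, side="left")
    hi = np.searchsorted(spos, neg, side="right")
    v01 = ((m - hi) + 0.5 * (hi - lo)) / m
    return v10, v01


@dataclass
class RocResult:
    """ROC summary: AUC, DeLong variance, normal-approximation 95% CI, curve points."""

    auc: float
    variance: float
    ci_low: float
    ci_high: float
    fpr: np.ndarray = field(repr=False)
    tpr: np.ndarray = field(repr=False)
    thresholds: np.ndarray = field(repr=False)


def auc(scores, labels, alpha: float = 0.05) -> RocResult:
    """AUC as the normalized Mann-Whitney statistic with DeLong variance.

    Ties between a case and a control count one half. The CI is
    AUC +/- z * sqrt(var), clipped to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    v10, v01 = _placements(scores, labels)
    a = v10.mean()
    m, n = v10.size, v01.size
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    # ROC curve points at every distinct score threshold
    order = np.argsort(-scores, kind="mergesort")
    ls = labels[order]
    ss = scores[order]
    distinct = np.r_[np.diff(ss) != 0, True]
    tps = np.cumsum(ls)[distinct]
    fps = np.cumsum(1 - ls)[distinct]
    tpr = np.r_[0.0, tps / m]
    fpr = np.r_[0.0, fps / n]
    thresholds = np.r_[np.inf, ss[distinct]]
    return RocResult(
        auc=float(a),
        variance=float(var),
        ci_low=float(max(0.0, a - half)),
        ci_high=float(min(1.0, a + half)),
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
    )


def delong_test(scores_a, scores_b, labels):
    """DeLong's paired test for the difference of two correlated AUCs.

    Both score vectors must be predictions for the same samples. Returns
    (z, two-sided p). Zero variance of the difference (e.g. identical
    scores) yields z = 0, p = 1 with a flag.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = _check_binary(labels)
    if scores_a.shape != scores_b.shape or scores_a.shape[0] != labels.shape[0]:
        raise ValueError("paired scores must have identical shape matching labels")
    va10, va01 = _placements(scores_a, labels)
    vb10, vb01 = _placements(scores_b, labels)
    auc_a, auc_b = va10.mean(), vb10.mean()
    m, n = va10.size, va01.size
    s10 = np.cov(np.vstack([va10, vb10]), ddof=1)
    s01 = np.cov(np.vstack([va01, vb01]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    delta = auc_a - auc_b
    if var_diff <= 0:
        return {"z": 0.0, "p": 1.0, "delta_auc": float(delta), "degenerate": True}
    z = delta / np.sqrt(var_diff)
    p = 2 * stats.norm.sf(abs(z))
    return {"z": float(z), "p": float(p), "delta_auc": float(delta), "degenerate": False}


def hosmer_lemeshow(probs, labels, g: int = 10):
    """Hosmer-Lemeshow C statistic on deciles of predicted risk.

    Groups are equal-count bins of sorted predicted probabilities (ties kept
    in one bin, so fewer than g groups can result); empty bins are merged
    into their neighbor. statistic = sum (O - E)^2 / (E (1 - E/n_g)),
    df = n_groups - 2.
    """
    probs = np.asarray(probs, dtype=float)
    labels = _check_binary(labels)
    n = probs.size
    if n < g:
        raise ValueError(f"need at least g={g} samples, got {n}")
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    qs = np.quantile(probs, np.linspace(0, 1, g + 1)[1:-1])
    edges = np.unique(qs)
    group = np.searchsorted(edges, probs, side="right")
    stat = 0.0
    ngroups = 0
    for gi in np.unique(group):
        sel = group == gi
        ng = sel.sum()
        obs = labels[sel].sum()
        exp = probs[sel].sum()
        denom = exp * (1 - exp / ng)
        ngroups += 1
        if denom <= 0:
            # degenerate bin (all-0 or all-1 expected): contributes only if O != E
            if not np.isclose(obs, exp):
                stat += np.inf
            continue
        stat += (obs - exp) ** 2 / denom
    df = max(ngroups - 2, 1)
    p = float(stats.chi2.sf(stat, df)) if np.isfinite(stat) else 0.0
    return {"statistic": float(stat), "df": int(df), "p": p, "n_groups": int(ngroups)}


def decision_curve(probs, labels, thresholds=None):
    """Net-benefit table for the model plus treat-all / treat-none references."""
    probs = np.asarray(probs, dtype=float)
    labels = _check_binary(labels)
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie in (0, 1)")
    n = labels.size
    prev = labels.mean()
    rows = []
    for pt in thresholds:
        pred = probs >= pt
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        w = pt / (1 - pt)
        nb = tp / n - fp / n * w
        nb_all = prev - (1 - prev) * w
        rows.append((float(pt), float(nb), float(nb_all), 0.0))
    return {
        "threshold": np.array([r[0] for r in rows]),
        "net_benefit": np.array([r[1] for r in rows]),
        "treat_all": np.array([r[2] for r in rows]),
        "treat_none": np.array([r[3] for r in rows]),
    }


def confusion_metrics(probs, labels, threshold: float = 0.5):
    """Accuracy, sensitivity, specificity, precision, PPV, NPV at a fixed cutoff.

    Undefined ratios (zero denominators) are reported as None rather than NaN.
    PPV is the same quantity as precision; both keys are emitted.
    """
    probs = np.asarray(probs, dtype=float)
    labels = _check_binary(labels)
    pred = (probs >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    n = tp + tn + fp + fn

    def ratio(num, den):
        return num / den if den > 0 else None

    precision = ratio(tp, tp + fp)
    return {
        "tp": tp,
        "tn": tn,
        "fp": fp,
        "fn": fn,
        "accuracy": (tp + tn) / n,
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "precision": precision,
        "ppv": precision,
        "npv": ratio(tn, tn + fn),
    }


def calibration_curve(probs, labels, bins: int = 10):
    """Reliability points: (mean predicted, observed fraction) in equal-count bins."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels).astype(int)
    if probs.size < bins:
        raise ValueError("need at least as many samples as bins")
    order = np.argsort(probs, kind="mergesort")
    splits = np.array_split(order, bins)
    mean_pred, obs_frac, counts = [], [], []
    for idx in splits:
        if idx.size == 0:
            continue
        mean_pred.append(probs[idx].mean())
        obs_frac.append(labels[idx].mean())
        counts.append(idx.size)
    return {
        "mean_predicted": np.array(mean_pred),
        "observed_fraction": np.array(obs_frac),
        "count": np.array(counts),
    }


def evaluate_models(predictions: dict, labels, threshold: float = 0.5):
    """Full evaluation report for a dict of model_name -> predicted probabilities.

    Returns per-model ROC/confusion/calibration/HL/DCA and the pairwise
    DeLong comparisons, all computed on the same label vector.
    """
    labels = np.asarray(labels).astype(int)
    report = {"models": {}, "delong": {}}
    for name, probs in predictions.items():
        roc = auc(probs, labels)
        report["models"][name] = {
            "roc": roc,
            "confusion": confusion_metrics(probs, labels, threshold),
            "hosmer_lemeshow": hosmer_lemeshow(probs, labels)
            if len(labels) >= 10
            else None,
            "calibration": calibration_curve(probs, labels, bins=min(10, len(labels)))
            if len(labels) >= 2
            else None,
            "decision_curve": decision_curve(probs, labels),
        }
    names = list(predictions)
    for i, a_name in enumerate(names):
        for b_name in names[i + 1 :]:
            report["delong"][f"{a_name}_vs_{b_name}"] = delong_test(
                predictions[a_name], predictions[b_name], labels
            )
    return report
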
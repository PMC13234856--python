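"""Five-stage feature-selection cascade, fit on the training split only.

Stages (applied per feature pool - conventional, habitat, fusion):

1. Inter-rater reproducibility: ICC(2,1) (two-way random effects, absolute
   agreement, single rater) between feature tables extracted from the two
   raters' masks; keep ICC >= 0.90.
2. z-score standardization (training mean/SD).
3. Univariate filter: Shapiro-Wilk normality in both classes gates the
   choice between Welch's t-test and the Mann-Whitney U test; keep p < 0.05.
   No multiple-testing correction is applied at this stage.
4. Spearman redundancy pruning (|rho| > 0.90), greedy in ascending
   univariate-p order so the most outcome-relevant member of each
   correlated block survives.
5. mRMR (FCQ variant: F-statistic relevance / mean |Pearson| redundancy,
   greedy, deterministic) down to k features, then L1-penalized logistic
   regression with 10-fold cross-validated penalty (minimum mean binomial
   deviance); survivors are the nonzero coefficients.

Stage outputs are nested and every statistic is computed from training rows
alone; passing test-split rows raises.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold


@dataclass
class SelectionConfig:
    icc_threshold: float = 0.90
    p_threshold: float = 0.05
    shapiro_alpha: float = 0.05
    spearman_cutoff: float = 0.90
    mrmr_k: int = 30
    lasso_folds: int = 10
    n_lambdas: int = 40
    seed: int = 0


@dataclass
class SelectionReport:
    pool: str
    stages: dict = field(default_factory=dict)  # stage name -> surviving features
    statistics: pd.DataFrame | None = None
    scaler: dict = field(default_factory=dict)
    lasso_path: dict = field(default_factory=dict)

    @property
    def selected(self) -> list:
        return self.stages.get("lasso", [])


def icc_2_1(ratings1, ratings2):
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    Accepts per-subject value vectors (or matrices with features in
    columns) from the two raters; returns a float (or per-feature array)
    in [-1, 1]. Zero between-subject variance returns 0 (flagged
    convention).
    """
    a = np.asarray(ratings1, dtype=float)
    b = np.asarray(ratings2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("rater matrices must have identical shape")
    scalar = a.ndim == 1
    if scalar:
        a, b = a[:, None], b[:, None]
    n = a.shape[0]
    if n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    k = 2
    data = np.stack([a, b], axis=1)  # (n, k, p)
    grand = data.mean(axis=(0, 1))
    subj_mean = data.mean(axis=1)  # (n, p)
    rater_mean = data.mean(axis=0)  # (k, p)
    ss_subj = k * ((subj_mean - grand) ** 2).sum(axis=0)
    ss_rater = n * ((rater_mean - grand) ** 2).sum(axis=0)
    ss_total = ((data - grand) ** 2).sum(axis=(0, 1))
    ss_err = ss_total - ss_subj - ss_rater
    msr = ss_subj / (n - 1)
    msc = ss_rater / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = np.where(denom > 0, (msr - mse) / np.where(denom != 0, denom, 1.0), 0.0)
    icc = np.clip(icc, -1.0, 1.0)
    return float(icc[0]) if scalar else icc


def icc_filter(
    table_rater1: pd.DataFrame,
    table_rater2: pd.DataFrame,
    threshold: float = 0.90,
) -> pd.Series:
    """Per-feature ICC(2,1) between the two raters' training tables."""
    common = [c for c in table_rater1.columns if c in table_rater2.columns]
    icc = icc_2_1(
        table_rater1[common].to_numpy(), table_rater2.loc[table_rater1.index, common].to_numpy()
    )
    return pd.Series(icc, index=common, name="icc")


def univariate_filter(
    train_table: pd.DataFrame, labels: pd.Series, config: SelectionConfig | None = None
):
    """Per-feature two-group test; normality (Shapiro-Wilk, both classes) gates
    Welch's t vs Mann-Whitney U. Returns (survivors, stats frame)."""
    config = config or SelectionConfig()
    y = labels.loc[train_table.index].to_numpy()
    if (y == 0).sum() < 2 or (y == 1).sum() < 2:
        raise ValueError("both classes need >= 2 samples")
    rows = []
    for col in train_table.columns:
        x = train_table[col].to_numpy(dtype=float)
        g0, g1 = x[y == 0], x[y == 1]
        if np.nanstd(x) == 0 or not np.all(np.isfinite(x)):
            rows.append((col, "excluded", np.nan, "constant or non-finite"))
            continue
        normal = True
        for g in (g0, g1):
            if g.size < 3 or np.ptp(g) == 0:
                normal = False
                break
            if stats.shapiro(g).pvalue < config.shapiro_alpha:
                normal = False
                break
        if normal:
            p = stats.ttest_ind(g0, g1, equal_var=False).pvalue
            test = "welch_t"
        else:
            p = stats.mannwhitneyu(g0, g1, alternative="two-sided").pvalue
            test = "mannwhitney_u"
        rows.append((col, test, float(p), ""))
    frame = pd.DataFrame(rows, columns=["feature", "test", "p", "note"]).set_index(
        "feature"
    )
    survivors = [c for c in frame.index if frame.loc[c, "p"] < config.p_threshold]
    return survivors, frame


def spearman_prune(
    train_table: pd.DataFrame,
    survivors: list,
    cutoff: float = 0.90,
    priority: pd.Series | None = None,
) -> list:
    """Greedy redundancy pruning: no surviving pair has |Spearman rho| > cutoff.

    Features are visited in ascending ``priority`` (univariate p; column
    order when absent) and kept only if not too correlated with any
    already-kept feature. Deterministic.
    """
    if not survivors:
        raise ValueError("no surviving features to prune")
    if priority is not None:
        order = sorted(survivors, key=lambda c: (priority.get(c, np.inf), c))
    else:
        order = list(survivors)
    ranks = train_table[order].rank().to_numpy(dtype=float)
    ranks -= ranks.mean(axis=0)
    norm = np.sqrt((ranks**2).sum(axis=0))
    norm[norm == 0] = 1.0
    ranks /= norm
    kept_idx = []
    for j in range(len(order)):
        if kept_idx:
            rho = ranks[:, kept_idx].T @ ranks[:, j]
            if np.any(np.abs(rho) > cutoff):
                continue
        kept_idx.append(j)
    kept = {order[j] for j in kept_idx}
    return [c for c in survivors if c in kept]


def mrmr_select(train_table: pd.DataFrame, labels: pd.Series, k: int) -> list:
    """Greedy mRMR, FCQ variant: relevance = one-way F statistic vs the label,
    redundancy = mean |Pearson rho| to already-selected features, score =
    relevance / redundancy. First pick maximizes relevance. Ties resolve by
    feature-name order; k larger than the candidate set selects all with a
    warning."""
    cols = list(train_table.columns)
    if k > len(cols):
        warnings.warn(f"mrmr_k={k} > {len(cols)} candidates: selecting all")
        k = len(cols)
    y = labels.loc[train_table.index].to_numpy()
    X = train_table.to_numpy(dtype=float)
    g0, g1 = X[y == 0], X[y == 1]
    f_stat = np.zeros(len(cols))
    for j in range(len(cols)):
        f = stats.f_oneway(g0[:, j], g1[:, j]).statistic
        f_stat[j] = f if np.isfinite(f) else 0.0
    Z = X - X.mean(axis=0)
    norm = np.sqrt((Z**2).sum(axis=0))
    norm[norm == 0] = 1.0
    Z = Z / norm
    selected: list[int] = []
    remaining = list(range(len(cols)))
    while len(selected) < k and remaining:
        if not selected:
            scores = f_stat[remaining]
        else:
            red = np.abs(Z[:, remaining].T @ Z[:, selected]).mean(axis=1)
            red = np.maximum(red, 1e-12)
            scores = f_stat[remaining] / red
        best = int(np.argmax(scores))  # argmax returns the first max: name order
        selected.append(remaining.pop(best))
    return [cols[j] for j in selected]


def lasso_select(
    train_table: pd.DataFrame,
    labels: pd.Series,
    folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 40,
):
    """L1-penalized logistic regression over a log-spaced penalty grid.

    lambda* minimizes the mean cross-validated binomial deviance
    (stratified folds, deterministic under ``seed``); survivors are the
    features with nonzero coefficients in the refit at lambda*. Returns
    (survivors, path dict). An all-zero solution returns an empty list with
    a warning.
    """
    y = labels.loc[train_table.index].to_numpy()
    X = train_table.to_numpy(dtype=float)
    n = X.shape[0]
    if min((y == 0).sum(), (y == 1).sum()) < folds:
        folds = max(2, int(min((y == 0).sum(), (y == 1).sum())))
    cs = np.logspace(-2.5, 1.5, n_lambdas)  # C = 1 / (n * lambda)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    mean_dev = np.zeros(n_lambdas)
    for tr, va in cv.split(X, y):
        for i, c in enumerate(cs):
            clf = LogisticRegression(
                l1_ratio=1.0, C=c, solver="liblinear", max_iter=2000, random_state=seed
            )
            clf.fit(X[tr], y[tr])
            p = clf.predict_proba(X[va])[:, 1]
            mean_dev[i] += log_loss(y[va], p, labels=[0, 1]) * va.size
    mean_dev /= n
    best = int(np.argmin(mean_dev))
    clf = LogisticRegression(
        l1_ratio=1.0, C=cs[best], solver="liblinear", max_iter=2000, random_state=seed
    )
    clf.fit(X, y)
    coefs = clf.coef_.ravel()
    survivors = [c for c, b in zip(train_table.columns, coefs) if b != 0.0]
    if not survivors:
        warnings.warn("LASSO selected no features at the deviance-optimal penalty")
    path = {
        "lambda": (1.0 / (n * cs)).tolist(),
        "mean_deviance": mean_dev.tolist(),
        "best_index": best,
        "coefficients": dict(zip(train_table.columns, coefs.tolist())),
    }
    return survivors, path


def run_cascade(
    table: pd.DataFrame,
    table_rater2: pd.DataFrame | None,
    labels: pd.Series,
    train_ids: list,
    config: SelectionConfig | None = None,
    pool: str = "",
) -> SelectionReport:
    """The full ICC -> z-score -> univariate -> Spearman -> mRMR -> LASSO cascade.

    ``table``/``table_rater2`` hold all patients; only ``train_ids`` rows are
    ever used to compute statistics. Feature columns with missing values in
    the training rows (e.g. empty habitats) are dropped up front.
    """
    config = config or SelectionConfig()
    extra = set(train_ids) - set(table.index)
    if extra:
        raise ValueError(f"unknown training ids: {sorted(extra)[:3]}")
    test_ids = [i for i in table.index if i not in set(train_ids)]
    train = table.loc[train_ids]
    assert not set(train.index) & set(test_ids), "test rows leaked into selection"
    report = SelectionReport(pool=pool)

    complete = [c for c in train.columns if np.isfinite(train[c]).all()]
    report.stages["complete"] = complete
    train = train[complete]

    if table_rater2 is not None:
        icc = icc_filter(
            train, table_rater2.loc[train_ids], threshold=config.icc_threshold
        )
        surv_icc = [c for c in complete if icc.get(c, -1) >= config.icc_threshold]
    else:
        icc = pd.Series(np.nan, index=complete, name="icc")
        surv_icc = complete
    report.stages["icc"] = surv_icc
    train = train[surv_icc]

    mu = train.mean()
    sd = train.std(ddof=0).replace(0.0, 1.0)
    report.scaler = {"mean": mu.to_dict(), "sd": sd.to_dict()}
    z = (train - mu) / sd

    surv_uni, uni_stats = univariate_filter(z, labels, config)
    report.stages["univariate"] = surv_uni
    if not surv_uni:
        report.statistics = uni_stats.join(icc.rename("icc"))
        report.stages["spearman"] = []
        report.stages["mrmr"] = []
        report.stages["lasso"] = []
        return report

    surv_sp = spearman_prune(
        z[surv_uni], surv_uni, config.spearman_cutoff, priority=uni_stats["p"]
    )
    report.stages["spearman"] = surv_sp

    surv_mrmr = mrmr_select(z[surv_sp], labels, config.mrmr_k)
    report.stages["mrmr"] = surv_mrmr

    surv_lasso, path = lasso_select(
        z[surv_mrmr], labels, config.lasso_folds, config.seed, config.n_lambdas
    )
    report.stages["lasso"] = surv_lasso
    report.lasso_path = path

    stats_frame = uni_stats.join(icc.rename("icc"))
    stats_frame["selected"] = stats_frame.index.isin(surv_lasso)
    report.statistics = stats_frame
    return report
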
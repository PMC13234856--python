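"""Predictive models: logistic covariate screening and gradient-boosted classifiers.

Clinical covariates are screened with univariable logistic regression
(reference levels: TIC inflow/platform, BI-RADS 4a4b, grade G1-2, Ki-67
<20%); variables with p < 0.05 enter a multivariable fit whose significant
terms define the clinical model's feature set. Four XGBoost classifiers -
clinical, conventional radiomics, habitat radiomics, combined - are tuned by
exhaustive grid search under 5-fold stratified cross-validation on mean
validation AUC (ties broken toward fewer trees, then shallower depth) and
refit on the full training split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

CATEGORICAL_REFERENCE = {
    "tic": "inflow_or_platform",
    "bi_rads": "4a4b",
    "grade": "G1_2",
    "ki67": "lt20",
}
CONTINUOUS_VARS = ("age", "tumor_length", "aln_length", "alb_glb", "tc", "hdl_c", "ldl_c")


def odds_ratio_2x2(
    exposed_cases: int,
    unexposed_cases: int,
    exposed_controls: int,
    unexposed_controls: int,
    alpha: float = 0.05,
    continuity: bool = False,
):
    """Cross-product odds ratio with the Woolf log-scale confidence interval.

    OR = (exposed_cases * unexposed_controls) / (exposed_controls * unexposed_cases).
    A zero cell raises unless ``continuity`` adds 0.5 to every cell.
    """
    cells = [exposed_cases, unexposed_cases, exposed_controls, unexposed_controls]
    if any(c < 0 for c in cells):
        raise ValueError("counts must be non-negative")
    if any(c == 0 for c in cells):
        if not continuity:
            raise ValueError("zero cell: enable continuity=True for the Haldane correction")
        cells = [c + 0.5 for c in cells]
    a, c, b, d = cells  # a/c: cases exposed/unexposed, b/d: controls
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha / 2)
    return {
        "odds_ratio": float(or_),
        "ci_low": float(np.exp(np.log(or_) - z * se)),
        "ci_high": float(np.exp(np.log(or_) + z * se)),
    }


def clinical_design_matrix(clinical: pd.DataFrame) -> pd.DataFrame:
    """Numeric design matrix: continuous columns + dummies vs reference levels."""
    out = {}
    for var in CONTINUOUS_VARS:
        if var in clinical:
            out[var] = clinical[var].astype(float)
    if "menopause" in clinical:
        out["menopause"] = clinical["menopause"].astype(int)
    for var, ref in CATEGORICAL_REFERENCE.items():
        if var not in clinical:
            continue
        levels = [l for l in pd.unique(clinical[var]) if l != ref]
        for level in sorted(map(str, levels)):
            out[f"{var}_{level}"] = (clinical[var].astype(str) == level).astype(int)
    return pd.DataFrame(out, index=clinical.index)


@dataclass
class LogisticFit:
    model_type: str  # "univariable" | "multivariable"
    table: pd.DataFrame  # per-term coef, odds_ratio, ci_low, ci_high, p
    variable: str = ""
    flags: list = field(default_factory=list)

    @property
    def significant_terms(self) -> list:
        t = self.table
        return [i for i in t.index if np.isfinite(t.loc[i, "p"]) and t.loc[i, "p"] < 0.05]


def _fit_logit(X: pd.DataFrame, y: np.ndarray):
    """MLE logistic fit with Wald statistics; flags separation/convergence issues."""
    flags = []
    Xc = sm.add_constant(X.astype(float), has_constant="add")
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        params = res.params
        bse = res.bse
        pvals = res.pvalues
        if not res.mle_retvals.get("converged", True) or np.any(~np.isfinite(bse)):
            flags.append("non-convergence or infinite standard error (separation?)")
    except Exception as exc:  # perfect separation raises in statsmodels
        flags.append(f"fit failed: {exc}")
        params = pd.Series(np.nan, index=Xc.columns)
        bse = pd.Series(np.nan, index=Xc.columns)
        pvals = pd.Series(np.nan, index=Xc.columns)
    z = stats.norm.ppf(0.975)
    rows = {}
    for term in X.columns:
        b, se, p = params.get(term, np.nan), bse.get(term, np.nan), pvals.get(term, np.nan)
        rows[term] = {
            "coef": b,
            "odds_ratio": np.exp(b) if np.isfinite(b) else np.inf,
            "ci_low": np.exp(b - z * se) if np.isfinite(se) else np.nan,
            "ci_high": np.exp(b + z * se) if np.isfinite(se) else np.nan,
            "p": p,
        }
    return pd.DataFrame.from_dict(rows, orient="index"), flags


_VARIABLE_GROUPS = {
    "tic": ["tic_washout"],
    "bi_rads": ["bi_rads_4c", "bi_rads_5"],
    "grade": ["grade_G3"],
    "ki67": ["ki67_ge20"],
}


def univariable_screen(clinical_train: pd.DataFrame, labels: pd.Series) -> list:
    """One univariable logistic fit per clinical variable (training rows only).

    Multi-level variables are fitted with their full dummy block; the
    variable-level screening p is the smallest term p.
    """
    design = clinical_design_matrix(clinical_train)
    y = labels.loc[clinical_train.index].to_numpy()
    fits = []
    grouped = set(sum(_VARIABLE_GROUPS.values(), []))
    variables = [c for c in design.columns if c not in grouped]
    for var in variables:
        table, flags = _fit_logit(design[[var]], y)
        fits.append(LogisticFit("univariable", table, variable=var, flags=flags))
    for var, terms in _VARIABLE_GROUPS.items():
        present = [t for t in terms if t in design.columns]
        if not present:
            continue
        table, flags = _fit_logit(design[present], y)
        fits.append(LogisticFit("univariable", table, variable=var, flags=flags))
    return fits


def multivariable_fit(
    clinical_train: pd.DataFrame, labels: pd.Series, screened_fits: list
) -> LogisticFit:
    """Joint MLE over the univariable-significant variables."""
    design = clinical_design_matrix(clinical_train)
    y = labels.loc[clinical_train.index].to_numpy()
    terms = []
    flags = []
    for fit in screened_fits:
        if any(fit.table["p"] < 0.05):
            group = _VARIABLE_GROUPS.get(fit.variable, [fit.variable])
            terms.extend([t for t in group if t in design.columns])
    if not terms:
        # small-sample fallback: keep the single best-screening variable so
        # the clinical model stays defined
        best = min(
            screened_fits,
            key=lambda f: np.nanmin(f.table["p"].to_numpy()) if len(f.table) else np.inf,
        )
        group = _VARIABLE_GROUPS.get(best.variable, [best.variable])
        terms = [t for t in group if t in design.columns]
        flags.append(
            f"no variable passed the univariable screen: falling back to {best.variable}"
        )
    table, fit_flags = _fit_logit(design[terms], y)
    return LogisticFit(
        "multivariable", table, variable="+".join(terms), flags=flags + fit_flags
    )


@dataclass
class BoostConfig:
    max_depth: tuple = (2, 3, 4)
    learning_rate: tuple = (0.05, 0.1, 0.3)
    n_estimators: tuple = (50, 100, 200)
    subsample: tuple = (0.8, 1.0)
    colsample_bytree: tuple = (1.0,)
    reg_lambda: tuple = (1.0,)
    cv_folds: int = 5
    seed: int = 0

    def grid(self):
        keys = (
            "max_depth",
            "learning_rate",
            "n_estimators",
            "subsample",
            "colsample_bytree",
            "reg_lambda",
        )
        for combo in product(*[getattr(self, k) for k in keys]):
            yield dict(zip(keys, combo))


def _make_clf(params: dict, seed: int) -> XGBClassifier:
    return XGBClassifier(
        objective="binary:logistic",
        eval_metric="logloss",
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        **params,
    )


def tune_and_fit(
    features_train: pd.DataFrame,
    labels: pd.Series,
    config: BoostConfig | None = None,
    forbidden_ids=None,
):
    """Exhaustive grid scan under stratified CV on mean validation AUC.

    The winner (ties -> fewer trees, then shallower, then grid order) is
    refit on the full training rows. ``forbidden_ids`` (e.g. the test
    split) must not appear in ``features_train`` - an instrumentation
    guard against leakage.
    """
    config = config or BoostConfig()
    if forbidden_ids is not None:
        leaked = set(features_train.index) & set(forbidden_ids)
        assert not leaked, f"test rows reached tune_and_fit: {sorted(leaked)[:3]}"
    X = features_train.to_numpy(dtype=float)
    y = labels.loc[features_train.index].to_numpy()
    pos, neg = int(y.sum()), int((1 - y).sum())
    if min(pos, neg) < config.cv_folds:
        raise ValueError(
            f"need >= {config.cv_folds} samples per class, got {pos}/{neg}"
        )
    cv = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    folds = list(cv.split(X, y))
    results = []
    for gi, params in enumerate(config.grid()):
        aucs = []
        for tr, va in folds:
            clf = _make_clf(params, config.seed)
            clf.fit(X[tr], y[tr])
            p = clf.predict_proba(X[va])[:, 1]
            if np.unique(y[va]).size < 2:
                raise ValueError("degenerate fold: one class absent")
            aucs.append(roc_auc_score(y[va], p))
        results.append((float(np.mean(aucs)), params, gi))
    results.sort(
        key=lambda r: (-r[0], r[1]["n_estimators"], r[1]["max_depth"], r[2])
    )
    best_auc, best_params, _ = results[0]
    final = _make_clf(best_params, config.seed)
    final.fit(X, y)
    return {
        "model": final,
        "params": best_params,
        "cv_auc": best_auc,
        "scan": [(auc, p) for auc, p, _ in results],
        "feature_names": list(features_train.columns),
    }


@dataclass
class ModelBundle:
    models: dict  # name -> tune_and_fit result
    feature_lists: dict
    predictions: dict  # name -> {"train": Series, "test": Series}


def _predict(fit: dict, table: pd.DataFrame) -> pd.Series:
    p = fit["model"].predict_proba(table[fit["feature_names"]].to_numpy(dtype=float))[:, 1]
    return pd.Series(p, index=table.index)


def build_bundle(
    selection_reports: dict,
    clinical_fit: LogisticFit,
    clinical_design: pd.DataFrame,
    tables: dict,
    labels: pd.Series,
    split: dict,
    config: BoostConfig | None = None,
) -> ModelBundle:
    """Assemble and fit the four models from selection outputs.

    Feature sources: clinical = multivariable-significant covariates;
    conventional / habitat = their pools' cascade survivors; combined =
    fusion-pool survivors plus the clinical covariates. Radiomics features
    are standardized with each pool's training scaler; residual missing
    values are median-imputed on the training split.
    """
    config = config or BoostConfig()
    train_ids = [i for i in clinical_design.index if split[i] == "train"]
    test_ids = [i for i in clinical_design.index if split[i] == "test"]

    def scaled_pool(pool: str) -> pd.DataFrame:
        report = selection_reports[pool]
        feats = report.selected
        if not feats:
            raise ValueError(f"empty feature list for pool '{pool}'")
        t = tables[pool][feats].astype(float)
        mu = pd.Series(report.scaler["mean"])[feats]
        sd = pd.Series(report.scaler["sd"])[feats]
        z = (t - mu) / sd
        med = z.loc[train_ids].median()
        return z.fillna(med)

    clin_feats = clinical_fit.significant_terms
    if not clin_feats:
        # small-sample fallback: no term stays significant jointly -> keep the
        # univariable-screened set rather than an undefined clinical model
        clin_feats = list(clinical_fit.table.index)
        clinical_fit.flags.append(
            "no multivariable-significant term: using all screened covariates"
        )
    if not clin_feats:
        raise ValueError("empty feature list for pool 'clinical'")
    feature_tables = {
        "clinical": clinical_design[clin_feats].astype(float),
        "conventional": scaled_pool("conventional"),
        "habitat": scaled_pool("habitat"),
    }
    fusion = scaled_pool("fusion")
    feature_tables["combined"] = pd.concat(
        [fusion, clinical_design[clin_feats].astype(float)], axis=1
    )
    models, preds, flists = {}, {}, {}
    for name, table in feature_tables.items():
        fit = tune_and_fit(
            table.loc[train_ids], labels, config, forbidden_ids=test_ids
        )
        models[name] = fit
        flists[name] = list(table.columns)
        preds[name] = {
            "train": _predict(fit, table.loc[train_ids]),
            "test": _predict(fit, table.loc[test_ids]),
        }
    return ModelBundle(models=models, feature_lists=flists, predictions=preds)
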
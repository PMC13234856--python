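"""Shapley-value attributions for the gradient-boosted models.

Attributions are computed in log-odds (margin) space with the exact
polynomial-time TreeSHAP algorithm built into xgboost
(``pred_contribs=True``), whose conditional expectations follow the trees'
cover statistics. Local accuracy holds by construction:
base_value + sum(attributions) = margin output for every sample.

``exhaustive_shapley`` re-derives the values by brute-force subset
enumeration over the model's JSON dump (exponential in the number of
features) and exists purely as an independent validation oracle for small
models. The two routes coincide exactly whenever no root-to-leaf path
splits twice on the same feature; for repeated features the engine uses a
merged-path convention that redistributes credit between the occurrences
(totals, and hence local accuracy, are unaffected).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd
import xgboost


@dataclass
class ShapExplanation:
    base_value: float
    attributions: pd.DataFrame  # samples x features, log-odds units
    feature_names: list
    output_space: str = "log-odds"

    def model_output(self) -> pd.Series:
        """Reconstructed margin output per sample (base + sum of attributions)."""
        return self.attributions.sum(axis=1) + self.base_value


def _booster(model) -> xgboost.Booster:
    return model.get_booster() if hasattr(model, "get_booster") else model


def explain(model, X_explain: pd.DataFrame, feature_names=None) -> ShapExplanation:
    """Exact tree-Shapley attributions for every row of ``X_explain``.

    The expectation baseline is path-dependent (tree cover weights, i.e.
    the training data the trees saw). Deterministic. Raises on a feature
    schema mismatch.
    """
    booster = _booster(model)
    names = feature_names or list(X_explain.columns)
    if booster.num_features() != len(names):
        raise ValueError(
            f"model expects {booster.num_features()} features, got {len(names)}"
        )
    dm = xgboost.DMatrix(X_explain.to_numpy(dtype=float), feature_names=[str(n) for n in names])
    contribs = booster.predict(dm, pred_contribs=True)
    base = float(contribs[0, -1])
    att = pd.DataFrame(contribs[:, :-1], index=X_explain.index, columns=names)
    margins = booster.predict(dm, output_margin=True)
    err = np.abs(att.sum(axis=1).to_numpy() + base - margins).max()
    if err > 1e-4:
        raise AssertionError(f"local accuracy violated: max error {err}")
    return ShapExplanation(base_value=base, attributions=att, feature_names=names)


def global_importance(explanation: ShapExplanation) -> pd.Series:
    """Features ranked by descending mean |attribution| (ties by name)."""
    imp = explanation.attributions.abs().mean(axis=0)
    return imp.sort_index().sort_values(ascending=False, kind="mergesort")


def waterfall_data(explanation: ShapExplanation, sample_id) -> pd.DataFrame:
    """Ordered single-sample contribution list for a waterfall display.

    Rows are ordered by descending |attribution|; the cumulative column
    starts at the base value and ends at the model output.
    """
    if sample_id not in explanation.attributions.index:
        raise KeyError(f"unknown sample {sample_id!r}")
    row = explanation.attributions.loc[sample_id]
    order = row.abs().sort_values(ascending=False, kind="mergesort").index
    contrib = row[order]
    cumulative = explanation.base_value + contrib.cumsum()
    return pd.DataFrame(
        {"attribution": contrib, "cumulative": cumulative}, index=order
    )


# --------------------------------------------------------------------------
# brute-force oracle


def _tree_expvalue(node: dict, x: np.ndarray, subset: frozenset) -> float:
    """Cover-weighted conditional expectation of one tree given features in
    ``subset`` fixed at x."""
    if "leaf" in node:
        return float(node["leaf"])
    f = int(node["split"].lstrip("f")) if node["split"].startswith("f") else None
    if f is None:
        raise ValueError(f"unparseable split feature {node['split']!r}")
    kids = {k["nodeid"]: k for k in node["children"]}
    if f in subset:
        # the engine compares in float32; the JSON dump's shortest decimal
        # repr can land on either side of the true float32 threshold
        cond = float(np.float32(node["split_condition"]))
        branch = node["yes"] if x[f] < cond else node["no"]
        return _tree_expvalue(kids[branch], x, subset)
    total = sum(k["cover"] for k in node["children"])
    return sum(
        k["cover"] / total * _tree_expvalue(k, x, subset) for k in node["children"]
    )


def exhaustive_shapley(model, X: pd.DataFrame) -> ShapExplanation:
    """Brute-force Shapley values by 2^M subset enumeration (validation oracle).

    Only sensible for models with few features. Uses the same
    cover-weighted conditional expectation game as TreeSHAP, so the two
    must agree to numerical precision.
    """
    booster = _booster(model)
    trees = [json.loads(t) for t in booster.get_dump(dump_format="json", with_stats=True)]
    m = booster.num_features()
    if m > 12:
        raise ValueError("exhaustive enumeration is limited to <= 12 features")
    dm = xgboost.DMatrix(X.to_numpy(dtype=float))
    margins = booster.predict(dm, output_margin=True)
    # the tree engine compares in float32; match its branch decisions exactly
    Xa = X.to_numpy(dtype=np.float32).astype(float)

    def value(x, subset):
        return sum(_tree_expvalue(t, x, subset) for t in trees)

    feats = list(range(m))
    rows = np.zeros((Xa.shape[0], m))
    base = None
    for r, x in enumerate(Xa):
        v = {}
        for size in range(m + 1):
            for s in combinations(feats, size):
                v[frozenset(s)] = value(x, frozenset(s))
        full_offset = margins[r] - v[frozenset(feats)]  # global base_score margin
        if base is None:
            base = v[frozenset()] + full_offset
        for i in feats:
            phi = 0.0
            others = [f for f in feats if f != i]
            for size in range(m):
                w = factorial(size) * factorial(m - size - 1) / factorial(m)
                for s in combinations(others, size):
                    fs = frozenset(s)
                    phi += w * (v[fs | {i}] - v[fs])
            rows[r, i] = phi
    return ShapExplanation(
        base_value=float(base),
        attributions=pd.DataFrame(rows, index=X.index, columns=list(X.columns)),
        feature_names=list(X.columns),
    )
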
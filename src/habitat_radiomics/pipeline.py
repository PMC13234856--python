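"""End-to-end orchestration: generate -> preprocess -> habitats -> features ->
select -> train -> evaluate -> explain.

A single :class:`RunConfig` nests every stage's configuration plus a global
seed that propagates to each stochastic stage. Stage outputs are cached on
disk under ``<out_dir>/cache`` keyed by a hash of the stage's configuration,
so re-running with an identical config reuses cached results (and produces
identical metrics), while any config change invalidates downstream stages.
A JSON manifest records configs, hashes, timings and headline metrics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import yaml

from .evaluation import evaluate_models
from .features import FeatureBankConfig, extract_cohort_tables
from .habitats import build_habitat_maps
from .interpret import explain, global_importance
from .models import (
    BoostConfig,
    build_bundle,
    clinical_design_matrix,
    multivariable_fit,
    univariable_screen,
)
from .preprocess import PreprocessConfig, preprocess_study
from .selection import SelectionConfig, run_cascade
from .synthetic import SyntheticConfig, generate_cohort

STAGES = (
    "generate",
    "preprocess",
    "habitats",
    "features",
    "select",
    "train",
    "evaluate",
    "explain",
)


@dataclass
class HabitatStageConfig:
    window: int = 3
    compactness: float = 0.1
    mm3_per_supervoxel: float = 100.0
    k_range: tuple = (2, 10)
    seed: int = 0


@dataclass
class RunConfig:
    out_dir: str = "results"
    seed: int = 0
    stages: tuple = STAGES
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    habitats: HabitatStageConfig = field(default_factory=HabitatStageConfig)
    features: FeatureBankConfig = field(default_factory=FeatureBankConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    boost: BoostConfig = field(default_factory=BoostConfig)

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        # the global seed drives every stochastic stage
        self.synthetic.seed = self.seed
        self.habitats.seed = self.seed
        self.selection.seed = self.seed
        self.boost.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        nested = {
            "synthetic": SyntheticConfig,
            "preprocess": PreprocessConfig,
            "habitats": HabitatStageConfig,
            "features": FeatureBankConfig,
            "selection": SelectionConfig,
            "boost": BoostConfig,
        }
        for key, value in raw.items():
            if key in nested:
                kwargs[key] = nested[key](**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


def _hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


class PipelineRun:
    """Stateful runner with per-stage disk caching."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.cache = self.out / "cache"
        self.cache.mkdir(parents=True, exist_ok=True)
        self.manifest = {"stages": {}, "config": dataclasses.asdict(config)}
        self.state = {}

    def _stage_hash(self, stage: str) -> str:
        cfg = dataclasses.asdict(self.config)
        relevant = {
            "generate": ["synthetic"],
            "preprocess": ["synthetic", "preprocess"],
            "habitats": ["synthetic", "preprocess", "habitats"],
            "features": ["synthetic", "preprocess", "habitats", "features"],
            "select": ["synthetic", "preprocess", "habitats", "features", "selection"],
            "train": [
                "synthetic",
                "preprocess",
                "habitats",
                "features",
                "selection",
                "boost",
            ],
        }.get(stage, list(cfg))
        return _hash({k: cfg.get(k) for k in relevant})

    def _run_stage(self, stage: str, fn):
        h = self._stage_hash(stage)
        path = self.cache / f"{stage}-{h}.joblib"
        t0 = time.time()
        if path.exists():
            result = joblib.load(path)
            cached = True
        elif stage not in self.config.stages:
            raise RuntimeError(
                f"stage '{stage}' is disabled and has no cached outputs at {path}"
            )
        else:
            result = fn()
            joblib.dump(result, path)
            cached = False
        self.state[stage] = result
        self.manifest["stages"][stage] = {
            "hash": h,
            "cached": cached,
            "seconds": round(time.time() - t0, 3),
        }
        return result

    # stage bodies -----------------------------------------------------

    def generate(self):
        return self._run_stage("generate", lambda: generate_cohort(self.config.synthetic))

    def preprocess(self):
        cohort = self.state["generate"]

        def body():
            import copy

            out = copy.copy(cohort)
            out.studies = [
                preprocess_study(s, self.config.preprocess) for s in cohort.studies
            ]
            return out

        return self._run_stage("preprocess", body)

    def habitats(self):
        cohort = self.state["preprocess"]
        hc = self.config.habitats

        def body():
            model, maps, svsets = build_habitat_maps(
                cohort,
                window=hc.window,
                compactness=hc.compactness,
                mm3_per_supervoxel=hc.mm3_per_supervoxel,
                k_range=tuple(hc.k_range),
                seed=hc.seed,
            )
            return {"model": model, "maps": maps}

        return self._run_stage("habitats", body)

    def features(self):
        cohort = self.state["preprocess"]
        hab = self.state["habitats"]

        def body():
            import copy

            from .habitats import assign_habitats, slic_supervoxels, voxel_feature_maps

            hc = self.config.habitats
            label_maps = {pid: m.label_volume for pid, m in hab["maps"].items()}
            tables = extract_cohort_tables(
                cohort, label_maps, self.config.features, hab["model"].K
            )
            # rater 2: repeat the habitat assignment on the second mask with the
            # same fitted model, then re-extract everything
            rater2_studies = []
            label_maps2 = {}
            for study in cohort.studies:
                s2 = copy.copy(study)
                s2.tumor_mask = study.tumor_mask_rater2
                vfm = voxel_feature_maps(s2, window=hc.window)
                spacing = next(iter(s2.sequences.values()))[1]
                sv = slic_supervoxels(
                    vfm,
                    compactness=hc.compactness,
                    spacing=spacing,
                    mm3_per_supervoxel=hc.mm3_per_supervoxel,
                    patient_id=s2.patient_id,
                )
                label_maps2[s2.patient_id] = assign_habitats(sv, hab["model"]).label_volume
                rater2_studies.append(s2)
            cohort2 = copy.copy(cohort)
            cohort2.studies = rater2_studies
            tables2 = extract_cohort_tables(
                cohort2, label_maps2, self.config.features, hab["model"].K
            )
            return {"rater1": tables, "rater2": tables2}

        return self._run_stage("features", body)

    def select(self):
        cohort = self.state["preprocess"]
        feats = self.state["features"]

        def body():
            labels = cohort.labels
            train_ids = cohort.ids("train")
            reports = {}
            for pool in ("conventional", "habitat", "fusion"):
                reports[pool] = run_cascade(
                    feats["rater1"][pool],
                    feats["rater2"][pool],
                    labels,
                    train_ids,
                    self.config.selection,
                    pool=pool,
                )
            return reports

        return self._run_stage("select", body)

    def train(self):
        cohort = self.state["preprocess"]
        feats = self.state["features"]
        reports = self.state["select"]

        def body():
            labels = cohort.labels
            clinical = cohort.clinical_frame().drop(columns=["alnm", "split"])
            design = clinical_design_matrix(clinical)
            train_ids = cohort.ids("train")
            screen = univariable_screen(clinical.loc[train_ids], labels)
            multi = multivariable_fit(clinical.loc[train_ids], labels, screen)
            bundle = build_bundle(
                reports,
                multi,
                design,
                feats["rater1"],
                labels,
                cohort.split,
                self.config.boost,
            )
            return {"bundle": bundle, "univariable": screen, "multivariable": multi}

        return self._run_stage("train", body)

    def evaluate(self):
        cohort = self.state["preprocess"]
        trained = self.state["train"]

        def body():
            labels = cohort.labels
            out = {}
            for subset in ("train", "test"):
                ids = cohort.ids(subset)
                preds = {
                    name: trained["bundle"].predictions[name][subset]
                    for name in trained["bundle"].models
                }
                out[subset] = evaluate_models(
                    {k: v.to_numpy() for k, v in preds.items()},
                    labels.loc[ids].to_numpy(),
                )
            return out

        return self._run_stage("evaluate", body)

    def explain(self):
        cohort = self.state["preprocess"]
        trained = self.state["train"]

        def body():
            bundle = trained["bundle"]
            fit = bundle.models["combined"]
            test_ids = cohort.ids("test")
            test_pred = bundle.predictions["combined"]["test"]
            # rebuild the combined test table from stored per-model predictions'
            # index and the fitted feature list
            table = _combined_table(self, test_ids)
            expl = explain(fit["model"], table)
            return {
                "explanation": expl,
                "importance": global_importance(expl),
                "test_prediction": test_pred,
            }

        return self._run_stage("explain", body)

    # ------------------------------------------------------------------

    def run(self):
        order = [s for s in STAGES]
        for stage in order:
            getattr(self, stage)()
        self._write_outputs()
        return self.out

    def _write_outputs(self):
        out = self.out
        cohort = self.state["preprocess"]
        cohort.clinical_frame().to_csv(out / "clinical.csv", index_label="patient_id")
        hab = self.state["habitats"]
        (out / "habitats.json").write_text(
            json.dumps(
                {
                    "K": hab["model"].K,
                    "silhouette_by_k": hab["model"].silhouette_by_k,
                    "ordering_rule": hab["model"].ordering_rule,
                },
                indent=2,
            )
        )
        reports = self.state["select"]
        sel = {
            pool: {stage: feats for stage, feats in r.stages.items()}
            for pool, r in reports.items()
        }
        (out / "selection.json").write_text(json.dumps(sel, indent=2))
        ev = self.state["evaluate"]
        metrics = {}
        for subset, rep in ev.items():
            metrics[subset] = {
                name: {
                    "auc": m["roc"].auc,
                    "auc_ci": [m["roc"].ci_low, m["roc"].ci_high],
                    "confusion": {
                        k: v
                        for k, v in m["confusion"].items()
                        if k not in ("tp", "tn", "fp", "fn")
                    },
                }
                for name, m in rep["models"].items()
            }
            metrics[subset]["delong"] = {
                pair: {"z": d["z"], "p": d["p"]} for pair, d in rep["delong"].items()
            }
        (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
        for name, m in ev["test"]["models"].items():
            mdir = out / "models" / name
            mdir.mkdir(parents=True, exist_ok=True)
            pd.DataFrame(
                {"fpr": m["roc"].fpr, "tpr": m["roc"].tpr, "threshold": m["roc"].thresholds}
            ).to_csv(mdir / "roc_test.csv", index=False)
            pd.DataFrame(m["decision_curve"]).to_csv(mdir / "dca_test.csv", index=False)
            if m["calibration"] is not None:
                pd.DataFrame(m["calibration"]).to_csv(
                    mdir / "calibration_test.csv", index=False
                )
        expl = self.state["explain"]
        expl["explanation"].attributions.to_csv(out / "shap_test.csv")
        expl["importance"].rename("mean_abs_shap").to_csv(out / "shap_importance.csv")
        (out / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, default=str)
        )


def _combined_table(run: PipelineRun, ids) -> pd.DataFrame:
    """Reassemble the combined model's feature table for the given patients."""
    cohort = run.state["preprocess"]
    feats = run.state["features"]
    reports = run.state["select"]
    trained = run.state["train"]
    bundle = trained["bundle"]
    train_ids = cohort.ids("train")
    report = reports["fusion"]
    sel = report.selected
    t = feats["rater1"]["fusion"][sel].astype(float)
    mu = pd.Series(report.scaler["mean"])[sel]
    sd = pd.Series(report.scaler["sd"])[sel]
    z = (t - mu) / sd
    z = z.fillna(z.loc[train_ids].median())
    clinical = cohort.clinical_frame().drop(columns=["alnm", "split"])
    design = clinical_design_matrix(clinical)
    clin_cols = [c for c in bundle.feature_lists["combined"] if c in design.columns]
    table = pd.concat([z, design[clin_cols].astype(float)], axis=1)
    return table.loc[ids, bundle.feature_lists["combined"]]


def run(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the results directory."""
    return PipelineRun(config).run()
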
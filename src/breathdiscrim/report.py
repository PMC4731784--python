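"""End-to-end pipeline orchestration and figure/table data export.

``run_pipeline`` drives the whole analysis from a single config: simulate or
ingest a feature matrix, optionally preprocess raw chromatograms, select the
discriminatory panel by PLS-DA + sMC, validate by repeated stratified holdout
and a permutation test, run the cohort statistics, and export everything as
plain delimited/JSON data files with a checksummed manifest.  Figures are
emitted as data (score-plot coordinates, bi-plot arrows, ROC points), not
rendered images.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import FeatureMatrix
from . import synthetic, plsda, smc, validate as vd, cohortstats

__all__ = ["RunConfig", "run_pipeline", "export_figure_data"]


@dataclass
class RunConfig:
    """Round-trippable run configuration (YAML in, YAML out, identical run)."""

    out_dir: str = "results"
    seed: int = 0
    # data: synthetic generator block, or paths to a feature table + metadata
    generator: dict = field(default_factory=lambda: {
        "n_compounds": 500, "effect_magnitude": 1.5,
        "n_per_class": {"CIR": 34, "CLD": 87, "HC": 31}})
    features_path: str | None = None
    metadata_path: str | None = None
    # model block
    contrast: tuple = ("CLD", "CIR")         # (negative, positive)
    n_lv: object = 2                          # int or "auto"
    scaling: str = "autoscale"
    log_transform: bool = True               # model log abundances
    # selection block
    selection_mode: str = "fdr"               # "fdr" | "top_k"
    alpha: float = 0.05
    top_k: int | None = None
    paper_mode: bool = False                  # select on the full dataset (optimistic)
    # validation block
    n_train_per_class: int = 27
    n_val_per_class: int = 7
    n_repeats: int = 100
    n_perm: int = 100
    # cohort statistics
    confounders: tuple = ("etiology", "smoking", "ppi")
    rmanova_n_perm: int = 499

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.contrast = tuple(cfg.contrast)
        cfg.confounders = tuple(cfg.confounders)
        return cfg

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["contrast"] = list(self.contrast)
        d["confounders"] = list(self.confounders)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_or_simulate(config: RunConfig):
    if config.features_path:
        fm = FeatureMatrix.from_csv(config.features_path, config.metadata_path)
        return fm, None
    gen = dict(config.generator)
    design = synthetic.default_design(
        n_compounds=int(gen.get("n_compounds", 500)),
        effect_magnitude=float(gen.get("effect_magnitude", 1.5)),
        n_per_class=gen.get("n_per_class"),
        noise_sd=float(gen.get("noise_sd", 1.0)),
        seed=config.seed)
    cohort = synthetic.generate_feature_matrix(design)
    return cohort.features, cohort


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": config.seed,
                "config": json.loads(json.dumps(asdict(config), default=str)),
                "stages": [], "files": {}}

    def stage(name):
        manifest["stages"].append({"stage": name, "time": time.time()})

    try:
        stage("data")
        features, cohort = _load_or_simulate(config)
        neg, pos = config.contrast
        two_class = features.restrict_classes([neg, pos])
        if config.log_transform:
            two_class = two_class.log_abundances()

        stage("split")
        hconf = vd.HoldoutConfig(positive_class=pos, negative_class=neg,
                                 n_train_per_class=config.n_train_per_class,
                                 n_val_per_class=config.n_val_per_class,
                                 n_repeats=config.n_repeats,
                                 n_lv=config.n_lv, scaling=config.scaling)
        plan = vd.make_splits(two_class, hconf, seed=config.seed)

        stage("select")
        sel_data = (two_class if config.paper_mode
                    else two_class.subset(plan.repeats[0]["train"]))
        full_model = plsda.fit(sel_data, n_lv=config.n_lv, scaling=config.scaling,
                               positive_class=pos)
        stats = smc.smc_statistics(full_model)
        result = smc.select_panel(
            stats, alpha=config.alpha,
            top_k=config.top_k if config.selection_mode == "top_k" else None)
        panel = result.panel or stats.table.nsmallest(11, "p").index.tolist()
        result.to_csv(out / "panel_table.tsv")

        stage("fit")
        train0 = two_class.subset(plan.repeats[0]["train"])
        model = smc.refit_on_panel(train0, panel, n_lv=config.n_lv,
                                   scaling=config.scaling, positive_class=pos)

        stage("validate")
        hconf.panel = list(panel)
        report = vd.run_holdout(two_class, plan, hconf)
        perm = vd.permutation_test(two_class, hconf, n_perm=config.n_perm,
                                   seed=config.seed + 1, observed=report.auc)
        report.permutation = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                              for k, v in perm.items() if k != "null"}
        report.to_json(out / "validation.json")
        report.roc_points.to_csv(out / "roc_points.tsv", sep="\t", index=False)

        stage("cohortstats")
        if features.covariates is not None:
            kinds = {"age": "continuous", "bmi": "continuous"}
            t1 = cohortstats.table_one(
                features.covariates.loc[two_class.sample_ids,
                                        [c for c in ("age", "bmi", "sex", "smoking")
                                         if c in features.covariates.columns]],
                two_class.y, kinds)
            t1.to_csv(out / "table_one.tsv", sep="\t")
            rmanova_out = {}
            panel_mat = two_class.X[panel]
            rm = cohortstats.rmanova(panel_mat, two_class.y,
                                     n_perm=config.rmanova_n_perm,
                                     seed=config.seed + 2, factor_name="class")
            rmanova_out["class"] = {"statistic": rm.statistic, "p": rm.p_value,
                                    "lambda": rm.lam}
            for fac in config.confounders:
                if fac not in features.covariates.columns:
                    continue
                levels = features.covariates.loc[two_class.sample_ids, fac]
                if levels.nunique() < 2 or levels.value_counts().min() < 2:
                    continue
                rm = cohortstats.rmanova(panel_mat, levels,
                                         n_perm=config.rmanova_n_perm,
                                         seed=config.seed + 3, factor_name=fac)
                rmanova_out[fac] = {"statistic": rm.statistic, "p": rm.p_value,
                                    "lambda": rm.lam}
            with open(out / "rmanova.json", "w") as fh:
                json.dump(rmanova_out, fh, indent=2)

        stage("report")
        export_figure_data(model, two_class, plan, out)
        if cohort is not None:
            cohort.features.to_csv(out / "features.tsv", out / "metadata.tsv")
            cohort.truth_to_json(out / "truth.json")
        config.to_yaml(out / "config.yaml")
    except Exception as exc:  # record the failing stage in the manifest
        manifest["error"] = {"stage": manifest["stages"][-1]["stage"],
                             "message": str(exc)}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise

    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][f.name] = _sha256(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def export_figure_data(model, features: FeatureMatrix, plan, out_dir) -> dict:
    """Write score-plot, bi-plot and set-membership data for one fitted model.

    Score-plot rows carry the split membership (train / val1 / val2 of the
    first repeat) so the plot can mark training versus validation samples.
    """
    out = Path(out_dir)
    if model.n_lv < 2:
        raise ValueError("figure export requires >= 2 latent variables")
    sets = pd.Series("unused", index=features.sample_ids)
    sets.loc[plan.repeats[0]["train"]] = "train"
    sets.loc[plan.repeats[0]["val1"]] = "val1"
    if plan.val2:
        sets.loc[plan.val2] = "val2"

    _, T = plsda.predict_scores(model, features)
    scores = pd.DataFrame(T[:, :2], columns=["LV1", "LV2"],
                          index=features.sample_ids)
    scores.insert(0, "sample_id", scores.index)
    scores["class"] = features.y
    scores["set"] = sets
    scores.to_csv(out / "score_plot.tsv", sep="\t", index=False)

    bp = plsda.biplot_data(model)
    arrows = bp["loadings"].copy()
    arrows.insert(0, "compound", arrows.index)
    arrows["direction"] = bp["signed_direction"]
    arrows.to_csv(out / "biplot_loadings.tsv", sep="\t", index=False)
    bp["loading_cosines"].to_csv(out / "biplot_cosines.tsv", sep="\t")
    return {"score_plot": str(out / "score_plot.tsv"),
            "biplot_loadings": str(out / "biplot_loadings.tsv")}
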
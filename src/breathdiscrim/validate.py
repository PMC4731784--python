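"""Model validation: repeated stratified holdout, ROC analysis, permutation test.

The validation scheme mirrors a two-tier internal validation design for a
majority/minority cohort (e.g. 87 CLD vs 34 CIR):

* a fixed hold-back set ("validation set 2") of majority-class samples that
  are never eligible for training;
* repeated stratified holdout: in each repeat a class-balanced training set
  (default 27 + 27) and a class-balanced validation set 1 (default 7 + 7) are
  drawn without replacement from the remaining pool; default 1000 repeats;
* a label-permutation test in which the whole fit-and-validate procedure is
  re-run on permuted class labels (one fresh split per permutation) to form
  the null distribution of the classification statistic (aggregated AUC).

ROC curves are built by sweeping the unique predicted class probabilities as
cutoffs; AUC by the trapezoid rule (equal to the Mann-Whitney U statistic
divided by n1*n2); the optimal cutoff maximises Youden's J with ties broken
toward the cutoff nearest 0.5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datatypes import FeatureMatrix
from . import plsda, smc

__all__ = ["SplitPlan", "HoldoutConfig", "ValidationReport", "make_splits",
           "run_holdout", "roc_curve", "classification_metrics", "permutation_test"]


# ---------------------------------------------------------------------------
# split plans
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Repeated stratified holdout plan with a fixed second validation set."""

    repeats: list               # list of {"train": [ids], "val1": [ids]}
    val2: list                  # fixed hold-back IDs (majority class)
    classes: tuple              # (negative_label, positive_label)
    n_train_per_class: int
    n_val_per_class: int
    seed: int

    @property
    def n_repeats(self) -> int:
        return len(self.repeats)


@dataclass
class HoldoutConfig:
    """Pipeline settings shared by holdout validation and the permutation test."""

    positive_class: str = "CIR"
    negative_class: str = "CLD"
    n_train_per_class: int = 27
    n_val_per_class: int = 7
    n_repeats: int = 1000
    selection: str = "none"        # "none" | "fdr" | "top_k" (per-repeat selection)
    alpha: float = 0.05
    top_k: int | None = None
    panel: list | None = None      # fixed pre-selected panel (overrides selection)
    n_lv: object = 2               # int or "auto"
    scaling: str = "autoscale"
    aggregation: str = "pooled"    # "pooled" | "per_repeat"
    statistic: str = "auc"         # permutation statistic: "auc" | "error"


def make_splits(features: FeatureMatrix, config: HoldoutConfig, seed: int) -> SplitPlan:
    """Draw a reproducible repeated stratified holdout plan.

    Validation set 2 is drawn once (majority-class samples beyond what the
    per-repeat train + validation-1 draws can use) and is identical across
    repeats; train and validation-1 samples are drawn without replacement
    from the remaining pool in every repeat.
    """
    rng = np.random.default_rng(seed)
    neg, pos = config.negative_class, config.positive_class
    need = config.n_train_per_class + config.n_val_per_class
    ids_by_class = {}
    for cls in (neg, pos):
        ids = features.sample_ids[features.y == cls]
        if len(ids) < need:
            raise ValueError(f"class {cls!r} has {len(ids)} samples; "
                             f"{need} required per repeat")
        ids_by_class[cls] = np.array(ids)

    # fixed hold-back: everything in the larger class beyond the per-repeat need
    sizes = {cls: len(ids) for cls, ids in ids_by_class.items()}
    major = max(sizes, key=lambda c: (sizes[c], c == neg))
    n_val2 = sizes[major] - need
    pool = dict(ids_by_class)
    if n_val2 > 0:
        perm = rng.permutation(ids_by_class[major])
        val2 = sorted(perm[:n_val2].tolist())
        pool[major] = perm[n_val2:]
    else:
        val2 = []

    repeats = []
    for _ in range(config.n_repeats):
        train, val1 = [], []
        for cls in (neg, pos):
            perm = rng.permutation(pool[cls])
            train.extend(perm[:config.n_train_per_class].tolist())
            val1.extend(perm[config.n_train_per_class:need].tolist())
        repeats.append({"train": train, "val1": val1})
    return SplitPlan(repeats=repeats, val2=val2, classes=(neg, pos),
                     n_train_per_class=config.n_train_per_class,
                     n_val_per_class=config.n_val_per_class, seed=seed)


# ---------------------------------------------------------------------------
# ROC and confusion-matrix metrics
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    points: pd.DataFrame        # columns FPR, TPR, cutoff; (0,0) first, (1,1) last
    auc: float
    optimal_cutoff: float
    sensitivity: float          # at the optimal cutoff
    specificity: float


def roc_curve(probs, labels, positive_class="CIR") -> ROCResult:
    """ROC from positive-class probabilities via a cutoff sweep.

    A sample is called positive when its probability is >= the cutoff.  The
    sweep runs over the unique probability values (plus a cutoff above the
    maximum for the (0,0) endpoint).
    """
    p = np.asarray(probs, dtype=float)
    yb = np.asarray(labels) == positive_class
    n_pos, n_neg = int(yb.sum()), int((~yb).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for a ROC curve")

    cuts = np.unique(p)[::-1]
    tpr = [0.0]
    fpr = [0.0]
    cutoffs = [np.inf]
    for c in cuts:
        called = p >= c
        tpr.append(np.sum(called & yb) / n_pos)
        fpr.append(np.sum(called & ~yb) / n_neg)
        cutoffs.append(c)
    points = pd.DataFrame({"FPR": fpr, "TPR": tpr, "cutoff": cutoffs})
    auc = float(np.trapezoid(points["TPR"], points["FPR"]))

    j = points["TPR"] - points["FPR"]                # Youden's J = sens + spec - 1
    finite = np.isfinite(points["cutoff"])
    j_max = j[finite].max()
    best = points[finite & (j >= j_max - 1e-12)]
    idx = (best["cutoff"] - 0.5).abs().idxmin()      # tie-break toward 0.5
    return ROCResult(points=points, auc=auc,
                     optimal_cutoff=float(points.loc[idx, "cutoff"]),
                     sensitivity=float(points.loc[idx, "TPR"]),
                     specificity=float(1.0 - points.loc[idx, "FPR"]))


def classification_metrics(predicted, truth, positive_class="CIR",
                           negative_class="CLD") -> dict:
    """Sensitivity, specificity, PPV, NPV and accuracy from hard class calls.

    Ratios with a zero denominator are reported as NaN (missing), not 0.
    """
    pred = np.asarray(predicted)
    true = np.asarray(truth)
    allowed = {positive_class, negative_class}
    bad = set(np.unique(np.concatenate([pred, true]))) - allowed
    if bad:
        raise ValueError(f"labels outside {sorted(allowed)}: {sorted(bad)}")
    tp = np.sum((pred == positive_class) & (true == positive_class))
    fn = np.sum((pred == negative_class) & (true == positive_class))
    tn = np.sum((pred == negative_class) & (true == negative_class))
    fp = np.sum((pred == positive_class) & (true == negative_class))

    def ratio(num, den):
        return float(num) / den if den > 0 else float("nan")

    return {"sensitivity": ratio(tp, tp + fn),
            "specificity": ratio(tn, tn + fp),
            "ppv": ratio(tp, tp + fp),
            "npv": ratio(tn, tn + fn),
            "accuracy": ratio(tp + tn, tp + fn + tn + fp)}


# ---------------------------------------------------------------------------
# repeated holdout
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    per_repeat: pd.DataFrame    # sensitivity, specificity, auc per repeat
    roc_points: pd.DataFrame
    auc: float                  # aggregated (pooled) AUC
    auc_ci: tuple               # 2.5/97.5 percentiles of per-repeat AUCs
    optimal_cutoff: float
    sensitivity: float          # at the optimal cutoff on the pooled ROC
    specificity: float
    mean_sensitivity: float     # averaged over repeats (at each repeat's 0.5 call)
    mean_specificity: float
    ppv: float
    npv: float
    val2_accuracy: float        # mean fraction of val-2 samples correctly assigned
    n_excluded: int
    permutation: dict | None = None

    def summary(self) -> dict:
        return {"auc": self.auc, "auc_ci": list(self.auc_ci),
                "optimal_cutoff": self.optimal_cutoff,
                "sensitivity": self.sensitivity, "specificity": self.specificity,
                "mean_sensitivity": self.mean_sensitivity,
                "mean_specificity": self.mean_specificity,
                "ppv": self.ppv, "npv": self.npv,
                "val2_accuracy": self.val2_accuracy,
                "n_repeats": int(len(self.per_repeat)),
                "n_excluded": int(self.n_excluded),
                "permutation": self.permutation}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2, allow_nan=False,
                      default=lambda o: None if (isinstance(o, float) and np.isnan(o)) else o)


def _fit_repeat(features: FeatureMatrix, train_ids, config: HoldoutConfig):
    """Fit one repeat's model: optional per-repeat panel selection, then PLS-DA."""
    train = features.subset(train_ids)
    if config.panel is not None:
        train = train.select_compounds(config.panel)
    elif config.selection != "none":
        full = plsda.fit(train, n_lv=config.n_lv, scaling=config.scaling,
                         positive_class=config.positive_class)
        res = smc.select_panel(smc.smc_statistics(full),
                               alpha=config.alpha,
                               top_k=config.top_k if config.selection == "top_k" else None)
        if not res.panel:
            raise RuntimeError("empty panel selected")
        train = train.select_compounds(res.panel)
    return plsda.fit(train, n_lv=config.n_lv, scaling=config.scaling,
                     positive_class=config.positive_class)


def _probs(model, features: FeatureMatrix, ids):
    sub = features.subset(ids)
    yhat, _ = plsda.predict_scores(model, sub)
    pr = plsda.class_probabilities(model, yhat)
    return pr[model.positive_class], sub.y


def run_holdout(features: FeatureMatrix, plan: SplitPlan,
                config: HoldoutConfig) -> ValidationReport:
    """Run every repeat of the holdout plan and aggregate.

    Per repeat: fit on the training draw (optionally selecting a panel inside
    it), score validation set 1, and classify the fixed validation set 2.
    The aggregated ROC pools all repeats' validation-1 probabilities
    (per-repeat averaging available via ``config.aggregation``).
    """
    pos, neg = config.positive_class, config.negative_class
    pooled_p, pooled_y = [], []
    rows, val2_acc = [], []
    n_excluded = 0
    for rep in plan.repeats:
        try:
            model = _fit_repeat(features, rep["train"], config)
            p1, y1 = _probs(model, features, rep["val1"])
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            n_excluded += 1
            continue
        pooled_p.append(p1.to_numpy())
        pooled_y.append(y1.to_numpy())
        rep_roc = roc_curve(p1, y1, positive_class=pos)
        calls = np.where(p1.to_numpy() >= 0.5, pos, neg)
        m = classification_metrics(calls, y1.to_numpy(), pos, neg)
        rows.append({"auc": rep_roc.auc, "sensitivity": m["sensitivity"],
                     "specificity": m["specificity"], "ppv": m["ppv"],
                     "npv": m["npv"]})
        if plan.val2:
            p2, y2 = _probs(model, features, plan.val2)
            calls2 = np.where(p2.to_numpy() >= 0.5, pos, neg)
            val2_acc.append(float(np.mean(calls2 == y2.to_numpy())))
    if not rows:
        raise RuntimeError("every repeat failed to fit")

    per_repeat = pd.DataFrame(rows)
    p_all = np.concatenate(pooled_p)
    y_all = np.concatenate(pooled_y)
    pooled = roc_curve(p_all, y_all, positive_class=pos)
    if config.aggregation == "per_repeat":
        agg_auc = float(per_repeat["auc"].mean())
    else:
        agg_auc = pooled.auc
    calls_all = np.where(p_all >= pooled.optimal_cutoff, pos, neg)
    m_all = classification_metrics(calls_all, y_all, pos, neg)
    ci = (float(np.percentile(per_repeat["auc"], 2.5)),
          float(np.percentile(per_repeat["auc"], 97.5)))
    return ValidationReport(per_repeat=per_repeat, roc_points=pooled.points,
                            auc=agg_auc, auc_ci=ci,
                            optimal_cutoff=pooled.optimal_cutoff,
                            sensitivity=pooled.sensitivity,
                            specificity=pooled.specificity,
                            mean_sensitivity=float(per_repeat["sensitivity"].mean()),
                            mean_specificity=float(per_repeat["specificity"].mean()),
                            ppv=m_all["ppv"], npv=m_all["npv"],
                            val2_accuracy=float(np.mean(val2_acc)) if val2_acc else float("nan"),
                            n_excluded=n_excluded)


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def _single_split_statistic(features: FeatureMatrix, config: HoldoutConfig,
                            seed: int) -> float:
    """One fresh split -> fit -> validation-1 statistic (AUC or error rate)."""
    one = HoldoutConfig(**{**asdict(config), "n_repeats": 1})
    plan = make_splits(features, one, seed)
    model = _fit_repeat(features, plan.repeats[0]["train"], one)
    p1, y1 = _probs(features=features, model=model, ids=plan.repeats[0]["val1"])
    if config.statistic == "error":
        calls = np.where(p1.to_numpy() >= 0.5, config.positive_class,
                         config.negative_class)
        return float(np.mean(calls != y1.to_numpy()))
    return roc_curve(p1, y1, positive_class=config.positive_class).auc


def permutation_test(features: FeatureMatrix, config: HoldoutConfig,
                     n_perm: int = 1000, seed: int = 0,
                     observed: float | None = None) -> dict:
    """Label-permutation significance test for the holdout classification.

    The observed statistic is the aggregated AUC of the full repeated-holdout
    procedure (computed here unless passed in).  Each permutation shuffles
    the class labels over all samples and re-runs fit-and-validate on one
    fresh split.  The p-value uses the count-over-iterations convention with
    a floor of one count: p = max(1, #{null >= observed}) / n_perm.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    if observed is None:
        plan = make_splits(features, config, seed=int(rng.integers(2**31)))
        observed = run_holdout(features, plan, config).auc

    null = np.empty(n_perm)
    labels = features.y.to_numpy()
    for i in range(n_perm):
        perm_y = pd.Series(rng.permutation(labels), index=features.sample_ids)
        perm_fm = FeatureMatrix(features.X, perm_y, features.covariates)
        null[i] = _single_split_statistic(perm_fm, config,
                                          seed=int(rng.integers(2**31)))
    if config.statistic == "error":
        count = int(np.sum(null <= observed))     # smaller error is more extreme
    else:
        count = int(np.sum(null >= observed))
    p = max(1, count) / n_perm
    return {"observed": float(observed), "null": null, "p_value": float(p),
            "n_perm": int(n_perm), "min_attainable_p": 1.0 / n_perm}
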
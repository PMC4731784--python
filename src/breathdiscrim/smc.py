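"""Variable selection by significant multivariate correlation (sMC).

sMC ranks each compound by how much of its (scaled) variance is explained by
the PLS regression direction.  With yhat = X b the model's prediction
direction, each scaled compound column x_j is regressed onto yhat by least
squares,

    x_hat_j = yhat (yhat' x_j) / (yhat' yhat),    e_j = x_j - x_hat_j,

and the explained and residual sums of squares

    SSR_j = ||x_hat_j||^2,    SSE_j = ||e_j||^2

form an F-ratio  F_j = (SSR_j / 1) / (SSE_j / (n - 2))  referred to the
F(1, n-2) distribution.  Because the projection is orthogonal, SSR_j + SSE_j
equals the compound's total sum of squares.  Selection controls the false
discovery rate with Benjamini-Hochberg (a fixed top-k override mimics a
fixed-size panel design).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from statsmodels.stats.multitest import multipletests

from .datatypes import FeatureMatrix
from .plsda import PLSModel, fit as plsda_fit

__all__ = ["SMCResult", "smc_statistics", "select_panel", "refit_on_panel"]


@dataclass
class SMCResult:
    """Per-compound sMC statistics and the selected panel."""

    table: pd.DataFrame          # columns: F, p, q, selected, direction, flagged
    panel: list                  # selected compound IDs sorted by ascending p
    n: int                       # training sample count
    alpha: float | None = None
    method: str | None = None

    @property
    def n_selected(self) -> int:
        return len(self.panel)

    def to_csv(self, path, sep: str = "\t") -> None:
        out = self.table.copy()
        out.index.name = "compound"
        out.to_csv(path, sep=sep)


def smc_statistics(model: PLSModel, train: FeatureMatrix | None = None) -> SMCResult:
    """Compute sMC F statistics and p-values for every training compound.

    ``train`` defaults to the training matrix cached on the model; passing it
    explicitly re-scales with the model's centering/scaling vectors.
    """
    if train is not None:
        Xs = model.scale(train.X[model.compound_ids].to_numpy(dtype=float))
    else:
        Xs = model.scale_training_X_
    if Xs is None:
        raise ValueError("no training data available on the model")
    n = Xs.shape[0]
    b = model.b
    if b @ b == 0:
        raise ValueError("regression vector is identically zero")
    t = Xs @ b                          # (n,) prediction direction yhat
    coef = Xs.T @ t / (t @ t)           # per-compound least-squares slope on yhat
    Xhat = np.outer(t, coef)
    E = Xs - Xhat
    ssr = np.sum(Xhat**2, axis=0)
    sse = np.sum(E**2, axis=0)

    flagged = sse <= np.finfo(float).eps * np.maximum(ssr, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(flagged, np.inf, ssr / (sse / (n - 2)))
    p = np.where(flagged, 0.0, f_dist.sf(np.where(flagged, 1.0, F), 1, n - 2))

    table = pd.DataFrame({"F": F, "p": p,
                          "direction": model.signed_direction.to_numpy(),
                          "flagged": flagged},
                         index=pd.Index(model.compound_ids, name="compound"))
    return SMCResult(table=table, panel=[], n=n)


def select_panel(result: SMCResult, alpha: float = 0.05, top_k: int | None = None,
                 method: str = "fdr_bh") -> SMCResult:
    """Flag the discriminatory panel by FDR control (or a fixed panel size).

    Parameters
    ----------
    alpha : float in (0, 1)
        FDR level for Benjamini-Hochberg (``method="fdr_bh"``) or family-wise
        level for Bonferroni (``method="bonferroni"``).
    top_k : int, optional
        Force a fixed panel of the k smallest p-values instead (k = 11
        mirrors a fixed-size panel design).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    table = result.table.copy()
    reject, qvals, *_ = multipletests(table["p"].to_numpy(), alpha=alpha, method=method)
    table["q"] = qvals
    if top_k is not None:
        order = table["p"].to_numpy().argsort(kind="stable")
        sel = np.zeros(len(table), dtype=bool)
        sel[order[:top_k]] = True
        table["selected"] = sel
    else:
        table["selected"] = reject
    panel = table[table["selected"]].sort_values("p").index.tolist()
    return replace(result, table=table, panel=panel, alpha=alpha, method=method)


def refit_on_panel(train: FeatureMatrix, panel, n_lv=2, scaling: str = "autoscale",
                   positive_class=None) -> PLSModel:
    """Refit PLS-DA on the selected compound panel only.

    The reduced model is what enters validation.  If the panel is smaller
    than the requested number of latent variables, n_lv is reduced with a
    warning.
    """
    panel = list(panel)
    if not panel:
        raise ValueError("panel is empty")
    if isinstance(n_lv, int) and n_lv > len(panel):
        warnings.warn(f"panel of size {len(panel)} < n_lv={n_lv}; reducing n_lv")
        n_lv = len(panel)
    reduced = train.select_compounds(panel)
    return plsda_fit(reduced, n_lv=n_lv, scaling=scaling, positive_class=positive_class)
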
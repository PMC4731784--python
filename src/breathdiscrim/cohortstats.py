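"""Cohort-level statistics: univariate group comparisons and the rMANOVA screen.

Continuous subject characteristics (age, BMI, serology) are compared between
patient groups with the Mann-Whitney U test; dichotomous variables (sex,
smoking) with Pearson's chi-square (no continuity correction).  The selected
VOC panel is screened for confounder effects (etiology, drug therapy,
smoking) with a regularized MANOVA: the within-group scatter is shrunk
toward its own diagonal so the multivariate test remains defined when
compounds are correlated or outnumber samples, and significance is assessed
by permuting the factor labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["GroupComparison", "RManovaResult", "mann_whitney", "chi_square",
           "rmanova", "table_one"]


@dataclass
class GroupComparison:
    variable: str
    kind: str                   # "continuous" | "dichotomous"
    groups: dict                # per-group summary: median/range or counts
    test: str
    statistic: float
    p_value: float

    def format_row(self) -> dict:
        row = {"variable": self.variable}
        for g, s in self.groups.items():
            row[g] = s
        row["test"] = self.test
        row["p"] = round(self.p_value, 3)
        return row


@dataclass
class RManovaResult:
    factor: str
    lam: float                  # shrinkage weight toward the diagonal, in [0, 1]
    statistic: float            # trace(S_within_reg^-1 . S_between)
    p_value: float
    n_perm: int
    null: np.ndarray


def mann_whitney(group_a, group_b, variable: str = "") -> GroupComparison:
    """Two-tailed Mann-Whitney U comparison of two value sets.

    Exact enumeration for small samples (n1 + n2 <= 12, no ties), otherwise
    the normal approximation with midrank tie correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        u, p = len(a) * len(b) / 2.0, 1.0
    else:
        has_ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (len(a) + len(b) <= 12 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        u, p = float(res.statistic), float(res.pvalue)
    summ = {"a": _median_range(a), "b": _median_range(b)}
    return GroupComparison(variable, "continuous", summ, "Mann-Whitney U", u, min(p, 1.0))


def _median_range(x: np.ndarray) -> str:
    return f"{np.median(x):g} ({np.min(x):g}-{np.max(x):g})"


def chi_square(table, variable: str = "") -> GroupComparison:
    """Pearson chi-square on a 2x2 count table, df = 1, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a 2x2 table of non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: zero row or column margin")
    res = stats.chi2_contingency(t, correction=False)
    groups = {"col0": f"{int(t[0, 0])}/{int(t[1, 0])}",
              "col1": f"{int(t[0, 1])}/{int(t[1, 1])}"}
    return GroupComparison(variable, "dichotomous", groups, "Chi-square",
                           float(res.statistic), float(res.pvalue))


# ---------------------------------------------------------------------------
# regularized MANOVA
# ---------------------------------------------------------------------------

def _shrinkage_lambda(resid: np.ndarray) -> float:
    """Analytic shrinkage weight toward the diagonal (Schafer-Strimmer style).

    lambda* = sum_{i != j} Var-hat(s_ij) / sum_{i != j} s_ij^2, clipped to [0, 1].
    """
    n, k = resid.shape
    if n < 4 or k < 2:
        return 1.0
    S = resid.T @ resid / (n - 1)
    # variance of the off-diagonal sample covariances
    W = np.einsum("ni,nj->nij", resid, resid)
    Wbar = W.mean(axis=0)
    var_s = n / (n - 1) ** 3 * np.sum((W - Wbar) ** 2, axis=0)
    off = ~np.eye(k, dtype=bool)
    denom = np.sum(S[off] ** 2)
    if denom <= 0:
        return 1.0
    return float(np.clip(np.sum(var_s[off]) / denom, 0.0, 1.0))


def _rmanova_statistic(Z: np.ndarray, codes: np.ndarray, lam: float | None):
    n, k = Z.shape
    levels = np.unique(codes)
    grand = Z.mean(axis=0)
    B = np.zeros((k, k))
    resid = np.empty_like(Z)
    for g in levels:
        idx = codes == g
        mg = Z[idx].mean(axis=0)
        d = mg - grand
        B += idx.sum() * np.outer(d, d)
        resid[idx] = Z[idx] - mg
    Sw = resid.T @ resid / (n - len(levels))
    if lam is None:
        lam = _shrinkage_lambda(resid)
    D = np.diag(np.diag(Sw))
    Sreg = (1 - lam) * Sw + lam * D
    # guard against a singular regularized scatter: raise the shrinkage floor
    floor = lam
    while np.linalg.cond(Sreg) > 1e12 and floor < 1.0:
        floor = min(1.0, floor + 0.1)
        Sreg = (1 - floor) * Sw + floor * D
        warnings.warn(f"singular within-scatter; shrinkage raised to {floor:.1f}")
    stat = float(np.trace(np.linalg.solve(Sreg, B)))
    return stat, float(lam)


def rmanova(panel_matrix, factor, n_perm: int = 999, seed: int = 0,
            lam: float | None = None, factor_name: str = "") -> RManovaResult:
    """Regularized MANOVA test of a categorical factor on a compound panel.

    The panel is autoscaled; the statistic is the trace of the regularized
    within-scatter inverse times the between-group scatter; the p-value comes
    from permuting factor labels: p = max(1, #{null >= observed}) / n_perm.
    ``lam`` fixes the shrinkage weight (default: analytic choice, recomputed
    per permutation).
    """
    X = np.asarray(panel_matrix, dtype=float)
    if isinstance(panel_matrix, pd.DataFrame):
        X = panel_matrix.to_numpy(dtype=float)
    fac = pd.Series(np.asarray(factor))
    codes = fac.astype("category").cat.codes.to_numpy()
    counts = np.bincount(codes)
    if len(counts) < 2 or (counts < 2).any():
        raise ValueError("factor needs >= 2 levels with >= 2 samples each")
    n, k = X.shape
    if k > n - len(counts):
        warnings.warn("more compounds than residual degrees of freedom; "
                      "relying on shrinkage")
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd

    stat, lam_used = _rmanova_statistic(Z, codes, lam)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = _rmanova_statistic(Z, rng.permutation(codes), lam)[0]
    p = max(1, int(np.sum(null >= stat))) / n_perm
    return RManovaResult(factor=factor_name or str(fac.name or "factor"),
                         lam=lam_used, statistic=stat, p_value=float(p),
                         n_perm=n_perm, null=null)


# ---------------------------------------------------------------------------
# table one
# ---------------------------------------------------------------------------

def table_one(covariates: pd.DataFrame, groups: pd.Series,
              kinds: dict | None = None) -> pd.DataFrame:
    """Per-variable group comparison table (medians + Mann-Whitney for
    continuous, counts + chi-square for dichotomous).

    ``kinds`` maps variable name to "continuous" or "dichotomous"; unmapped
    variables are inferred (numeric with > 2 distinct values = continuous).
    Missing values are dropped per variable with the complete-case n reported.
    """
    kinds = kinds or {}
    glabels = sorted(pd.Series(groups).unique().tolist())
    if len(glabels) != 2:
        raise ValueError("table_one compares exactly two groups")
    rows = []
    for var in covariates.columns:
        col = covariates[var]
        mask_a = (groups == glabels[0]) & col.notna()
        mask_b = (groups == glabels[1]) & col.notna()
        if mask_a.sum() == 0 or mask_b.sum() == 0:
            raise ValueError(f"variable {var!r} observed in only one group")
        kind = kinds.get(var)
        if kind is None:
            numeric = pd.api.types.is_numeric_dtype(col)
            kind = "continuous" if numeric and col.nunique() > 2 else "dichotomous"
        if kind == "continuous":
            gc = mann_whitney(col[mask_a], col[mask_b], variable=var)
            summ_a, summ_b = gc.groups["a"], gc.groups["b"]
        else:
            codes = col.astype("category").cat.codes
            tab = np.array([
                [np.sum((codes[mask_a] == 1)), np.sum((codes[mask_b] == 1))],
                [np.sum((codes[mask_a] == 0)), np.sum((codes[mask_b] == 0))]])
            gc = chi_square(tab, variable=var)
            summ_a = f"{tab[0, 0]}/{tab[1, 0]}"
            summ_b = f"{tab[0, 1]}/{tab[1, 1]}"
        n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
        rows.append({"variable": var, "kind": kind,
                     glabels[0]: summ_a, glabels[1]: summ_b,
                     f"n_{glabels[0]}": n_a, f"n_{glabels[1]}": n_b,
                     "test": gc.test, "statistic": gc.statistic,
                     "p": gc.p_value})
    return pd.DataFrame(rows).set_index("variable")
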
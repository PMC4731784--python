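"""Partial least squares discriminant analysis (PLS-DA) for two-class panels.

The model follows the standard two-equation latent-variable formulation

    X = T P' + E          (decomposition of the feature matrix)
    y = T q  + f          (inner relation to class membership)
    y = X b  + r          (equivalent regression form)

where T holds mutually orthogonal score vectors (latent variables), P and q
are the X- and y-loadings, and the regression vector b = W (P'W)^-1 q chains
the weights W through the deflation history.  Fitting uses NIPALS with
deterministic initialisation, so there is no randomness in the estimator.

Class membership is coded {0, 1} (positive class = 1, by default "CIR").  Any
affine recoding of y shifts the continuous prediction affinely and therefore
leaves class probabilities and ROC analyses unchanged.

Continuous predictions are turned into group probabilities by fitting one
Gaussian per class to the training predictions and taking the equal-prior
posterior; the two class probabilities sum to one by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .datatypes import FeatureMatrix

__all__ = ["PLSModel", "fit", "predict_scores", "class_probabilities", "biplot_data"]

NIPALS_TOL = 1e-12
NIPALS_MAX_ITER = 500


@dataclass
class PLSModel:
    """Fitted PLS-DA model (weights, scores, loadings, regression vector)."""

    W: np.ndarray               # (p, a) weight vectors
    T: np.ndarray               # (n, a) training scores, mutually orthogonal
    P: np.ndarray               # (p, a) X-loadings
    q: np.ndarray               # (a,)   y-loadings
    b: np.ndarray               # (p,)   regression vector on the scaled scale
    mu: np.ndarray              # (p,)   per-compound centering
    sigma: np.ndarray           # (p,)   per-compound scaling (ones if center-only)
    y_mean: float               # intercept on the coded-y scale
    n_lv: int
    compound_ids: list
    sample_ids: list
    train_labels: np.ndarray    # original class labels of the training samples
    classes: tuple              # (negative_label, positive_label); coded (0, 1)
    scaling: str
    calibration: dict           # per-class Gaussian params fitted on training yhat
    signed_direction: pd.Series # sign of scaled mean difference positive - negative
    flags: list = field(default_factory=list)

    @property
    def positive_class(self):
        return self.classes[1]

    @property
    def negative_class(self):
        return self.classes[0]

    def scale(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mu) / self.sigma

    def fitted_yhat(self) -> np.ndarray:
        """Training predictions via the regression form y = X b + intercept."""
        Xs = self.scale_training_X_
        return Xs @ self.b + self.y_mean

    # set during fit(); the scaled training matrix is kept for sMC and biplots
    scale_training_X_: np.ndarray = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "n_lv": int(self.n_lv),
            "scaling": self.scaling,
            "compound_ids": [str(c) for c in self.compound_ids],
            "W": self.W.tolist(),
            "P": self.P.tolist(),
            "q": self.q.tolist(),
            "b": self.b.tolist(),
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
            "y_mean": float(self.y_mean),
            "calibration": {k: {kk: float(vv) for kk, vv in v.items()}
                            for k, v in self.calibration.items()},
            "flags": list(self.flags),
        }


def _code_labels(y: pd.Series, positive_class) -> tuple[np.ndarray, tuple]:
    labels = sorted(y.unique().tolist())
    if len(labels) != 2:
        raise ValueError(f"PLS-DA requires exactly two classes, got {labels}")
    if positive_class is None:
        positive_class = "CIR" if "CIR" in labels else labels[-1]
    if positive_class not in labels:
        raise ValueError(f"positive class {positive_class!r} not among {labels}")
    negative = [c for c in labels if c != positive_class][0]
    coded = (y == positive_class).to_numpy(dtype=float)
    return coded, (negative, positive_class)


def _nipals(Xs: np.ndarray, yc: np.ndarray, n_lv: int):
    """NIPALS sequence for a single response: w ∝ X'y, t = Xw, deflate X and y."""
    n, p = Xs.shape
    Xd = Xs.copy()
    yd = yc.copy()
    W = np.zeros((p, n_lv))
    T = np.zeros((n, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    for a in range(n_lv):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw < NIPALS_TOL:
            # y residual orthogonal to remaining X variation: truncate
            return W[:, :a], T[:, :a], P[:, :a], q[:a]
        w = w / nw
        # single-response NIPALS converges immediately; iterate for the contract
        for _ in range(NIPALS_MAX_ITER):
            t = Xd @ w
            tt = t @ t
            q_a = (yd @ t) / tt
            w_new = Xd.T @ (yd * q_a)
            w_new /= np.linalg.norm(w_new)
            if np.linalg.norm(w_new - w) < NIPALS_TOL:
                w = w_new
                break
            w = w_new
        t = Xd @ w
        tt = t @ t
        p_a = Xd.T @ t / tt
        q_a = yd @ t / tt
        Xd -= np.outer(t, p_a)
        yd = yd - t * q_a
        W[:, a], T[:, a], P[:, a], q[a] = w, t, p_a, q_a
    return W, T, P, q


def _fit_fixed(train: FeatureMatrix, n_lv: int, scaling: str, positive_class) -> PLSModel:
    yc, classes = _code_labels(train.y, positive_class)
    X = train.X.to_numpy(dtype=float)
    ids = list(train.compound_ids)
    flags: list[str] = []

    mu = X.mean(axis=0)
    if scaling == "autoscale":
        sigma = X.std(axis=0, ddof=1)
        constant = sigma <= np.finfo(float).eps * np.maximum(np.abs(mu), 1.0) * 10
        if constant.any():
            dropped = [ids[j] for j in np.flatnonzero(constant)]
            warnings.warn(f"dropping {len(dropped)} constant compound(s) under autoscale")
            flags.append(f"dropped_constant:{dropped}")
            keep = ~constant
            X, mu, sigma = X[:, keep], mu[keep], sigma[keep]
            ids = [c for c, k in zip(ids, keep) if k]
    elif scaling == "center":
        sigma = np.ones_like(mu)
    else:
        raise ValueError("scaling must be 'autoscale' or 'center'")

    n = X.shape[0]
    n_lv = int(min(n_lv, n - 1, X.shape[1]))
    if n_lv < 1:
        raise ValueError("n_lv must be at least 1")
    Xs = (X - mu) / sigma
    ybar = float(yc.mean())

    W, T, P, q = _nipals(Xs, yc - ybar, n_lv)
    if W.shape[1] < n_lv:
        flags.append(f"truncated_lv:{W.shape[1]}")
        n_lv = W.shape[1]
    b = W @ np.linalg.solve(P.T @ W, q)

    yhat = Xs @ b + ybar
    calibration = {}
    for code, label in ((1.0, classes[1]), (0.0, classes[0])):
        vals = yhat[yc == code]
        calibration[label] = {"mean": float(vals.mean()),
                              "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0}

    diff = Xs[yc == 1].mean(axis=0) - Xs[yc == 0].mean(axis=0)
    signed = pd.Series(np.sign(diff), index=ids)

    model = PLSModel(W=W, T=T, P=P, q=q, b=b, mu=mu, sigma=sigma, y_mean=ybar,
                     n_lv=n_lv, compound_ids=ids, sample_ids=list(train.sample_ids),
                     train_labels=train.y.to_numpy(), classes=classes, scaling=scaling,
                     calibration=calibration, signed_direction=signed, flags=flags)
    model.scale_training_X_ = Xs
    return model


def _cv_folds(labels: np.ndarray, n_folds: int) -> np.ndarray:
    """Deterministic stratified fold assignment (round-robin within class)."""
    fold = np.zeros(len(labels), dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        fold[idx] = np.arange(len(idx)) % n_folds
    return fold


def select_n_lv(train: FeatureMatrix, max_lv: int = 10, n_folds: int = 10,
                scaling: str = "autoscale", positive_class=None) -> int:
    """Pick the number of latent variables by cross-validated misclassification.

    Deterministic stratified folds; ties broken toward the smaller model.
    """
    yc, _ = _code_labels(train.y, positive_class)
    n = train.n_samples
    max_lv = max(1, min(max_lv, n - 1 - (n // n_folds) , train.n_compounds))
    folds = _cv_folds(train.y.to_numpy(), min(n_folds, n))
    errors = np.zeros(max_lv)
    for k in np.unique(folds):
        tr = train.subset(train.sample_ids[folds != k])
        te = train.subset(train.sample_ids[folds == k])
        if tr.y.nunique() < 2 or te.n_samples == 0:
            continue
        model = _fit_fixed(tr, max_lv, scaling, positive_class)
        yhat_all = _project(model, te)[0]
        yte = (te.y == model.positive_class).to_numpy(dtype=float)
        for a in range(1, max_lv + 1):
            if a <= model.n_lv:
                b_a = model.W[:, :a] @ np.linalg.solve(model.P[:, :a].T @ model.W[:, :a],
                                                       model.q[:a])
                Xs = model.scale(te.X[model.compound_ids].to_numpy(float))
                yh = Xs @ b_a + model.y_mean
            else:
                yh = yhat_all
            errors[a - 1] += np.sum((yh >= 0.5) != (yte == 1.0))
    return int(np.argmin(errors) + 1)


def fit(train: FeatureMatrix, n_lv="auto", scaling: str = "autoscale",
        positive_class=None) -> PLSModel:
    """Fit a two-class PLS-DA model.

    Parameters
    ----------
    train : FeatureMatrix
        Training data containing exactly two classes.
    n_lv : int or "auto"
        Number of latent variables; "auto" selects by 10-fold cross-validated
        misclassification within the training set.
    scaling : {"autoscale", "center"}
        Autoscaling (mean-center + unit variance, the metabolomics default) or
        mean-centering only.
    positive_class : label, optional
        Class coded 1 (default "CIR" when present, else the lexicographically
        last label).
    """
    if n_lv == "auto":
        n_lv = select_n_lv(train, scaling=scaling, positive_class=positive_class)
    return _fit_fixed(train, int(n_lv), scaling, positive_class)


def _project(model: PLSModel, newdata: FeatureMatrix):
    missing = [c for c in model.compound_ids if c not in newdata.X.columns]
    if missing:
        raise KeyError(f"new data lacks training compounds: {missing}")
    Xs = model.scale(newdata.X[model.compound_ids].to_numpy(dtype=float))
    yhat = Xs @ model.b + model.y_mean
    R = model.W @ np.linalg.inv(model.P.T @ model.W)
    T_new = Xs @ R
    return yhat, T_new


def predict_scores(model: PLSModel, newdata: FeatureMatrix):
    """Continuous predictions yhat = X_scaled b + intercept, plus projected scores.

    Columns of ``newdata`` are aligned to the training compounds by ID; a
    missing compound is an error (listed in the message).
    """
    yhat, T_new = _project(model, newdata)
    return pd.Series(yhat, index=newdata.sample_ids, name="yhat"), T_new


def class_probabilities(model: PLSModel, yhat) -> pd.DataFrame:
    """Equal-prior Gaussian posterior per class from the continuous prediction.

    Returns a DataFrame with one column per class; each row sums to one
    exactly.  If a training class had zero variance the posterior degenerates
    and a distance-based softmax is used instead (with a warning).
    """
    index = yhat.index if isinstance(yhat, pd.Series) else None
    vals = np.asarray(yhat, dtype=float)
    neg, pos = model.classes
    cal_p, cal_n = model.calibration[pos], model.calibration[neg]
    if cal_p["sd"] <= 0 or cal_n["sd"] <= 0:
        warnings.warn("zero within-class variance; using distance-based softmax")
        d_p = -np.abs(vals - cal_p["mean"])
        d_n = -np.abs(vals - cal_n["mean"])
        m = np.maximum(d_p, d_n)
        ep, en = np.exp(d_p - m), np.exp(d_n - m)
    else:
        lp = norm.logpdf(vals, cal_p["mean"], cal_p["sd"])
        ln = norm.logpdf(vals, cal_n["mean"], cal_n["sd"])
        m = np.maximum(lp, ln)
        ep, en = np.exp(lp - m), np.exp(ln - m)
    p_pos = ep / (ep + en)
    return pd.DataFrame({pos: p_pos, neg: 1.0 - p_pos}, index=index)


def biplot_data(model: PLSModel) -> dict:
    """Score coordinates, loading arrows and loading-angle cosines for a bi-plot.

    Requires at least two latent variables.  The angle cosine between two
    compounds' loading vectors reflects their correlation; the signed class
    direction is the sign of the scaled mean difference (positive - negative
    class) of each compound.
    """
    if model.n_lv < 2:
        raise ValueError("bi-plot requires at least 2 latent variables")
    scores = pd.DataFrame(model.T[:, :2], columns=["LV1", "LV2"],
                          index=model.sample_ids)
    scores["class"] = model.train_labels
    loadings = pd.DataFrame(model.P[:, :2], columns=["LV1", "LV2"],
                            index=model.compound_ids)
    L = model.P[:, :2]
    norms = np.linalg.norm(L, axis=1)
    norms[norms == 0] = 1.0
    U = L / norms[:, None]
    cosines = pd.DataFrame(U @ U.T, index=model.compound_ids,
                           columns=model.compound_ids)
    return {"scores": scores, "loadings": loadings,
            "loading_cosines": cosines,
            "signed_direction": model.signed_direction}
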
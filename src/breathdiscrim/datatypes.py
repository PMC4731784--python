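"""Core in-memory containers shared across the pipeline.

The central object is :class:`FeatureMatrix`, a thin wrapper around a pandas
DataFrame of relative VOC abundances (samples x compounds) together with the
class label of each sample and an optional covariate table (age, BMI, sex,
smoking, etiology, drug flags).  Raw single-sample chromatograms are held as
:class:`Breathogram` objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FeatureMatrix", "Breathogram"]


@dataclass
class FeatureMatrix:
    """Samples x compounds abundance matrix with labels and covariates.

    Parameters
    ----------
    X : pandas.DataFrame
        Abundance matrix; index = sample IDs, columns = compound IDs.
        Must contain no missing values (preprocessing imputes absent peaks).
    y : pandas.Series
        Class label per sample, e.g. ``{"CIR", "CLD", "HC"}``; index must
        match ``X.index``.
    covariates : pandas.DataFrame, optional
        Per-sample metadata table aligned on the same index.
    """

    X: pd.DataFrame
    y: pd.Series
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.X = pd.DataFrame(self.X)
        self.y = pd.Series(self.y, index=self.X.index)
        if self.X.index.has_duplicates:
            raise ValueError("duplicate sample IDs")
        if self.X.columns.has_duplicates:
            raise ValueError("duplicate compound IDs")
        if not self.X.index.equals(self.y.index):
            raise ValueError("X and y are not aligned on sample IDs")
        if self.X.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        if self.covariates is not None:
            self.covariates = self.covariates.loc[self.X.index]

    # -- convenience accessors -------------------------------------------------
    @property
    def sample_ids(self) -> pd.Index:
        return self.X.index

    @property
    def compound_ids(self) -> pd.Index:
        return self.X.columns

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_compounds(self) -> int:
        return self.X.shape[1]

    def subset(self, sample_ids) -> "FeatureMatrix":
        """Row-subset by sample ID, carrying labels and covariates along."""
        cov = self.covariates.loc[sample_ids] if self.covariates is not None else None
        return FeatureMatrix(self.X.loc[sample_ids], self.y.loc[sample_ids], cov)

    def select_compounds(self, compound_ids) -> "FeatureMatrix":
        """Column-subset to a compound panel (order of ``compound_ids`` kept)."""
        missing = [c for c in compound_ids if c not in self.X.columns]
        if missing:
            raise KeyError(f"compounds not in matrix: {missing}")
        return FeatureMatrix(self.X.loc[:, list(compound_ids)], self.y, self.covariates)

    def log_abundances(self) -> "FeatureMatrix":
        """Natural-log transform of the abundance matrix.

        Peak areas are positive and right-skewed (log-normal-like); modelling
        on the log scale is the standard variance-stabilizing choice before
        autoscaling.  Requires strictly positive values.
        """
        if (self.X.to_numpy() <= 0).any():
            raise ValueError("log transform requires strictly positive abundances")
        return FeatureMatrix(np.log(self.X), self.y, self.covariates)

    def classes(self) -> list:
        return sorted(self.y.unique().tolist())

    def restrict_classes(self, labels) -> "FeatureMatrix":
        keep = self.y.isin(list(labels))
        return self.subset(self.X.index[keep])

    # -- text I/O --------------------------------------------------------------
    def to_csv(self, features_path, metadata_path=None, sep: str = "\t") -> None:
        out = self.X.copy()
        out.index.name = "sample_id"
        out.to_csv(features_path, sep=sep)
        if metadata_path is not None:
            meta = pd.DataFrame({"class": self.y})
            if self.covariates is not None:
                meta = meta.join(self.covariates)
            meta.index.name = "sample_id"
            meta.to_csv(metadata_path, sep=sep)

    @classmethod
    def from_csv(cls, features_path, metadata_path=None, sep: str = "\t") -> "FeatureMatrix":
        X = pd.read_csv(features_path, sep=sep, index_col=0)
        if metadata_path is not None:
            meta = pd.read_csv(metadata_path, sep=sep, index_col=0)
            y = meta["class"]
            cov = meta.drop(columns=["class"]) if meta.shape[1] > 1 else None
        else:
            y = pd.Series("unknown", index=X.index)
            cov = None
        return cls(X, y, cov)


@dataclass
class Breathogram:
    """One sample's chromatographic trace: retention-time grid + intensities."""

    sample_id: str
    rt: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.ndim != 1 or self.rt.shape != self.intensity.shape:
            raise ValueError("rt and intensity must be 1-D and equal length")
        if np.any(np.diff(self.rt) <= 0):
            raise ValueError("retention-time grid must be strictly increasing")

    def copy_with(self, intensity: np.ndarray) -> "Breathogram":
        return Breathogram(self.sample_id, self.rt, np.asarray(intensity, float), dict(self.meta))

    def to_csv(self, path, sep: str = "\t") -> None:
        pd.DataFrame({"rt": self.rt, "intensity": self.intensity}).to_csv(path, sep=sep, index=False)

    @classmethod
    def from_csv(cls, path, sample_id: str | None = None, sep: str = "\t") -> "Breathogram":
        df = pd.read_csv(path, sep=sep)
        sid = sample_id if sample_id is not None else str(path)
        return cls(sid, df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())
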
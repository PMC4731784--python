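"""Synthetic breathomics cohorts: feature matrices and raw chromatograms.

The generator emulates the data structure of a GC-MS breath study of chronic
liver disease: a cohort of 34 cirrhotic (CIR), 87 non-cirrhotic (CLD) and 31
healthy-control (HC) subjects, a feature matrix of 3718 VOC relative
abundances per breath sample, an 11-compound discriminatory panel with known
signed directions (3 compounds reduced, 8 elevated in CIR), inter-compound
correlation structure, and subject covariates (age, BMI, sex, smoking,
etiology, drug flags).

Abundances are log-normal: peak areas are positive and right-skewed, and
class effects act additively on the log scale (a standardized shift of d
means the two class means differ by d within-class standard deviations).
Correlation blocks are realized through latent Gaussian factors shared
within a block, with per-compound signs so that negatively correlated pairs
(e.g. propanoic acid vs 1-hexadecanol) can coexist in one block.

Raw chromatograms are sums of Gaussian peaks (one per compound, area equal
to the sample's feature value) over a retention-time grid, plus a slow
baseline (sinusoidal drift + a monotone column-bleed ramp) and white noise;
peak apexes are jittered per sample to emulate chromatographic drift.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datatypes import Breathogram, FeatureMatrix

__all__ = ["CohortDesign", "SyntheticCohort", "PeakModel", "default_design",
           "generate_feature_matrix", "generate_chromatograms"]

# signed directions of the discriminatory panel: (-) reduced, (+) elevated in CIR
PANEL_SIGNS = (-1, +1, +1, +1, +1, +1, +1, +1, -1, -1, +1)


@dataclass
class CohortDesign:
    """Full description of a synthetic cohort; same design + seed = same data."""

    n_per_class: dict = field(default_factory=lambda: {"CIR": 34, "CLD": 87, "HC": 31})
    n_compounds: int = 3718
    effect_sizes: dict = field(default_factory=dict)   # compound index -> signed shift (log-SD units)
    contrast: tuple = ("CIR", "CLD")                   # classes carrying the planted effect
    correlation_blocks: list = field(default_factory=list)  # (indices, rho, signs | None)
    noise_sd: float = 1.0                              # within-class SD on the log scale
    baseline_log_mean: float = 2.0                     # typical log peak area
    covariate_spec: dict | None = None                 # per-class covariate distributions
    confounding: dict | None = None                    # optional covariate -> feature hook
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_per_class.values()):
            raise ValueError("class sizes must be positive")
        if self.n_compounds <= 0:
            raise ValueError("n_compounds must be positive")
        bad = [j for j in self.effect_sizes if not 0 <= j < self.n_compounds]
        if bad:
            raise ValueError(f"effect indices out of range: {bad}")
        for blk in self.correlation_blocks:
            idx, rho = blk[0], blk[1]
            if not abs(rho) < 1:
                raise ValueError("pairwise correlation must satisfy |rho| < 1")
            if any(not 0 <= j < self.n_compounds for j in idx):
                raise ValueError("correlation-block index out of range")

    @property
    def n_discriminatory(self) -> int:
        return len(self.effect_sizes)


@dataclass
class SyntheticCohort:
    features: FeatureMatrix
    truth: pd.DataFrame            # columns: compound, index, sign, effect_size
    design: CohortDesign

    @property
    def truth_compounds(self) -> list:
        return self.truth["compound"].tolist()

    def truth_to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"panel": self.truth.to_dict(orient="records"),
                       "design": {k: v for k, v in asdict(self.design).items()
                                  if k != "covariate_spec"}}, fh, indent=2, default=str)


def default_design(n_compounds: int = 3718, effect_magnitude: float = 1.5,
                   n_per_class: dict | None = None, seed: int = 0,
                   noise_sd: float = 1.0) -> CohortDesign:
    """Cohort design mirroring the study layout (34 CIR / 87 CLD / 31 HC,
    11 discriminatory compounds with the panel's signed directions, and a
    correlation block linking three of them: two positively correlated
    elevated compounds and one negatively correlated reduced compound).

    Effect magnitudes are free parameters of the generator (the study reports
    directions only); the default of 1.5 within-class SDs gives a clearly
    separable but imperfect classifier, matching a strong biomarker panel.
    """
    n_disc = len(PANEL_SIGNS)
    if n_compounds < n_disc:
        raise ValueError("need at least as many compounds as panel members")
    # spread panel compounds across the matrix deterministically
    idx = np.linspace(0, n_compounds - 1, n_disc).astype(int)
    effects = {int(j): float(s) * effect_magnitude for j, s in zip(idx, PANEL_SIGNS)}
    # emulate the observed structure: propanoic acid (panel 2) and octane
    # (panel 3) positively correlated, 1-hexadecanol (panel 9) anti-correlated
    blocks = [((int(idx[1]), int(idx[2]), int(idx[8])), 0.6, (+1, +1, -1))]
    return CohortDesign(n_per_class=n_per_class or {"CIR": 34, "CLD": 87, "HC": 31},
                        n_compounds=n_compounds, effect_sizes=effects,
                        correlation_blocks=blocks, noise_sd=noise_sd, seed=seed)


def _block_signs(design: CohortDesign) -> dict:
    """Resolve per-compound factor signs; reject inconsistent overlaps."""
    signs: dict[int, list] = {}
    for bi, blk in enumerate(design.correlation_blocks):
        idx, rho = blk[0], blk[1]
        s = blk[2] if len(blk) > 2 and blk[2] is not None else tuple(1 for _ in idx)
        if len(s) != len(idx):
            raise ValueError("signs must match block indices")
        for j, sj in zip(idx, s):
            prev = signs.get(j)
            if prev is not None and prev[0] != sj:
                raise ValueError(
                    f"compound {j} appears in overlapping correlation blocks "
                    f"with inconsistent signs ({prev[0]} vs {sj})")
            signs[j] = (sj, bi)
    return signs


DEFAULT_COVARIATES = {
    # per class: (age median-ish mean, sd), (bmi mean, sd), P(male), P(smoker)
    "CIR": {"age": (58, 11), "bmi": (26.5, 4.5), "p_male": 21 / 34, "p_smoker": 12 / 34},
    "CLD": {"age": (52, 12), "bmi": (29.0, 5.5), "p_male": 47 / 87, "p_smoker": 20 / 87},
    "HC":  {"age": (47, 13), "bmi": (24.7, 3.0), "p_male": 0.52, "p_smoker": 0.2},
}
ETIOLOGIES = ("alcohol", "viral", "autoimmune", "metabolic", "other")
DRUGS = ("antibiotics", "steroids", "immunosuppressives", "laxatives", "ppi", "udca")


def _covariates(rng: np.random.Generator, labels: np.ndarray,
                spec: dict | None) -> pd.DataFrame:
    spec = spec or DEFAULT_COVARIATES
    n = len(labels)
    rows = {"age": np.empty(n), "bmi": np.empty(n),
            "sex": np.empty(n, dtype=object), "smoking": np.zeros(n, dtype=int),
            "etiology": np.empty(n, dtype=object)}
    for d in DRUGS:
        rows[d] = np.zeros(n, dtype=int)
    for cls in np.unique(labels):
        m = labels == cls
        cs = spec.get(cls, DEFAULT_COVARIATES.get(cls, DEFAULT_COVARIATES["HC"]))
        k = int(m.sum())
        rows["age"][m] = np.clip(rng.normal(*cs["age"], size=k), 18, 90)
        rows["bmi"][m] = np.clip(rng.normal(*cs["bmi"], size=k), 15, 55)
        rows["sex"][m] = np.where(rng.random(k) < cs["p_male"], "M", "F")
        rows["smoking"][m] = (rng.random(k) < cs["p_smoker"]).astype(int)
        if cls == "HC":
            rows["etiology"][m] = "none"
        else:
            rows["etiology"][m] = rng.choice(ETIOLOGIES, size=k)
        for d in DRUGS:
            if cls != "HC":
                rows[d][m] = (rng.random(k) < 0.25).astype(int)
    return pd.DataFrame(rows)


def generate_feature_matrix(design: CohortDesign) -> SyntheticCohort:
    """Draw a synthetic cohort's feature matrix from the stated design.

    Log abundances are baseline + class shift + correlated Gaussian noise;
    abundances are the exponential, hence strictly positive.  Planted
    compounds shift by ``effect_sizes[j] * noise_sd`` on the log scale
    between the two contrast classes (split symmetrically); all other
    compounds have zero expected class difference.
    """
    rng = np.random.default_rng(design.seed)
    signs = _block_signs(design)

    labels = np.concatenate([[cls] * n for cls, n in design.n_per_class.items()])
    n = len(labels)
    p = design.n_compounds

    Z = rng.standard_normal((n, p))
    if design.correlation_blocks:
        factors = rng.standard_normal((n, len(design.correlation_blocks)))
        for j, (sj, bi) in signs.items():
            rho = abs(design.correlation_blocks[bi][1])
            Z[:, j] = np.sqrt(1 - rho) * Z[:, j] + sj * np.sqrt(rho) * factors[:, bi]

    log_x = design.baseline_log_mean + design.noise_sd * Z
    hi, lo = design.contrast
    for j, d in design.effect_sizes.items():
        shift = d * design.noise_sd
        log_x[labels == hi, j] += shift / 2.0
        log_x[labels == lo, j] -= shift / 2.0

    cov = _covariates(rng, labels, design.covariate_spec)
    if design.confounding:
        # optional hook: covariate value scales extra log-abundance on chosen compounds
        for var, mapping in design.confounding.items():
            v = pd.to_numeric(cov[var], errors="coerce").fillna(0).to_numpy()
            v = (v - v.mean()) / (v.std() or 1.0)
            for j, beta in mapping.items():
                log_x[:, int(j)] += beta * v

    compound_ids = [f"VOC{j + 1:04d}" for j in range(p)]
    sample_ids = [f"S{i + 1:03d}_{labels[i]}" for i in range(n)]
    X = pd.DataFrame(np.exp(log_x), index=sample_ids, columns=compound_ids)
    y = pd.Series(labels, index=sample_ids, name="class")
    cov.index = pd.Index(sample_ids)

    truth = pd.DataFrame(
        [{"compound": compound_ids[j], "index": int(j),
          "sign": int(np.sign(d)) if d else 0, "effect_size": float(d)}
         for j, d in sorted(design.effect_sizes.items())])
    if truth.empty:
        truth = pd.DataFrame(columns=["compound", "index", "sign", "effect_size"])
    fm = FeatureMatrix(X, y, cov)
    return SyntheticCohort(features=fm, truth=truth, design=design)


# ---------------------------------------------------------------------------
# raw chromatograms
# ---------------------------------------------------------------------------

@dataclass
class PeakModel:
    """Parameters of the synthetic chromatogram front-end."""

    rt_max: float = 1800.0           # seconds
    n_points: int = 6000
    peak_width_range: tuple = (1.5, 4.0)   # Gaussian sigma range, seconds
    jitter_sd: float = 0.0           # per-sample apex jitter, seconds
    drift_amplitude: float = 0.0     # slow sinusoidal baseline amplitude
    bleed_slope: float = 0.0         # monotone ramp, intensity units over the run
    noise_sd: float = 0.0            # white-noise SD
    margin: float = 30.0             # keep peaks away from the run edges


def generate_chromatograms(cohort: SyntheticCohort, peak_model: PeakModel | None = None,
                           seed: int | None = None) -> list[Breathogram]:
    """Render each sample's feature vector as a chromatographic trace.

    Every compound gets a fixed apex position on the retention axis (evenly
    spaced, deterministic per design) and a fixed Gaussian width; a sample's
    trace is the sum of its peaks (area = feature value) plus baseline drift,
    a bleed ramp, and white noise.  Apexes are jittered per sample.
    """
    pm = peak_model or PeakModel()
    fm = cohort.features
    p = fm.n_compounds
    rng = np.random.default_rng(cohort.design.seed + 1 if seed is None else seed)

    rt = np.linspace(0.0, pm.rt_max, pm.n_points)
    span = pm.rt_max - 2 * pm.margin
    if span <= 0 or (p > 1 and span / (p - 1) <= 0):
        raise ValueError("retention axis too short to place all peaks")
    centers = (np.linspace(pm.margin, pm.rt_max - pm.margin, p)
               if p > 1 else np.array([pm.rt_max / 2]))
    min_spacing = span / max(p - 1, 1)
    if min_spacing < 1e-9:
        raise ValueError("retention axis too short to place all peaks")
    widths = rng.uniform(*pm.peak_width_range, size=p)

    out = []
    X = fm.X.to_numpy(dtype=float)
    for i, sid in enumerate(fm.sample_ids):
        jitter = rng.normal(0.0, pm.jitter_sd, size=p) if pm.jitter_sd > 0 else np.zeros(p)
        signal = np.zeros_like(rt)
        for j in range(p):
            c, w = centers[j] + jitter[j], widths[j]
            lo = np.searchsorted(rt, c - 6 * w)
            hi = np.searchsorted(rt, c + 6 * w)
            signal[lo:hi] += X[i, j] / (w * np.sqrt(2 * np.pi)) * np.exp(
                -0.5 * ((rt[lo:hi] - c) / w) ** 2)
        baseline = pm.bleed_slope * (rt / pm.rt_max)
        if pm.drift_amplitude:
            phase = rng.uniform(0, 2 * np.pi)
            baseline = baseline + pm.drift_amplitude * (
                1 + np.sin(2 * np.pi * rt / pm.rt_max + phase)) / 2
        noise = rng.normal(0.0, pm.noise_sd, size=rt.shape) if pm.noise_sd > 0 else 0.0
        out.append(Breathogram(str(sid), rt, signal + baseline + noise,
                               meta={"centers": centers + jitter, "widths": widths}))
    return out
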
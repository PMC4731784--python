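import numpy as np
import pandas as pd
import pytest

from breathdiscrim import synthetic
from breathdiscrim.datatypes import FeatureMatrix


def small_cohort(n_per_class=None, n_compounds=100, effect=1.5, seed=0,
                 correlation_blocks=None):
    """Planted two-class cohort at reduced dimensions for fast tests."""
    n_per_class = n_per_class or {"CIR": 27, "CLD": 27}
    idx = np.linspace(0, n_compounds - 1, 11).astype(int)
    effects = {int(j): float(s) * effect
               for j, s in zip(idx, synthetic.PANEL_SIGNS)}
    design = synthetic.CohortDesign(
        n_per_class=n_per_class, n_compounds=n_compounds,
        effect_sizes=effects, correlation_blocks=correlation_blocks or [],
        seed=seed)
    return synthetic.generate_feature_matrix(design)


def null_cohort(n_per_class=None, n_compounds=100, seed=0):
    design = synthetic.CohortDesign(
        n_per_class=n_per_class or {"CIR": 27, "CLD": 27},
        n_compounds=n_compounds, effect_sizes={}, seed=seed)
    return synthetic.generate_feature_matrix(design)


@pytest.fixture
def planted():
    """Cohort with a clearly planted 11-compound panel."""
    return small_cohort(seed=42)


@pytest.fixture
def planted_features(planted):
    """Two-class view on the log-abundance scale (the modelling scale)."""
    return planted.features.restrict_classes(["CIR", "CLD"]).log_abundances()


@pytest.fixture
def null_features():
    return null_cohort(seed=7).features.restrict_classes(["CIR", "CLD"]).log_abundances()


def random_feature_matrix(rng, n=12, p=6, classes=("CLD", "CIR")):
    """Unstructured random two-class matrix for oracle comparisons."""
    X = pd.DataFrame(np.exp(rng.standard_normal((n, p))),
                     index=[f"s{i}" for i in range(n)],
                     columns=[f"c{j}" for j in range(p)])
    y = pd.Series([classes[i % 2] for i in range(n)], index=X.index)
    return FeatureMatrix(X, y)
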
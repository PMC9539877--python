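import numpy as np
import pandas as pd
import pytest

from finnet.dataset import CATEGORICAL, CONTINUOUS, FeatureMatrix, FeatureMeta, preprocess
from finnet.synth import SynthConfig, generate_synthetic_dataset


def make_matrix(columns: dict, kinds: dict | None = None, categories: dict | None = None,
                ontology: dict | None = None, preprocessed: bool = False) -> FeatureMatrix:
    """Build a FeatureMatrix from name -> values, with optional metadata."""
    kinds = kinds or {}
    categories = categories or {}
    ontology = ontology or {}
    values = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in columns.items()})
    values.index = [f"g{i}" for i in range(len(values))]
    metas = []
    for name in values.columns:
        kind = kinds.get(name)
        if kind is None:
            nonmiss = values[name].dropna()
            kind = CATEGORICAL if nonmiss.isin([0.0, 1.0]).all() and len(nonmiss) else CONTINUOUS
        metas.append(FeatureMeta(name=name, category=categories.get(name, "unknown"),
                                 kind=kind, ontology_id=ontology.get(name)))
    return FeatureMatrix(values=values, features=metas, preprocessed=preprocessed)


@pytest.fixture(scope="session")
def small_synth():
    """A small, fast synthetic dataset shared by read-only tests."""
    cfg = SynthConfig(n_genes=300, n_blocks=2, n_noise_features=5,
                      n_term_parents=1, missing_rate=0.05, seed=11)
    matrix, truth = generate_synthetic_dataset(cfg)
    return matrix, truth, cfg


@pytest.fixture(scope="session")
def small_synth_preprocessed(small_synth):
    matrix, truth, cfg = small_synth
    return preprocess(matrix), truth, cfg
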
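import numpy as np
import pandas as pd
import pytest

import igensigrx as ig


SMALL_COHORT = dict(
    n_samples=120,
    n_genes=150,
    n_sensitive_genes=12,
    n_resistant_genes=12,
)


@pytest.fixture(scope="session")
def small_cohort():
    """One small synthetic cohort with planted signal, shared across tests."""
    cfg = ig.GeneratorConfig(seed=101, **SMALL_COHORT)
    expr, muts, y, truth = ig.generate_cohort(cfg)
    return cfg, expr, muts, y, truth


@pytest.fixture(scope="session")
def small_features(small_cohort):
    cfg, expr, muts, y, truth = small_cohort
    fm = ig.cohort_feature_matrix(expr, muts)
    return fm


@pytest.fixture(scope="session")
def small_corpus(small_cohort, small_features):
    cfg, *_ = small_cohort
    return ig.generate_background(cfg, small_features.index)


@pytest.fixture(scope="session")
def small_model(small_cohort, small_features, small_corpus):
    cfg, expr, muts, y, truth = small_cohort
    return ig.train(small_features, y, small_corpus)


def random_binary(rng, n, require_nonconstant=True):
    while True:
        v = rng.integers(0, 2, n)
        if not require_nonconstant or v.min() != v.max():
            return v
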
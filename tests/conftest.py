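"""Shared fixtures: small handcrafted cohorts and session-scoped simulations."""

import numpy as np
import pandas as pd
import pytest

import qherit as q


@pytest.fixture
def toy_cohort():
    """Six sibs in three families, two phenotypes, handcrafted values."""
    data = pd.DataFrame({
        "family_id": ["f1", "f1", "f2", "f2", "f2", "f3"],
        "person_id": ["a", "b", "c", "d", "e", "g"],
        "sex": ["F", "M", "F", "F", "M", "M"],
        "age": [40.0, 42.0, 35.0, 37.0, 39.0, 50.0],
        "leptin": [10.0, 8.0, 15.0, 20.0, 12.0, 9.0],
        "leptin_receptor": [20.0, 16.0, 25.0, 25.0, 24.0, 18.0],
    })
    return q.Cohort(data)


@pytest.fixture
def two_family_pairs():
    """Two 2-sib families with values (1,3) and (2,6): slope -6/14 by hand."""
    data = pd.DataFrame({
        "family_id": ["f1", "f1", "f2", "f2"],
        "person_id": ["a", "b", "c", "d"],
        "sex": ["F", "M", "F", "M"],
        "age": [30.0] * 4,
        "leptin": [1.0, 3.0, 2.0, 6.0],
    })
    cohort = q.Cohort(data)
    pv = cohort.phenotype("leptin")
    return q.build_pairs(cohort, pv, pv)


def _pairs_from_cohort(cohort, transform="identity", dep_sex_filter="all"):
    pv = q.adjust_phenotype(cohort, cohort.phenotype("leptin", transform=transform))
    return q.build_pairs(cohort, pv, pv, dep_sex_filter=dep_sex_filter)


@pytest.fixture(scope="session")
def flat_null_pairs():
    """Bivariate-normal sibs (rho = 0.3, 1500 size-2 families), adjusted pairs."""
    cfg = q.SyntheticConfig(n_families=1500, family_size_probs={2: 1.0},
                            sib_correlation=0.3, seed=20260101)
    cohort, truth = q.generate(cfg)
    return _pairs_from_cohort(cohort), truth


@pytest.fixture(scope="session")
def paperlike_cohort():
    """Calibrated right-skewed cohort at study scale."""
    cfg = q.SyntheticConfig.paper_like(seed=20260102)
    cohort, truth = q.generate(cfg)
    return cohort, truth


@pytest.fixture(scope="session")
def skewed_qsf(paperlike_cohort):
    """Slope function with bootstrap VCV on the skewed cohort (coarse grid)."""
    cohort, _ = paperlike_cohort
    pairs = _pairs_from_cohort(cohort)
    return q.bootstrap_vcv(pairs, q.QuantileGrid.coarse(5), n_boot=100,
                           seed=20260103)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
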
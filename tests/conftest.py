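"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from uvbgweis.genotypes import GenotypeMatrix
from uvbgweis.gweis import prepare_phenotype
from uvbgweis.simulate import SimConfig, simulate_cohort, simulate_genotypes


def make_cohort(g, seed=0, **sim_kwargs):
    """Cohort + truth for a genotype matrix, exposure drawn gamma(5, 20)."""
    rng = np.random.default_rng(seed + 10_000)
    exposures = pd.DataFrame(
        {
            "participant_id": g.sample_ids,
            "cwduvb": rng.gamma(5.0, 20.0, g.n_samples),
        }
    )
    cfg = SimConfig(seed=seed, n_samples=g.n_samples, n_variants=g.n_variants,
                    **sim_kwargs)
    return simulate_cohort(g, exposures, cfg)


def make_dataset(seed=0, n_samples=500, n_variants=100, **sim_kwargs):
    cfg = SimConfig(seed=seed, n_samples=n_samples, n_variants=n_variants,
                    **sim_kwargs)
    g, _ = simulate_genotypes(cfg)
    cohort, truth = make_cohort(g, seed=seed, **sim_kwargs)
    return g, cohort, truth


@pytest.fixture(scope="session")
def small_dataset():
    """500 samples x 100 variants, additive genetics."""
    return make_dataset(seed=11, n_samples=500, n_variants=100,
                        n_causal_main=10, h2_target=0.2)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def toy_genotypes(dosage, chrom=None, pos=None):
    """Wrap a raw dosage array into a GenotypeMatrix with stub metadata."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    variants = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["1"] * m,
            "pos": pos if pos is not None else 1000 * (np.arange(m) + 1),
            "id": [f"v{j}" for j in range(m)],
            "ref": "A",
            "alt": "G",
            "info_score": 1.0,
        }
    )
    sample_ids = np.array([f"S{i}" for i in range(n)], dtype=object)
    return GenotypeMatrix(sample_ids, variants, dosage)


def toy_cohort(n, y=None, exposure=None, seed=0):
    """Minimal cohort table with standard covariate columns."""
    r = np.random.default_rng(seed)
    cohort = pd.DataFrame(
        {
            "participant_id": [f"S{i}" for i in range(n)],
            "age": r.normal(57, 8, n),
            "sex": r.integers(0, 2, n).astype(float),
            "vitd_supp": (r.random(n) < 0.2).astype(float),
            "fishoil_supp": (r.random(n) < 0.3).astype(float),
            "cwduvb": exposure if exposure is not None else r.gamma(5, 20, n),
        }
    )
    for i in range(1, 11):
        cohort[f"pc{i}"] = r.standard_normal(n)
    if y is None:
        y = r.standard_normal(n)
    cohort["pheno_raw"] = np.exp(3.85 + 0.5 * np.asarray(y))
    cohort["pheno_std"] = prepare_phenotype(cohort["pheno_raw"].to_numpy())
    return cohort
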
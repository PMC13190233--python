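"""Shared fixtures: one standard synthetic study, fitted once per session."""

import numpy as np
import pandas as pd
import pytest

from gwsub import (SyntheticTruth, fit_loadings, multivariable_ldsc,
                   per_snp_effects, simulate_factor_sumstats,
                   simulate_genotype_panel)


@pytest.fixture(scope="session")
def truth():
    return SyntheticTruth(seed=1)


@pytest.fixture(scope="session")
def sim(truth):
    return simulate_factor_sumstats(truth)


@pytest.fixture(scope="session")
def cov_fit(sim):
    return multivariable_ldsc(sim.sumstats, sim.ldscores)


@pytest.fixture(scope="session")
def sub_fit(cov_fit):
    return fit_loadings(cov_fit, sz="sz", bd="bd")


@pytest.fixture(scope="session")
def latent(sim, sub_fit):
    return per_snp_effects(sim.sumstats["sz"], sim.sumstats["bd"], sub_fit,
                           sim.ref_freq)


@pytest.fixture(scope="session")
def panel(sim):
    return simulate_genotype_panel(sim, n_ind=4000, m_snps=5000, seed=1)


def toy_sumstats(n=5, seed=0, **overrides):
    """Small valid canonical table for IO/harmonization tests."""
    rng = np.random.default_rng(seed)
    eaf = rng.uniform(0.1, 0.9, n)
    beta = rng.normal(0, 0.02, n)
    se = rng.uniform(0.005, 0.02, n)
    from gwsub.sumstats import pvalues_from_z

    df = pd.DataFrame({
        "snp": [f"rs{i}" for i in range(1, n + 1)],
        "chrom": np.full(n, 1), "pos": np.arange(1, n + 1) * 1000,
        "effect_allele": ["A"] * n, "other_allele": ["G"] * n,
        "eaf": eaf, "beta": beta, "se": se,
        "pval": pvalues_from_z(beta / se), "n_eff": np.full(n, 10_000.0),
    })
    for key, val in overrides.items():
        df[key] = val
    return df


class DenseLDProvider:
    """Brute-force provider over an explicit r^2 matrix (test oracle)."""

    def __init__(self, snps: pd.DataFrame, r2: np.ndarray):
        self.snps = snps.reset_index(drop=True)
        self.r2_matrix = r2
        self._idx = {s: i for i, s in enumerate(self.snps["snp"])}

    def neighbors(self, snp_id):
        i = self._idx[snp_id]
        others = np.array([j for j in range(len(self.snps)) if j != i])
        return (self.snps["snp"].to_numpy()[others],
                self.r2_matrix[i, others],
                self.snps["chrom"].to_numpy()[others],
                self.snps["pos"].to_numpy()[others])


class NoLDProvider:
    """Provider reporting zero LD everywhere."""

    def neighbors(self, snp_id):
        empty = np.array([])
        return empty, empty, empty, empty
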
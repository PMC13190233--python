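"""Synthetic GWAS generator with a shared + trait-specific latent factor model.

Two binary-trait GWAS (schizophrenia-like ``SZ`` and bipolar-like ``BD``) are
generated so that their true per-SNP effects arise from a latent factor shared
between the traits and a factor specific to SZ, exactly the path model the
subtraction stage estimates: with the shared factor scaled to BD and the
specific factor scaled to SZ (scaling loadings fixed to 1, latent variances
fixed to 1, residual variances of the observed traits fixed to 0),

    beta_BD,j = gamma_shared,j
    beta_SZ,j = lambda * gamma_shared,j + gamma_specific,j

Two quantitative-trait GWAS (IQ-like and EA-like) are genetically correlated
with the two factors with signed correlations of opposite direction for the
specific vs the shared factor.  LD is block-diagonal with AR(1) correlation
(r^2 decays geometrically with index distance), which keeps per-SNP LD scores
exact and gives clumping something real to do.  Observed z-scores follow the
LD score regression expectation E[chi^2_j] = 1 + N h2 l_j / M, with optional
cross-trait sample-overlap correlation of the noise.

Every random draw flows from one seed through a documented
``numpy.random.SeedSequence`` split: child 0 -> allele frequencies/alleles,
child 1 -> latent effect sizes, child 2 -> z-score noise, child 3 -> genotype
panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .sumstats import LDScoreTable, pvalues_from_z

logger = logging.getLogger(__name__)

TRAITS = ("sz", "bd", "iq", "ea")
LATENTS = ("shared", "specific", "iq", "ea")

# ordered non-identical, non-palindromic allele pairs; default munging drops
# strand-ambiguous SNPs so the generator avoids creating them
_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
                 ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G")]

_SNP_SPACING_BP = 10_000
_N_CHROM = 22


@dataclass
class LDBlockModel:
    """Block-diagonal LD: within a block, r^2 between SNPs i and j is
    ``within_block_r2_decay ** |i - j|`` (signed correlation is the AR(1)
    matrix with rho = sqrt(decay), hence positive definite); zero between
    blocks.  ``n_singletons`` LD-free SNPs (LD score exactly 1) follow the
    blocks, emulating the genome's low-recombination-free regions; they pin
    the LD score regression intercept the way low-LD SNPs do in real data."""

    n_blocks: int = 500
    block_size: int = 50
    within_block_r2_decay: float = 0.8
    n_singletons: int = 25_000

    def __post_init__(self) -> None:
        if not (0.0 < self.within_block_r2_decay < 1.0):
            raise ValueError("within_block_r2_decay must be in (0,1)")
        if self.block_size < 1 or self.n_blocks < 1 or self.n_singletons < 0:
            raise ValueError("block dimensions must be positive")

    @property
    def m_snps(self) -> int:
        return self.n_blocks * self.block_size + self.n_singletons

    @property
    def n_block_snps(self) -> int:
        return self.n_blocks * self.block_size

    def correlation(self) -> np.ndarray:
        """Within-block signed correlation matrix (block_size x block_size)."""
        idx = np.arange(self.block_size)
        rho = np.sqrt(self.within_block_r2_decay)
        return rho ** np.abs(idx[:, None] - idx[None, :])

    def cholesky(self) -> np.ndarray:
        return np.linalg.cholesky(self.correlation())

    def ld_scores(self) -> np.ndarray:
        """Exact per-SNP LD scores: tiled block pattern then ones for the
        singleton stretch; every score >= 1."""
        r2 = self.correlation() ** 2
        per_block = r2.sum(axis=1)
        return np.concatenate([np.tile(per_block, self.n_blocks),
                               np.ones(self.n_singletons)])

    @classmethod
    def for_m_snps(cls, m_snps: int, block_size: int = 50,
                   within_block_r2_decay: float = 0.8,
                   singleton_fraction: float = 0.5) -> "LDBlockModel":
        if m_snps < block_size:
            block_size = max(m_snps, 1)
        n_blocks = max(1, round(m_snps * (1.0 - singleton_fraction) / block_size))
        n_singletons = max(0, m_snps - n_blocks * block_size)
        return cls(n_blocks=n_blocks, block_size=block_size,
                   within_block_r2_decay=within_block_r2_decay,
                   n_singletons=n_singletons)


def snp_map(ld: LDBlockModel) -> pd.DataFrame:
    """Chromosome/position layout: blocks are contiguous, split across 22
    chromosomes, SNPs every 10 kb (so a 500 kb window spans 50 SNPs).
    Singleton SNPs get their own size-1 blocks after the LD blocks."""
    m = ld.m_snps
    snp = np.array([f"rs{i + 1}" for i in range(m)])
    block = np.concatenate([
        np.repeat(np.arange(ld.n_blocks), ld.block_size),
        np.arange(ld.n_blocks, ld.n_blocks + ld.n_singletons),
    ])
    # balance chromosomes by SNP count, keeping each block on one chromosome
    chrom_raw = (np.arange(m) * _N_CHROM) // m + 1
    first_in_block = np.zeros(m, dtype=bool)
    first_in_block[np.unique(block, return_index=True)[1]] = True
    chrom = np.maximum.accumulate(np.where(first_in_block, chrom_raw, 0))
    pos = np.empty(m, dtype=int)
    for c in np.unique(chrom):
        sel = chrom == c
        pos[sel] = 1 + _SNP_SPACING_BP * np.arange(sel.sum())
    return pd.DataFrame({"snp": snp, "chrom": chrom.astype(int), "pos": pos,
                         "block": block})


class BlockLDProvider:
    """Pairwise r^2 lookup backed by an :class:`LDBlockModel` layout.

    Satisfies the LD-provider protocol used by clumping and instrument
    selection: ``neighbors(snp_id)`` returns every other SNP with nonzero r^2
    together with the r^2 values, positions, and chromosome.
    """

    def __init__(self, ld: LDBlockModel, snps: pd.DataFrame | None = None):
        self.model = ld
        self.snps = snps if snps is not None else snp_map(ld)
        self._index = pd.Series(np.arange(len(self.snps)),
                                index=self.snps["snp"]).to_dict()
        self._block = self.snps["block"].to_numpy()
        self._chrom = self.snps["chrom"].to_numpy()
        self._pos = self.snps["pos"].to_numpy()
        self._snp_ids = self.snps["snp"].to_numpy()
        self._decay = ld.within_block_r2_decay
        self._bs = ld.block_size

    def r2(self, snp_a: str, snp_b: str) -> float:
        ia, ib = self._index[snp_a], self._index[snp_b]
        if self._block[ia] != self._block[ib]:
            return 0.0
        return float(self._decay ** abs(ia - ib))

    def neighbors(self, snp_id: str) -> tuple[np.ndarray, np.ndarray,
                                              np.ndarray, np.ndarray]:
        """All other SNPs in the same block: (ids, r2, chrom, pos)."""
        i = self._index[snp_id]
        b = self._block[i]
        lo = int(np.searchsorted(self._block, b, side="left"))
        hi = int(np.searchsorted(self._block, b, side="right"))
        idx = np.arange(lo, hi)
        idx = idx[idx != i]
        r2 = self._decay ** np.abs(idx - i).astype(float)
        return self._snp_ids[idx], r2, self._chrom[idx], self._pos[idx]


def _default_latent_rg() -> np.ndarray:
    # order: shared, specific, IQ, EA
    return np.array([
        [1.00, 0.00, -0.07, 0.11],
        [0.00, 1.00, -0.24, -0.06],
        [-0.07, -0.24, 1.00, 0.70],
        [0.11, -0.06, 0.70, 1.00],
    ])


@dataclass
class SyntheticTruth:
    """The generating parameters against which recovery is judged.

    Defaults follow the study conditions of the source application: shared /
    specific standardized loadings on SZ of 0.679 / 0.734, observed-scale SNP
    heritabilities 0.24 (SZ), 0.16 (BD), 0.19 (IQ), 0.12 (EA), effective
    sample sizes 117,498 (SZ) and 101,962 (BD) and 100,000 for the
    quantitative traits, and latent-level genetic correlations (shared,
    specific) x (IQ, EA) of (-0.07, -0.24) and (+0.11, -0.06) with
    rg(IQ, EA) = 0.70.
    """

    lambda_std_shared: float = 0.679
    lambda_std_specific: float = 0.734
    h2: dict = field(default_factory=lambda: {
        "sz": 0.24, "bd": 0.16, "iq": 0.19, "ea": 0.12})
    latent_rg: np.ndarray = field(default_factory=_default_latent_rg)
    neff: dict = field(default_factory=lambda: {
        "sz": 117_498, "bd": 101_962, "iq": 100_000, "ea": 100_000})
    m_snps: int = 50_000
    overlap_rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.latent_rg = np.asarray(self.latent_rg, dtype=float)
        if self.latent_rg.shape != (4, 4):
            raise ValueError("latent_rg must be 4x4 over (shared, specific, IQ, EA)")
        if not np.allclose(self.latent_rg, self.latent_rg.T):
            raise ValueError("latent_rg must be symmetric")
        if not np.allclose(np.diag(self.latent_rg), 1.0):
            raise ValueError("latent_rg must have unit diagonal")
        if np.linalg.eigvalsh(self.latent_rg).min() < -1e-10:
            raise ValueError("latent_rg is not positive semi-definite")
        ssq = self.lambda_std_shared ** 2 + self.lambda_std_specific ** 2
        # degenerate corners (0 or 1) are allowed: they express the null
        # models (no specific factor / fully independent traits)
        if not (0 <= self.lambda_std_shared <= 1
                and 0 <= self.lambda_std_specific <= 1):
            raise ValueError("standardized loadings must lie in [0,1]")
        if abs(ssq - 1.0) > 0.01:
            raise ValueError(
                "squared standardized loadings must sum to 1 (residual "
                f"variance of SZ is fixed to 0); got {ssq:.4f}")
        if not (-1.0 < self.overlap_rho < 1.0):
            raise ValueError("overlap_rho must be in (-1,1)")

    # -- derived quantities ------------------------------------------------

    @property
    def lambda_unstd(self) -> float:
        """Loading of the shared factor on SZ on the standardized-beta scale
        (shared factor scaled to BD): lambda = l_shared * sqrt(h2_SZ/h2_BD)."""
        return self.lambda_std_shared * np.sqrt(self.h2["sz"] / self.h2["bd"])

    @property
    def h2_specific(self) -> float:
        """Genetic variance of the specific factor on the SZ scale."""
        return self.lambda_std_specific ** 2 * self.h2["sz"]

    @property
    def h2_shared(self) -> float:
        """Genetic variance of the shared factor on its own (BD) scale."""
        return self.h2["bd"]

    def implied_neff(self) -> dict:
        """Effective sample sizes of the two latent-factor GWAS implied by
        the subtraction identity on the standardized scale:
        ``se_specific^2 = se_SZ^2 + lambda^2 se_BD^2 - 2 lambda cov`` with
        ``se_t^2 = 1/(2pq N_t)``, so
        ``N_specific = 1 / (1/N_SZ + lambda^2/N_BD - 2 lambda rho /
        sqrt(N_SZ N_BD))`` and ``N_shared = N_BD``."""
        lam = self.lambda_unstd
        n_sz, n_bd = self.neff["sz"], self.neff["bd"]
        inv = (1.0 / n_sz + lam ** 2 / n_bd
               - 2.0 * lam * self.overlap_rho / np.sqrt(n_sz * n_bd))
        return {"specific": 1.0 / inv, "shared": float(n_bd)}

    def rg_matrix(self) -> pd.DataFrame:
        """True 6x6 genetic correlation matrix over
        (SZ, BD, SZ_specific, PSY_shared, IQ, EA)."""
        l1, l2 = self.lambda_std_shared, self.lambda_std_specific
        lam = np.array([
            [l1, l2, 0, 0],   # SZ
            [1, 0, 0, 0],     # BD
            [0, 1, 0, 0],     # SZ_specific
            [1, 0, 0, 0],     # PSY_shared
            [0, 0, 1, 0],     # IQ
            [0, 0, 0, 1],     # EA
        ])
        cov = lam @ self.latent_rg @ lam.T
        d = np.sqrt(np.diag(cov))
        rg = cov / np.outer(d, d)
        labels = ["SZ", "BD", "SZ_specific", "PSY_shared", "IQ", "EA"]
        return pd.DataFrame(rg, index=labels, columns=labels)

    def overlap_matrix(self) -> np.ndarray:
        """Cross-trait intercept matrix of the z-score noise (sample overlap
        applies to the two case-control GWAS)."""
        omega = np.eye(4)
        omega[0, 1] = omega[1, 0] = self.overlap_rho
        return omega


@dataclass
class FactorSimulation:
    """Output bundle of :func:`simulate_factor_sumstats`."""

    sumstats: dict            # trait -> canonical sumstats DataFrame
    ldscores: LDScoreTable
    true_effects: pd.DataFrame  # per-SNP latent scores and true std betas
    ld: BlockLDProvider
    truth: SyntheticTruth

    @property
    def ref_freq(self) -> pd.Series:
        """Reference effect-allele frequencies keyed by snp id."""
        return self.true_effects.set_index("snp")["eaf"]


def _trait_effect_matrix(truth: SyntheticTruth, u: np.ndarray,
                         m: int) -> np.ndarray:
    """Map unit-variance latent scores (m x 4) to true standardized per-SNP
    trait effects (m x 4, trait order sz/bd/iq/ea)."""
    b = np.empty_like(u)
    b[:, 0] = np.sqrt(truth.h2["sz"] / m) * (
        truth.lambda_std_shared * u[:, 0]
        + truth.lambda_std_specific * u[:, 1])
    b[:, 1] = np.sqrt(truth.h2["bd"] / m) * u[:, 0]
    b[:, 2] = np.sqrt(truth.h2["iq"] / m) * u[:, 2]
    b[:, 3] = np.sqrt(truth.h2["ea"] / m) * u[:, 3]
    return b


def simulate_factor_sumstats(truth: SyntheticTruth,
                             ld: LDBlockModel | None = None,
                             seed: int | None = None) -> FactorSimulation:
    """Generate the four GWAS, exact LD scores, and the generating truth.

    Within each LD block with correlation ``R`` (Cholesky factor ``L``), the
    observed z-scores are ``z = sqrt(N) R beta_true + L e`` with ``e``
    standard normal, correlated across the two case-control traits by
    ``truth.overlap_rho``; this reproduces the LD score regression
    expectations for mean chi^2 and for the cross-trait intercept.
    """
    if ld is None:
        ld = LDBlockModel.for_m_snps(truth.m_snps)
    m = ld.m_snps
    if m < 1000:
        logger.warning("m_snps=%d is small; LDSC estimates will be unstable", m)
    seq = np.random.SeedSequence(truth.seed if seed is None else seed)
    rng_frq, rng_eff, rng_noise, _ = [np.random.default_rng(s)
                                      for s in seq.spawn(4)]

    layout = snp_map(ld)
    eaf = rng_frq.uniform(0.05, 0.95, size=m)
    pair_idx = rng_frq.integers(0, len(_ALLELE_PAIRS), size=m)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])

    c4 = np.linalg.cholesky(truth.latent_rg + 1e-12 * np.eye(4))
    u = rng_eff.standard_normal((m, 4)) @ c4.T
    beta_true = _trait_effect_matrix(truth, u, m)

    omega_l = np.linalg.cholesky(truth.overlap_matrix())
    eps = rng_noise.standard_normal((m, 4)) @ omega_l.T

    R = ld.correlation()
    L = np.linalg.cholesky(R)
    bs, nb = ld.block_size, ld.n_blocks
    mb = ld.n_block_snps
    n_vec = np.array([truth.neff[t] for t in TRAITS], dtype=float)
    # batched per-block operation for the LD blocks: (nb, bs, 4) tensors;
    # singleton SNPs need no mixing
    bt = beta_true[:mb].reshape(nb, bs, 4)
    et = eps[:mb].reshape(nb, bs, 4)
    z = np.empty((m, 4))
    z[:mb] = (np.matmul(R, bt) * np.sqrt(n_vec) + np.matmul(L, et)).reshape(mb, 4)
    z[mb:] = beta_true[mb:] * np.sqrt(n_vec) + eps[mb:]

    sumstats = {}
    for k, t in enumerate(TRAITS):
        n = truth.neff[t]
        se = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)
        beta = z[:, k] * se
        sumstats[t] = pd.DataFrame({
            "snp": layout["snp"], "chrom": layout["chrom"], "pos": layout["pos"],
            "effect_allele": ea, "other_allele": oa, "eaf": eaf,
            "beta": beta, "se": se, "pval": pvalues_from_z(z[:, k]),
            "n_eff": float(n),
        })

    true_effects = pd.DataFrame({
        "snp": layout["snp"], "block": layout["block"], "eaf": eaf,
        "u_shared": u[:, 0], "u_specific": u[:, 1],
        "u_iq": u[:, 2], "u_ea": u[:, 3],
        "beta_sz": beta_true[:, 0], "beta_bd": beta_true[:, 1],
        "beta_iq": beta_true[:, 2], "beta_ea": beta_true[:, 3],
    })
    ldscores = LDScoreTable(
        table=pd.DataFrame({"snp": layout["snp"], "ldscore": ld.ld_scores()}),
        M=m)
    provider = BlockLDProvider(ld, layout)
    return FactorSimulation(sumstats=sumstats, ldscores=ldscores,
                            true_effects=true_effects, ld=provider, truth=truth)


# ---------------------------------------------------------------------------
# Genotype / phenotype panel


#: default qualification -> years-in-education mapping shipped with the
#: package.  This is the package's own default (modelled on the conventions
#: of large education-genetics studies), not a table taken from any cohort.
DEFAULT_EDUCATION_MAPPING: dict[str, float] = {
    "none": 7, "gcse": 10, "alevel": 13,
    "professional": 15, "nvq_hnc": 19, "degree": 20,
}

#: standardized couplings of the panel phenotypes to the (specific, shared)
#: latent genetic values; signs follow the truth rg matrix (EA: negative on
#: specific, positive on shared; fluid intelligence: negative on both)
DEFAULT_COUPLINGS: dict[str, tuple[float, float]] = {
    "edu_years": (-0.13, 0.14),
    "fluid_intelligence": (-0.09, -0.08),
}

_COVARIATES = ["sex", "yob"] + [f"pc{i}" for i in range(1, 7)]


@dataclass
class GenotypePanel:
    """Continuous (imputed-style) dosage panel with phenotypes/covariates.

    ``dosages`` is individuals x SNPs on the 0..2 scale, generated from the
    block LD model's Gaussian copula so that clumped polygenic-score weights
    retain their LD tagging.  ``phenotypes`` carries the constructed
    education-years and fluid-intelligence outcomes, the covariates, and the
    true latent genetic values used to build them.
    """

    dosages: np.ndarray
    snps: pd.DataFrame
    phenotypes: pd.DataFrame
    qualifications: pd.DataFrame
    couplings: Mapping[str, tuple[float, float]]

    def dosage_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, columns=self.snps["snp"],
                            index=self.phenotypes["iid"])


def _years_to_code(years: np.ndarray,
                   mapping: Mapping[str, float]) -> np.ndarray:
    codes = np.array(list(mapping.keys()))
    vals = np.array([mapping[c] for c in codes], dtype=float)
    order = np.argsort(vals)
    codes, vals = codes[order], vals[order]
    idx = np.clip(np.searchsorted(vals, years), 0, len(vals) - 1)
    lower = np.clip(idx - 1, 0, len(vals) - 1)
    use_lower = np.abs(years - vals[lower]) < np.abs(years - vals[idx])
    return np.where(use_lower, codes[lower], codes[idx])


def simulate_genotype_panel(sim: FactorSimulation, n_ind: int = 10_000,
                            m_snps: int = 5_000,
                            couplings: Mapping[str, tuple[float, float]] | None = None,
                            seed: int | None = None) -> GenotypePanel:
    """Simulate an individual-level panel tied to the factor simulation.

    A random subset of whole LD blocks totalling ``m_snps`` SNPs is taken
    from the GWAS SNPs; dosages are Hardy-Weinberg in expectation with the
    block correlation structure.  Phenotypes are built as standardized
    couplings to the (specific, shared) true genetic values plus covariate
    effects (sex, year of birth, six PC-like covariates) plus noise, then
    rescaled: education years to mean 14, SD 5; fluid intelligence to mean
    6.7, SD 2.1.  Qualification code lists consistent with the continuous
    years are emitted for the education-years derivation step.
    """
    if n_ind < 500:
        raise ValueError("n_ind must be >= 500")
    truth = sim.truth
    model = sim.ld.model
    if couplings is None:
        couplings = DEFAULT_COUPLINGS
    seq = np.random.SeedSequence(truth.seed if seed is None else seed)
    rng = np.random.default_rng(seq.spawn(4)[3])

    # the panel draws from the LD-block portion only (uniform block size
    # keeps the dosage copula a single batched operation)
    bs = model.block_size
    n_blocks_panel = max(1, min(model.n_blocks, int(round(m_snps / bs))))
    blocks = np.sort(rng.choice(model.n_blocks, size=n_blocks_panel,
                                replace=False))
    te = sim.true_effects
    sel = te["block"].isin(blocks).to_numpy()
    snp_rows = te[sel].reset_index(drop=True)
    m_panel = len(snp_rows)
    eaf = snp_rows["eaf"].to_numpy()

    L = model.cholesky().T.astype(np.float32)
    xi = rng.standard_normal((n_ind, n_blocks_panel, bs), dtype=np.float32)
    dos = np.matmul(xi, L).reshape(n_ind, m_panel)
    del xi
    eaf32 = eaf.astype(np.float32)
    # in place: latent Gaussian -> dosage on the 0..2 scale
    dos *= np.sqrt(2.0 * eaf32 * (1.0 - eaf32))
    dos += 2.0 * eaf32
    np.clip(dos, 0.0, 2.0, out=dos)

    # true genetic values via mat-vec on the raw dosages (no standardized
    # copy of the matrix): x_std @ u == dos @ (u/sd) - mean @ (u/sd)
    mu = dos.mean(axis=0)
    sd = dos.std(axis=0)

    def genetic_value(u: np.ndarray) -> np.ndarray:
        w = (u / sd).astype(np.float32)
        return dos @ w - float(mu @ w)

    g_spec = genetic_value(snp_rows["u_specific"].to_numpy())
    g_shared = genetic_value(snp_rows["u_shared"].to_numpy())
    g_spec = (g_spec - g_spec.mean()) / g_spec.std()
    g_shared = (g_shared - g_shared.mean()) / g_shared.std()

    sex = rng.integers(0, 2, size=n_ind).astype(float)
    yob = rng.integers(1940, 1970, size=n_ind).astype(float)
    pcs = rng.standard_normal((n_ind, 6))
    cov_std = np.column_stack([
        (sex - sex.mean()) / sex.std(),
        (yob - yob.mean()) / yob.std(),
        pcs,
    ])
    cov_effects = np.array([0.05, -0.05] + [0.02] * 6)

    def build(coupling: tuple[float, float], loc: float, scale: float) -> np.ndarray:
        c_spec, c_shared = coupling
        signal = c_spec * g_spec + c_shared * g_shared + cov_std @ cov_effects
        resid_var = 1.0 - c_spec ** 2 - c_shared ** 2 - (cov_effects ** 2).sum()
        if resid_var <= 0:
            raise ValueError("couplings imply > 100% explained variance")
        y = signal + rng.standard_normal(n_ind) * np.sqrt(resid_var)
        return loc + scale * y

    edu_years = build(couplings["edu_years"], 14.0, 5.0)
    fluid = build(couplings["fluid_intelligence"], 6.7, 2.1)

    iid = np.array([f"ind{i + 1}" for i in range(n_ind)])
    phenotypes = pd.DataFrame({
        "iid": iid, "edu_years": edu_years, "fluid_intelligence": fluid,
        "sex": sex, "yob": yob,
        **{f"pc{i + 1}": pcs[:, i] for i in range(6)},
        "g_specific_true": g_spec, "g_shared_true": g_shared,
    })

    # qualification codes: visit 0 bins the continuous years; ~30% report a
    # second, never-higher qualification at a later visit (exercises the
    # maximum-across-visits rule)
    code0 = _years_to_code(edu_years, DEFAULT_EDUCATION_MAPPING)
    qual_rows = [pd.DataFrame({"iid": iid, "visit": 0, "code": code0})]
    second = rng.random(n_ind) < 0.3
    vals = DEFAULT_EDUCATION_MAPPING
    codes_sorted = np.array(sorted(vals, key=vals.get))
    rank = {c: i for i, c in enumerate(codes_sorted)}
    ranks = np.array([rank[c] for c in code0])
    lower_pick = codes_sorted[rng.integers(0, ranks + 1)]
    qual_rows.append(pd.DataFrame({
        "iid": iid[second], "visit": 1, "code": lower_pick[second]}))
    qualifications = pd.concat(qual_rows, ignore_index=True)

    layout = sim.ld.snps.set_index("snp")
    gw = sim.sumstats["sz"].set_index("snp")
    snps = pd.DataFrame({
        "snp": snp_rows["snp"],
        "effect_allele": gw.loc[snp_rows["snp"], "effect_allele"].to_numpy(),
        "other_allele": gw.loc[snp_rows["snp"], "other_allele"].to_numpy(),
        "eaf": eaf,
        "chrom": layout.loc[snp_rows["snp"], "chrom"].to_numpy(),
        "pos": layout.loc[snp_rows["snp"], "pos"].to_numpy(),
    })
    return GenotypePanel(dosages=dos, snps=snps, phenotypes=phenotypes,
                         qualifications=qualifications, couplings=dict(couplings))


def write_panel(panel: GenotypePanel, outdir) -> None:
    """Write the panel as plain text: dosage matrix (iid rows, SNP columns),
    variant table, phenotype/covariate table, qualification codes."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel.dosage_frame().to_csv(outdir / "dosages.tsv", sep="\t",
                                float_format="%.4f")
    panel.snps.to_csv(outdir / "variants.tsv", sep="\t", index=False)
    panel.phenotypes.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
    panel.qualifications.to_csv(outdir / "qualifications.tsv", sep="\t",
                                index=False)


def read_panel(indir) -> GenotypePanel:
    """Read a panel written by :func:`write_panel`."""
    from pathlib import Path

    indir = Path(indir)
    dosage = pd.read_csv(indir / "dosages.tsv", sep="\t", index_col=0)
    snps = pd.read_csv(indir / "variants.tsv", sep="\t")
    phenotypes = pd.read_csv(indir / "phenotypes.tsv", sep="\t")
    qual_path = indir / "qualifications.tsv"
    if qual_path.exists():
        qualifications = pd.read_csv(qual_path, sep="\t")
    else:
        qualifications = pd.DataFrame(columns=["iid", "visit", "code"])
    return GenotypePanel(
        dosages=dosage.to_numpy(dtype=np.float32),
        snps=snps, phenotypes=phenotypes, qualifications=qualifications,
        couplings={})
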
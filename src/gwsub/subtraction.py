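"""GWAS-by-subtraction: split one disorder's genetic liability into a
component shared with a second disorder and a disorder-specific component.

The path model regresses the SZ and BD summary statistics onto two latent
variables.  The shared factor is scaled to BD (its loading on BD fixed to 1)
and the specific factor to SZ; latent variances are fixed to 1 via the
standardization below, residual variances of the observed traits to 0, and
the factors are uncorrelated.  With genetic covariance matrix ``S`` over
(SZ, BD) the model is just-identified, so the loadings have a closed form:

    lambda      = S[SZ,BD] / S[BD,BD]          (shared loading on SZ)
    v_specific  = S[SZ,SZ] - lambda^2 S[BD,BD] (specific-factor variance)

Standardized loadings divide each path's contribution by sqrt(S[SZ,SZ]); a
full V-weighted WLS SEM fit must agree with the closed form and is provided
as :func:`fit_loadings_wls` for cross-checking.  Stage 2 propagates the
loadings to per-SNP effects on the standardized (2pq) scale, giving two
derived GWAS whose effective sample sizes are then inferred from z-scores
and allele frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator

from .ldsc import GeneticCovarianceFit
from .sumstats import harmonize_alleles, pvalues_from_z, zscores

logger = logging.getLogger(__name__)


@dataclass
class SubtractionFit:
    """Stage-1 result: loadings, their SEs, and the variance decomposition."""

    lambda_shared_on_sz: float          # unstandardized, shared factor scaled to BD
    lambda_std: tuple                   # (shared, specific) standardized on SZ
    lambda_std_se: tuple
    var_explained: tuple                # (specific, shared) fractions, sum to 1
    specific_variance: float            # on the SZ genetic-variance scale
    cross_intercept: float = 0.0
    neff_specific: float | None = None
    neff_shared: float | None = None

    def to_json_dict(self) -> dict:
        return {
            "lambda_shared_on_sz": self.lambda_shared_on_sz,
            "lambda_std_shared": self.lambda_std[0],
            "lambda_std_specific": self.lambda_std[1],
            "lambda_std_shared_se": self.lambda_std_se[0],
            "lambda_std_specific_se": self.lambda_std_se[1],
            "var_explained_specific": self.var_explained[0],
            "var_explained_shared": self.var_explained[1],
            "specific_variance": self.specific_variance,
            "cross_intercept": self.cross_intercept,
            "neff_specific": self.neff_specific,
            "neff_shared": self.neff_shared,
        }


def _vech3(fit: GeneticCovarianceFit, sz: str, bd: str):
    """Extract (S_ss, S_sb, S_bb) and the matching 3x3 block of V."""
    i, j = fit.trait_index(sz), fit.trait_index(bd)
    idx = [fit.vech_index(i, i), fit.vech_index(i, j), fit.vech_index(j, j)]
    s = np.array([fit.S[i, i], fit.S[i, j], fit.S[j, j]])
    v = fit.V[np.ix_(idx, idx)]
    return s, v


def fit_loadings(fit: GeneticCovarianceFit, sz: str = "sz",
                 bd: str = "bd") -> SubtractionFit:
    """Closed-form just-identified loadings with delta-method SEs from V."""
    (s_ss, s_sb, s_bb), v = _vech3(fit, sz, bd)
    if s_bb <= 0:
        raise ValueError(f"non-positive genetic variance for {bd}")
    if s_ss <= 0:
        raise ValueError(f"non-positive genetic variance for {sz}")
    lam = s_sb / s_bb
    spec_var = s_ss - lam ** 2 * s_bb
    if spec_var <= 0:
        raise ValueError(
            "shared factor explains all genetic variance of "
            f"{sz} (implied specific variance {spec_var:.3g} <= 0)")

    l_shared = s_sb / np.sqrt(s_ss * s_bb)
    l_specific = np.sqrt(spec_var / s_ss)  # == sqrt(1 - l_shared^2)

    # delta-method gradients wrt (s_ss, s_sb, s_bb)
    g_shared = np.array([
        -s_sb / (2.0 * s_ss ** 1.5 * np.sqrt(s_bb)),
        1.0 / np.sqrt(s_ss * s_bb),
        -s_sb / (2.0 * np.sqrt(s_ss) * s_bb ** 1.5),
    ])
    u = s_sb ** 2 / (s_ss * s_bb)
    g_u = np.array([-u / s_ss, 2.0 * s_sb / (s_ss * s_bb), -u / s_bb])
    g_specific = -g_u / (2.0 * l_specific)
    se_shared = float(np.sqrt(g_shared @ v @ g_shared))
    se_specific = float(np.sqrt(g_specific @ v @ g_specific))

    prop_specific = l_specific ** 2 / (l_specific ** 2 + l_shared ** 2)
    i, j = fit.trait_index(sz), fit.trait_index(bd)
    return SubtractionFit(
        lambda_shared_on_sz=float(lam),
        lambda_std=(float(l_shared), float(l_specific)),
        lambda_std_se=(se_shared, se_specific),
        var_explained=(float(prop_specific), float(1.0 - prop_specific)),
        specific_variance=float(spec_var),
        cross_intercept=float(fit.intercepts[i, j]),
    )


def fit_loadings_wls(S: np.ndarray, V: np.ndarray,
                     tol: float = 1e-12) -> dict:
    """Iterative WLS SEM fit of the subtraction model (independent of the
    closed form): minimize the V-weighted discrepancy between vech(S) and
    the model-implied covariance over (lambda, v_shared, v_specific).

    Because the model is just-identified the minimum discrepancy is zero and
    the solution must coincide with :func:`fit_loadings`.
    """
    S = np.asarray(S, dtype=float)
    s_obs = np.array([S[0, 0], S[0, 1], S[1, 1]])
    W = np.linalg.pinv(np.asarray(V, dtype=float))
    # whiten: the discrepancy is the squared norm of Lw (s_obs - implied)
    Lw = np.linalg.cholesky(W + 1e-30 * np.eye(3)).T

    def residual(theta):
        lam, v_sh, v_sp = theta
        implied = np.array([lam ** 2 * v_sh + v_sp, lam * v_sh, v_sh])
        return Lw @ (s_obs - implied)

    x0 = np.array([0.0, max(S[1, 1], 1e-4), max(S[0, 0], 1e-4)])
    res = optimize.least_squares(residual, x0, method="lm",
                                 xtol=tol, ftol=tol, gtol=tol,
                                 max_nfev=10_000)
    lam, v_sh, v_sp = res.x
    total = lam ** 2 * v_sh + v_sp
    return {
        "lambda": float(lam),
        "v_shared": float(v_sh),
        "v_specific": float(v_sp),
        "lambda_std_shared": float(lam * np.sqrt(v_sh / total)),
        "lambda_std_specific": float(np.sqrt(abs(v_sp) / total)),
        "discrepancy": float(2.0 * res.cost),
        "converged": bool(res.success),
    }


def variance_decomposition(fit) -> tuple:
    """Proportions of the SZ genetic variance on the (specific, shared)
    factors: ``l_specific^2 / (l_specific^2 + l_shared^2)`` and complement.
    Accepts a :class:`SubtractionFit` or a (shared, specific) loading pair.
    """
    if isinstance(fit, SubtractionFit):
        l_shared, l_specific = fit.lambda_std
    else:
        l_shared, l_specific = fit
    tot = l_shared ** 2 + l_specific ** 2
    prop_specific = l_specific ** 2 / tot
    return float(prop_specific), float(1.0 - prop_specific)


def per_snp_effects(sz: pd.DataFrame, bd: pd.DataFrame, fit: SubtractionFit,
                    ref_freq: pd.Series | dict,
                    drop_palindromic: bool = True) -> pd.DataFrame:
    """Stage 2: per-SNP effects of the two latent factors.

    On the standardized (2pq) scale, the just-identified solution of the
    path model gives ``beta_shared = beta_BD`` and ``beta_specific =
    beta_SZ - lambda beta_BD``; the SE of the difference accounts for the
    per-SNP sampling covariance implied by the cross-trait LDSC intercept,
    ``cov_j = intercept_cross * se_SZ,j * se_BD,j``.  Reference allele
    frequencies come from ``ref_freq`` (snp id -> effect-allele frequency);
    SNPs missing from either GWAS or the reference are excluded and counted.
    """
    sz_h, bd_h, _ = harmonize_alleles(sz, bd, drop_palindromic=drop_palindromic)
    if not isinstance(ref_freq, pd.Series):
        ref_freq = pd.Series(ref_freq)
    p_ref = sz_h["snp"].map(ref_freq)
    missing = p_ref.isna()
    if missing.any():
        logger.info("per_snp_effects: %d SNPs without reference frequency "
                    "excluded", int(missing.sum()))
        sz_h = sz_h[~missing.to_numpy()].reset_index(drop=True)
        bd_h = bd_h[~missing.to_numpy()].reset_index(drop=True)
        p_ref = p_ref[~missing].reset_index(drop=True)
    p = p_ref.to_numpy(dtype=float)
    two_pq = 2.0 * p * (1.0 - p)

    z_sz, z_bd = zscores(sz_h), zscores(bd_h)
    n_sz = sz_h["n_eff"].to_numpy(dtype=float)
    n_bd = bd_h["n_eff"].to_numpy(dtype=float)
    se_sz = 1.0 / np.sqrt(two_pq * n_sz)
    se_bd = 1.0 / np.sqrt(two_pq * n_bd)
    b_sz = z_sz * se_sz
    b_bd = z_bd * se_bd

    lam = fit.lambda_shared_on_sz
    cov_j = fit.cross_intercept * se_sz * se_bd
    beta_specific = b_sz - lam * b_bd
    var_specific = se_sz ** 2 + lam ** 2 * se_bd ** 2 - 2.0 * lam * cov_j
    if np.any(var_specific <= 0):
        raise ValueError("negative implied per-SNP sampling variance; "
                         "check the cross-trait intercept")
    se_specific = np.sqrt(var_specific)

    out = pd.DataFrame({
        "snp": sz_h["snp"], "chrom": sz_h["chrom"], "pos": sz_h["pos"],
        "effect_allele": sz_h["effect_allele"],
        "other_allele": sz_h["other_allele"],
        "eaf": p,
        "beta_specific": beta_specific, "se_specific": se_specific,
        "p_specific": pvalues_from_z(beta_specific / se_specific),
        "beta_shared": b_bd, "se_shared": se_bd,
        "p_shared": pvalues_from_z(z_bd),
    })
    return out


def latent_to_sumstats(latent: pd.DataFrame, which: str,
                       n_eff: float) -> pd.DataFrame:
    """Repackage one latent-factor GWAS as a canonical sumstats table so it
    feeds polygenic scoring and Mendelian randomisation unchanged."""
    if which not in ("specific", "shared"):
        raise ValueError("which must be 'specific' or 'shared'")
    return pd.DataFrame({
        "snp": latent["snp"], "chrom": latent["chrom"], "pos": latent["pos"],
        "effect_allele": latent["effect_allele"],
        "other_allele": latent["other_allele"],
        "eaf": latent["eaf"],
        "beta": latent[f"beta_{which}"], "se": latent[f"se_{which}"],
        "pval": latent[f"p_{which}"], "n_eff": float(n_eff),
    })


def estimate_neff(latent: pd.DataFrame, which: str = "specific",
                  maf_window: tuple = (0.10, 0.40),
                  min_snps: int = 1000) -> float:
    """Infer the effective sample size of a latent-factor GWAS from its
    z-scores and reference allele frequencies:

        N_j = (z_j / beta_j)^2 / (2 p_j (1 - p_j))

    averaged over SNPs whose reference MAF lies inside ``maf_window``.
    Rows with a zero effect estimate are skipped.
    """
    lo, hi = maf_window
    beta = latent[f"beta_{which}"].to_numpy(dtype=float)
    se = latent[f"se_{which}"].to_numpy(dtype=float)
    p = latent["eaf"].to_numpy(dtype=float)
    maf = np.minimum(p, 1.0 - p)
    keep = (maf >= lo) & (maf <= hi) & (beta != 0)
    if keep.sum() < min_snps:
        raise ValueError(
            f"only {int(keep.sum())} SNPs inside MAF window; need >= {min_snps}")
    z = beta[keep] / se[keep]
    n_hat = (z / beta[keep]) ** 2 / (2.0 * p[keep] * (1.0 - p[keep]))
    return float(n_hat.mean())


def clump_hits(table: pd.DataFrame, ld, p_threshold: float = 5e-8,
               r2_threshold: float = 0.1, window_kb: int = 500,
               p_col: str = "pval") -> list:
    """Greedy LD clumping.

    Repeatedly take the smallest-p unassigned SNP below ``p_threshold`` as
    an index SNP and assign away every SNP within ``window_kb`` of it (same
    chromosome) with r^2 >= ``r2_threshold``.  ``ld`` follows the provider
    protocol: ``neighbors(snp_id) -> (ids, r2, chrom, pos)`` and must cover
    all candidates.  Returns index SNP ids in selection order (may be empty).
    """
    cand = table.loc[table[p_col] < p_threshold,
                     ["snp", "chrom", "pos", p_col]]
    # p-values clamped at the underflow floor tie exactly; break ties by
    # genomic coordinate so the selection is deterministic
    cand = cand.sort_values([p_col, "chrom", "pos"], kind="mergesort")
    assigned: set = set()
    index_snps: list = []
    window_bp = window_kb * 1000
    for snp, chrom, pos in zip(cand["snp"], cand["chrom"], cand["pos"]):
        if snp in assigned:
            continue
        index_snps.append(snp)
        assigned.add(snp)
        try:
            ids, r2, nb_chrom, nb_pos = ld.neighbors(snp)
        except KeyError as exc:
            raise KeyError(f"LD provider does not cover SNP {snp}") from exc
        hit = (r2 >= r2_threshold) & (nb_chrom == chrom) \
            & (np.abs(nb_pos - pos) <= window_bp)
        assigned.update(np.asarray(ids)[hit].tolist())
    return index_snps


class GwasBySubtraction(BaseEstimator):
    """Estimator interface over the two-stage subtraction.

    ``fit`` consumes a :class:`~gwsub.ldsc.GeneticCovarianceFit` holding the
    SZ and BD cells; ``transform`` maps a harmonized pair of summary-
    statistics tables to the two latent-factor GWAS.

    Parameters
    ----------
    sz, bd : str
        Trait labels inside the covariance fit.

    Fitted attributes
    -----------------
    lambda_ : unstandardized shared-factor loading on SZ.
    lambda_std_, lambda_std_se_ : standardized (shared, specific) loadings.
    var_explained_ : (specific, shared) fractions of SZ genetic variance.
    result_ : the full :class:`SubtractionFit`.
    """

    def __init__(self, sz: str = "sz", bd: str = "bd"):
        self.sz = sz
        self.bd = bd

    def fit(self, covariance_fit: GeneticCovarianceFit, y=None):
        res = fit_loadings(covariance_fit, sz=self.sz, bd=self.bd)
        self.lambda_ = res.lambda_shared_on_sz
        self.lambda_std_ = res.lambda_std
        self.lambda_std_se_ = res.lambda_std_se
        self.var_explained_ = res.var_explained
        self.cross_intercept_ = res.cross_intercept
        self.result_ = res
        return self

    def transform(self, sz_table: pd.DataFrame, bd_table: pd.DataFrame,
                  ref_freq, drop_palindromic: bool = True) -> pd.DataFrame:
        if not hasattr(self, "result_"):
            raise AttributeError("call fit() before transform()")
        latent = per_snp_effects(sz_table, bd_table, self.result_, ref_freq,
                                 drop_palindromic=drop_palindromic)
        try:
            self.result_.neff_specific = estimate_neff(latent, "specific")
            self.result_.neff_shared = estimate_neff(latent, "shared")
        except ValueError:
            logger.info("too few SNPs in the MAF window to estimate Neff")
        return latent
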
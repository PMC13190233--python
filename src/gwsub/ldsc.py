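"""LD score regression: heritability, genetic covariance, intercepts, and a
block-jackknife sampling covariance matrix for downstream structural models.

Single-trait model: ``E[chi^2_j] = 1 + N h2 l_j / M`` with a free intercept
absorbing confounding.  Cross-trait: ``E[z_a,j z_b,j] = rho_ab +
sqrt(N_a N_b) cov_g l_j / M`` where the intercept ``rho_ab`` absorbs sample
overlap.  With the regressor written as ``l_j sqrt(N_a,j N_b,j) / M`` the
slope estimates the genetic covariance directly.  All quantities stay on the
observed/effective-N scale; genetic correlation is scale-invariant so no
liability conversion is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .sumstats import LDScoreTable, zscores

logger = logging.getLogger(__name__)

MIN_SNPS = 200


@dataclass
class GeneticCovarianceFit:
    """Genetic covariance matrix ``S`` with jackknife sampling covariance
    ``V`` of ``vech(S)`` (row-major upper triangle) and the LDSC intercept
    matrix (diagonal: single-trait; off-diagonal: cross-trait overlap)."""

    traits: list
    S: np.ndarray
    V: np.ndarray
    intercepts: np.ndarray
    m_snps_used: int
    n_blocks: int
    delete_values: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        d = len(self.traits)
        k = d * (d + 1) // 2
        if self.S.shape != (d, d) or self.V.shape != (k, k):
            raise ValueError("inconsistent S/V dimensions")

    def vech_index(self, i: int, j: int) -> int:
        d = len(self.traits)
        i, j = min(i, j), max(i, j)
        return i * d - i * (i - 1) // 2 + (j - i)

    def trait_index(self, label: str) -> int:
        return self.traits.index(label)

    def se(self, label_a: str, label_b: str | None = None) -> float:
        """Jackknife SE of one cell of S."""
        i = self.trait_index(label_a)
        j = i if label_b is None else self.trait_index(label_b)
        return float(np.sqrt(self.V[self.vech_index(i, j), self.vech_index(i, j)]))

    def to_json_dict(self) -> dict:
        return {
            "traits": list(self.traits),
            "S": self.S.tolist(),
            "V": self.V.tolist(),
            "intercepts": self.intercepts.tolist(),
            "m_snps_used": int(self.m_snps_used),
            "n_blocks": int(self.n_blocks),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "GeneticCovarianceFit":
        return cls(traits=list(d["traits"]), S=np.asarray(d["S"], dtype=float),
                   V=np.asarray(d["V"], dtype=float),
                   intercepts=np.asarray(d["intercepts"], dtype=float),
                   m_snps_used=int(d["m_snps_used"]),
                   n_blocks=int(d["n_blocks"]))


def _solve_2x2(sw, sx, sxx, sy, sxy):
    """Closed-form WLS solve of y ~ 1 + x from weighted sufficient statistics
    (vectorized over leading dimensions). Returns (intercept, slope)."""
    det = sw * sxx - sx ** 2
    intercept = (sxx * sy - sx * sxy) / det
    slope = (sw * sxy - sx * sy) / det
    return intercept, slope


def _block_sums(values: np.ndarray, blocks: np.ndarray, n_blocks: int) -> np.ndarray:
    return np.bincount(blocks, weights=values, minlength=n_blocks)


def _wls_jackknife(y, x, w, blocks, n_blocks):
    """Weighted regression of y on [1, x] with delete-one-block estimates.

    Returns (intercept, slope, delete_intercepts, delete_slopes).
    """
    parts = {
        "sw": w, "sx": w * x, "sxx": w * x * x,
        "sy": w * y, "sxy": w * x * y,
    }
    per_block = {k: _block_sums(v, blocks, n_blocks) for k, v in parts.items()}
    tot = {k: v.sum() for k, v in per_block.items()}
    icept, slope = _solve_2x2(tot["sw"], tot["sx"], tot["sxx"],
                              tot["sy"], tot["sxy"])
    d_icept, d_slope = _solve_2x2(
        tot["sw"] - per_block["sw"], tot["sx"] - per_block["sx"],
        tot["sxx"] - per_block["sxx"], tot["sy"] - per_block["sy"],
        tot["sxy"] - per_block["sxy"])
    return float(icept), float(slope), d_icept, d_slope


def jackknife_se(delete_values: np.ndarray) -> float:
    """Delete-one-block jackknife standard error."""
    n = len(delete_values)
    mean = delete_values.mean()
    return float(np.sqrt((n - 1) / n * ((delete_values - mean) ** 2).sum()))


def jackknife_cov(delete_values: np.ndarray) -> np.ndarray:
    """Jackknife covariance of a matrix of delete-values (blocks x params)."""
    n = delete_values.shape[0]
    centred = delete_values - delete_values.mean(axis=0)
    return (n - 1) / n * centred.T @ centred


def nearest_psd(mat: np.ndarray, eps: float = 1e-12) -> tuple[np.ndarray, float]:
    """Project a symmetric matrix to the PSD cone by eigenvalue clipping.
    Returns the projection and the Frobenius distance moved."""
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() >= 0:
        return sym, 0.0
    clipped = np.clip(vals, eps, None)
    out = vecs @ np.diag(clipped) @ vecs.T
    out = (out + out.T) / 2.0
    return out, float(np.linalg.norm(out - sym))


class LDScoreRegression(BaseEstimator):
    """Multivariable LD score regression with a joint block jackknife.

    Parameters
    ----------
    n_blocks : int
        Contiguous jackknife blocks over the merged SNP set (200 is the
        field convention).
    n_weight_iter : int
        Iterations of the heteroskedasticity + overcounting regression
        weights (two passes after the initial ``1/l`` fit).
    chisq_max : float or None
        Per-trait chi-square cap; ``None`` uses ``max(80, 0.001 N)``.
        Capped SNPs are excluded from the regression only.

    Fitted attributes
    -----------------
    traits_, S_, V_, intercepts_, m_snps_used_, result_ (a
    :class:`GeneticCovarianceFit`), h2_ and h2_se_ (dicts per trait).
    """

    def __init__(self, n_blocks: int = 200, n_weight_iter: int = 2,
                 chisq_max: float | None = None):
        self.n_blocks = n_blocks
        self.n_weight_iter = n_weight_iter
        self.chisq_max = chisq_max

    # -- internals ---------------------------------------------------------

    def _pair_weights(self, ell, xreg, h2_i, h2_j, n_i, n_j, cov, icept, M):
        term_i = np.maximum(1.0 + n_i * max(h2_i, 0.0) * ell / M, 0.1)
        term_j = np.maximum(1.0 + n_j * max(h2_j, 0.0) * ell / M, 0.1)
        cross = cov * xreg + icept
        var = term_i * term_j + cross ** 2
        return 1.0 / (np.maximum(ell, 1.0) * np.maximum(var, 0.05))

    def _fit_pair(self, zi, zj, ell, n_i, n_j, M, blocks, mask,
                  h2_i=None, h2_j=None):
        """One pair regression; for i == j this is the chi-square regression.

        When ``h2_i``/``h2_j`` are None (self pair), the heritability used in
        the weights is the current slope estimate itself.
        """
        y = (zi * zj)[mask]
        ell_m = ell[mask]
        xreg = (ell_m * np.sqrt(n_i[mask] * n_j[mask]) / M)
        bl = blocks[mask]
        self_pair = h2_i is None
        w = 1.0 / np.maximum(ell_m, 1.0)
        icept, slope, d_icept, d_slope = _wls_jackknife(
            y, xreg, w, bl, self.n_blocks)
        for _ in range(self.n_weight_iter):
            if self_pair:
                hi = hj = np.clip(slope, 0.0, 2.0)
            else:
                hi, hj = h2_i, h2_j
            w = self._pair_weights(ell_m, xreg, hi, hj,
                                   n_i[mask], n_j[mask], slope, icept, M)
            icept, slope, d_icept, d_slope = _wls_jackknife(
                y, xreg, w, bl, self.n_blocks)
        return icept, slope, d_icept, d_slope

    # -- public API ----------------------------------------------------------

    def fit(self, sumstats, ldscores: LDScoreTable, traits: list | None = None):
        """Fit all single-trait and cross-trait regressions jointly.

        ``sumstats`` is a mapping of trait label to canonical table, or a
        list of tables (labelled ``trait0..``).  All regressions run on the
        common SNP set with one shared jackknife block partition, so the
        sampling covariance ``V_`` is coherent across cells of ``S_``.
        """
        if isinstance(sumstats, (list, tuple)):
            labels = traits or [f"trait{i}" for i in range(len(sumstats))]
            tables = dict(zip(labels, sumstats))
        else:
            tables = dict(sumstats)
        labels = list(tables.keys())
        d = len(labels)
        if d < 1:
            raise ValueError("need at least one trait")

        merged = ldscores.table[["snp", "ldscore"]].copy()
        for t in labels:
            tab = tables[t]
            sub = pd.DataFrame({"snp": tab["snp"],
                                f"z_{t}": zscores(tab),
                                f"n_{t}": tab["n_eff"].to_numpy(dtype=float)})
            merged = merged.merge(sub, on="snp", how="inner")
        m = len(merged)
        if m < MIN_SNPS:
            raise ValueError(f"only {m} SNPs after merging; need >= {MIN_SNPS}")
        if m < 2 * self.n_blocks:
            raise ValueError(
                f"{m} SNPs cannot support {self.n_blocks} jackknife blocks")

        M = float(ldscores.M)
        ell = merged["ldscore"].to_numpy(dtype=float)
        Z = np.column_stack([merged[f"z_{t}"].to_numpy(dtype=float)
                             for t in labels])
        N = np.column_stack([merged[f"n_{t}"].to_numpy(dtype=float)
                             for t in labels])
        blocks = np.minimum((np.arange(m) * self.n_blocks) // m,
                            self.n_blocks - 1)

        caps = np.empty(d)
        masks = np.empty((m, d), dtype=bool)
        for k in range(d):
            cap = self.chisq_max
            if cap is None:
                cap = max(80.0, 0.001 * np.max(N[:, k]))
            caps[k] = cap
            masks[:, k] = Z[:, k] ** 2 <= cap

        npair = d * (d + 1) // 2
        S = np.zeros((d, d))
        intercepts = np.zeros((d, d))
        delete = np.zeros((self.n_blocks, npair))
        h2 = {}

        # self pairs first: their h2 feeds the cross-pair weights
        pair_pos = {}
        pos = 0
        for i in range(d):
            for j in range(i, d):
                pair_pos[(i, j)] = pos
                pos += 1
        for i in range(d):
            mask = masks[:, i]
            icept, slope, _, d_slope = self._fit_pair(
                Z[:, i], Z[:, i], ell, N[:, i], N[:, i], M, blocks, mask)
            S[i, i] = slope
            intercepts[i, i] = icept
            delete[:, pair_pos[(i, i)]] = d_slope
            h2[labels[i]] = slope
        for i in range(d):
            for j in range(i + 1, d):
                mask = masks[:, i] & masks[:, j]
                icept, slope, _, d_slope = self._fit_pair(
                    Z[:, i], Z[:, j], ell, N[:, i], N[:, j], M, blocks, mask,
                    h2_i=h2[labels[i]], h2_j=h2[labels[j]])
                S[i, j] = S[j, i] = slope
                intercepts[i, j] = intercepts[j, i] = icept
                delete[:, pair_pos[(i, j)]] = d_slope

        V = jackknife_cov(delete)
        V, dist = nearest_psd(V)
        if dist > 0:
            logger.info("V smoothed to nearest PSD (Frobenius distance %.3g)",
                        dist)

        self.traits_ = labels
        self.S_ = S
        self.V_ = V
        self.intercepts_ = intercepts
        self.m_snps_used_ = m
        self.h2_ = h2
        self.h2_se_ = {labels[i]: float(np.sqrt(V[pair_pos[(i, i)],
                                                  pair_pos[(i, i)]]))
                       for i in range(d)}
        self.result_ = GeneticCovarianceFit(
            traits=labels, S=S, V=V, intercepts=intercepts, m_snps_used=m,
            n_blocks=self.n_blocks, delete_values=delete)
        return self


@dataclass
class UnivariateLDSC:
    h2: float
    h2_se: float
    intercept: float
    intercept_se: float
    m_snps_used: int
    delete_values: np.ndarray


@dataclass
class BivariateLDSC:
    covariance: float
    covariance_se: float
    intercept: float
    m_snps_used: int
    delete_values: np.ndarray


def univariate_ldsc(table: pd.DataFrame, ldscores: LDScoreTable,
                    n_blocks: int = 200, **kwargs) -> UnivariateLDSC:
    """Single-trait heritability + intercept with per-block delete values."""
    est = LDScoreRegression(n_blocks=n_blocks, **kwargs)
    est.fit({"trait": table}, ldscores)
    # intercept delete values need a dedicated pass for the SE
    merged = ldscores.table.merge(
        pd.DataFrame({"snp": table["snp"], "z": zscores(table),
                      "n": table["n_eff"].astype(float)}),
        on="snp", how="inner")
    fit = est.result_
    # re-derive intercept SE by jackknifing the full pair regression
    m = len(merged)
    blocks = np.minimum((np.arange(m) * n_blocks) // m, n_blocks - 1)
    z = merged["z"].to_numpy()
    n = merged["n"].to_numpy()
    ell = merged["ldscore"].to_numpy()
    cap = est.chisq_max or max(80.0, 0.001 * n.max())
    mask = z ** 2 <= cap
    icept, slope, d_icept, d_slope = est._fit_pair(
        z, z, ell, n, n, float(ldscores.M), blocks, mask)
    return UnivariateLDSC(
        h2=fit.S[0, 0], h2_se=fit.se("trait"),
        intercept=fit.intercepts[0, 0], intercept_se=jackknife_se(d_icept),
        m_snps_used=fit.m_snps_used,
        delete_values=fit.delete_values[:, 0].copy())


def bivariate_ldsc(a: pd.DataFrame, b: pd.DataFrame, ldscores: LDScoreTable,
                   n_blocks: int = 200, **kwargs) -> BivariateLDSC:
    """Cross-trait genetic covariance + overlap intercept."""
    est = LDScoreRegression(n_blocks=n_blocks, **kwargs)
    est.fit({"a": a, "b": b}, ldscores)
    fit = est.result_
    idx = fit.vech_index(0, 1)
    return BivariateLDSC(
        covariance=fit.S[0, 1], covariance_se=fit.se("a", "b"),
        intercept=fit.intercepts[0, 1], m_snps_used=fit.m_snps_used,
        delete_values=fit.delete_values[:, idx].copy())


def multivariable_ldsc(tables, ldscores: LDScoreTable, n_blocks: int = 200,
                       traits: list | None = None,
                       **kwargs) -> GeneticCovarianceFit:
    """Assemble the full ``(S, V, intercepts)`` fit over >= 2 traits with a
    single shared jackknife partition."""
    est = LDScoreRegression(n_blocks=n_blocks, **kwargs)
    est.fit(tables, ldscores, traits=traits)
    return est.result_
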
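"""Genetic correlation matrix with Benjamini-Hochberg FDR control.

For every unordered pair of traits in a fitted genetic covariance matrix,
``rg = S_ab / sqrt(S_aa S_bb)`` with a delta-method SE from the jackknife
sampling covariance ``V`` and a two-sided normal p-value; the family of all
pairs in one run is then BH-adjusted at q = 0.05.  Estimates may fall
outside [-1, 1] and are reported unclamped with a flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .ldsc import GeneticCovarianceFit


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-d sequence")
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def correlation_matrix(fit: GeneticCovarianceFit, q: float = 0.05,
                       include_self: bool = False) -> pd.DataFrame:
    """Long-format table of pairwise genetic correlations with FDR flags.

    Columns: trait_a, trait_b, rg, se, p_raw, p_fdr, significant,
    out_of_bounds.  The FDR family is the set of unordered distinct pairs
    of this one call (self-correlations are excluded by default; when
    included they are reported but never enter the BH family).
    """
    d = len(fit.traits)
    diag = np.diag(fit.S)
    for t, v in zip(fit.traits, diag):
        if v <= 0:
            raise ValueError(f"non-positive genetic variance for trait {t!r}")

    rows = []
    for i in range(d):
        for j in range(i, d):
            if i == j and not include_self:
                continue
            s_ab, s_aa, s_bb = fit.S[i, j], fit.S[i, i], fit.S[j, j]
            rg = s_ab / np.sqrt(s_aa * s_bb)
            if i == j:
                se, p_raw = 0.0, np.nan
            else:
                grad = np.array([
                    -rg / (2.0 * s_aa),          # d/dS_aa
                    1.0 / np.sqrt(s_aa * s_bb),  # d/dS_ab
                    -rg / (2.0 * s_bb),          # d/dS_bb
                ])
                idx = [fit.vech_index(i, i), fit.vech_index(i, j),
                       fit.vech_index(j, j)]
                var = grad @ fit.V[np.ix_(idx, idx)] @ grad
                se = float(np.sqrt(max(var, 0.0)))
                from scipy.stats import norm
                p_raw = float(np.clip(2.0 * norm.sf(abs(rg) / se), 1e-300, 1.0))
            rows.append({
                "trait_a": fit.traits[i], "trait_b": fit.traits[j],
                "rg": float(rg), "se": se, "p_raw": p_raw,
                "out_of_bounds": bool(abs(rg) > 1.0),
            })
    out = pd.DataFrame(rows)
    family = out["trait_a"] != out["trait_b"]
    p_fdr = np.full(len(out), np.nan)
    p_fdr[family.to_numpy()] = bh_adjust(out.loc[family, "p_raw"].to_numpy())
    out["p_fdr"] = p_fdr
    out["significant"] = out["p_fdr"] <= q
    return out


def rg_square(entries: pd.DataFrame, traits: list | None = None) -> pd.DataFrame:
    """Pivot the long-format pair table into a square rg matrix."""
    if traits is None:
        traits = list(pd.unique(entries[["trait_a", "trait_b"]].to_numpy().ravel()))
    mat = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    for _, row in entries.iterrows():
        mat.loc[row["trait_a"], row["trait_b"]] = row["rg"]
        mat.loc[row["trait_b"], row["trait_a"]] = row["rg"]
    return mat
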
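"""Polygenic scoring and covariate-adjusted association.

Weights come from clumping + thresholding over any canonical summary-
statistics table (including the derived latent-factor GWAS); the weights
interface also accepts externally computed weight files, so a shrinkage-
based weight set can be dropped in unchanged.  Scores are allele-aligned
weighted dosage sums, z-standardized across individuals.  Associations are
ordinary least squares of an outcome on the standardized score plus
covariates (by default the six PC-like covariates, sex and year of birth).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .simulate import DEFAULT_EDUCATION_MAPPING, GenotypePanel
from .subtraction import clump_hits

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ["sex", "yob", "pc1", "pc2", "pc3", "pc4", "pc5", "pc6"]


@dataclass
class AssociationResult:
    outcome: str
    predictor: str
    beta: float
    se: float
    p: float
    n: int
    covariates: list

    def to_dict(self) -> dict:
        return {"outcome": self.outcome, "predictor": self.predictor,
                "beta": self.beta, "se": self.se, "p": self.p, "n": self.n,
                "covariates": ",".join(self.covariates)}


def build_weights(table: pd.DataFrame, ld, p_threshold: float = 1.0,
                  r2_threshold: float = 0.1, window_kb: int = 500,
                  p_col: str = "pval",
                  snp_subset=None) -> pd.DataFrame:
    """Clumping + thresholding weights: the index SNPs' betas.

    Default ``p_threshold = 1`` keeps every clumped SNP, matching the
    direction-oriented use of these scores.  ``snp_subset`` restricts the
    summary statistics to the scoring panel's variants before clumping (the
    usual practice when the target panel is genotyped on a subset).
    Returns a 3-column frame (snp, effect_allele, weight).
    """
    if snp_subset is not None:
        table = table[table["snp"].isin(set(snp_subset))]
    index_snps = clump_hits(table, ld, p_threshold=p_threshold,
                            r2_threshold=r2_threshold, window_kb=window_kb,
                            p_col=p_col)
    if not index_snps:
        logger.warning("build_weights: empty weight set")
        return pd.DataFrame(columns=["snp", "effect_allele", "weight"])
    sub = table.set_index("snp").loc[index_snps]
    return pd.DataFrame({
        "snp": index_snps,
        "effect_allele": sub["effect_allele"].to_numpy(),
        "weight": sub["beta"].to_numpy(dtype=float),
    })


def score_individuals(weights: pd.DataFrame, panel: GenotypePanel,
                      min_coverage: float = 0.5) -> pd.Series:
    """Allele-aligned weighted dosage sum, z-standardized across individuals.

    A weight whose effect allele matches the panel's other allele is applied
    to the flipped dosage (sign flip).  Raises if fewer than
    ``min_coverage`` of the weight SNPs are present in the panel.
    """
    if weights["snp"].duplicated().any():
        raise ValueError("duplicate snp ids in weights")
    panel_idx = pd.Series(np.arange(len(panel.snps)),
                          index=panel.snps["snp"])
    present = weights["snp"].isin(panel_idx.index)
    coverage = present.mean() if len(weights) else 0.0
    if coverage < min_coverage:
        raise ValueError(
            f"panel covers only {coverage:.1%} of weight SNPs "
            f"(floor {min_coverage:.0%})")
    w = weights[present.to_numpy()]
    cols = panel_idx[w["snp"]].to_numpy()
    dos = panel.dosages[:, cols]

    pan_ea = panel.snps["effect_allele"].to_numpy()[cols]
    pan_oa = panel.snps["other_allele"].to_numpy()[cols]
    w_ea = w["effect_allele"].to_numpy()
    flipped = w_ea == pan_oa
    unmatched = ~flipped & (w_ea != pan_ea)
    if unmatched.any():
        raise ValueError(f"{int(unmatched.sum())} weight SNPs have alleles "
                         "absent from the panel")
    sign = np.where(flipped, -1.0, 1.0)
    raw = (dos @ (w["weight"].to_numpy() * sign)
           .astype(panel.dosages.dtype)).astype(float)
    sd = raw.std()
    if sd == 0:
        logger.warning("degenerate score (zero variance)")
        return pd.Series(np.zeros(len(raw)), index=panel.phenotypes["iid"],
                         name="pgs")
    return pd.Series((raw - raw.mean()) / sd,
                     index=panel.phenotypes["iid"], name="pgs")


def derive_education_years(qualifications: pd.DataFrame,
                           mapping: Mapping[str, float] | None = None,
                           on_unknown: str = "drop") -> pd.Series:
    """Per-individual years in education: the maximum years across all
    reported qualifications over all visits.

    ``qualifications`` is long format with columns (iid, visit, code).
    Unknown codes either drop the individual (``on_unknown='drop'``) or are
    ignored (``'ignore'``); either way they are logged.
    """
    if mapping is None:
        mapping = DEFAULT_EDUCATION_MAPPING
    if on_unknown not in ("drop", "ignore"):
        raise ValueError("on_unknown must be 'drop' or 'ignore'")
    df = qualifications.copy()
    df["years"] = df["code"].map(mapping)
    unknown = df["years"].isna()
    if unknown.any():
        logger.warning("derive_education_years: %d unknown codes (%s)",
                       int(unknown.sum()), on_unknown)
        if on_unknown == "drop":
            bad = set(df.loc[unknown, "iid"])
            df = df[~df["iid"].isin(bad)]
        else:
            df = df[~unknown]
    out = df.groupby("iid", sort=False)["years"].max()
    out.name = "edu_years"
    return out


def fit_association(outcome: pd.Series, pgs: pd.Series,
                    covariates: pd.DataFrame | None = None,
                    outcome_label: str = "outcome",
                    predictor_label: str = "pgs") -> AssociationResult:
    """OLS of the outcome on the standardized score plus covariates.

    Complete-case analysis over the index intersection; the reported beta is
    the score coefficient with its two-sided p-value.  A rank-deficient
    design raises, naming the collinear columns.
    """
    df = pd.DataFrame({"outcome": outcome, "pgs": pgs})
    if covariates is not None:
        df = df.join(covariates, how="inner")
    df = df.dropna()
    k = df.shape[1] - 1
    if len(df) < k + 2:
        raise ValueError("too few complete cases for the design")
    X = sm.add_constant(df.drop(columns="outcome"))
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = X.drop(columns="const").corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax()
        raise ValueError(f"rank-deficient design; check columns {worst}")
    res = sm.OLS(df["outcome"], X).fit()
    return AssociationResult(
        outcome=outcome_label, predictor=predictor_label,
        beta=float(res.params["pgs"]), se=float(res.bse["pgs"]),
        p=float(res.pvalues["pgs"]), n=int(res.nobs),
        covariates=[c for c in df.columns if c not in ("outcome", "pgs")],
    )
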
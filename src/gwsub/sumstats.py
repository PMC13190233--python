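"""Reading, validation, harmonization and munging of GWAS summary statistics.

A summary-statistics table is a :class:`pandas.DataFrame` with the canonical
columns ``snp, chrom, pos, effect_allele, other_allele, eaf, beta, se, pval,
n_eff``.  ``beta`` is the per-allele effect on the trait scale (log-odds for
binary traits) and ``n_eff`` the effective sample size (the sample size of a
balanced case-control study with equivalent power).  All downstream stages
(LD score regression, GWAS-by-subtraction, polygenic scoring, Mendelian
randomisation) consume this layout.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = [
    "snp", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n_eff",
]

#: Header spellings accepted out of the box.  ``read_sumstats`` lower-cases
#: headers before applying the map, so e.g. ``SNP`` and ``snp`` both resolve.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "snp": "snp", "rsid": "snp", "markername": "snp", "id": "snp",
    "chrom": "chrom", "chr": "chrom", "chromosome": "chrom",
    "pos": "pos", "bp": "pos", "position": "pos", "base_pair_location": "pos",
    "effect_allele": "effect_allele", "a1": "effect_allele", "ea": "effect_allele",
    "other_allele": "other_allele", "a2": "other_allele", "oa": "other_allele",
    "non_effect_allele": "other_allele",
    "eaf": "eaf", "freq": "eaf", "af": "eaf", "effect_allele_frequency": "eaf",
    "maf": "eaf",
    "beta": "beta", "b": "beta", "effect": "beta",
    "se": "se", "standard_error": "se",
    "pval": "pval", "p": "pval", "p_value": "pval", "pvalue": "pval",
    "n_eff": "n_eff", "n": "n_eff", "neff": "n_eff", "n_effective": "n_eff",
    "z": "z", "zscore": "z", "z_score": "z",
    "or": "odds_ratio", "odds_ratio": "odds_ratio",
    "info": "info",
}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_ALLELES = frozenset("ACGT")

#: smallest positive normal double; p-values below underflow are clamped here
#: and downstream tests should work with z-scores instead.
P_FLOOR = float(np.finfo(np.float64).tiny)


def zscores(table: pd.DataFrame) -> np.ndarray:
    """Association z-scores ``beta / se``."""
    return (table["beta"] / table["se"]).to_numpy(dtype=float)


def pvalues_from_z(z: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(z))
    return np.clip(p, P_FLOOR, 1.0)


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_sumstats(path: str | Path,
                  column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a whitespace/tab-delimited summary-statistics file.

    ``column_map`` maps header names (case-insensitive) in the file to
    canonical names; it is merged over :data:`DEFAULT_COLUMN_MAP`.  A file
    carrying a ``z`` column but no ``beta``/``se`` is converted to the
    standardized per-allele scale via ``beta = z / sqrt(2 p q n_eff)`` and
    ``se = 1 / sqrt(2 p q n_eff)``, which reproduces the z-score exactly.
    Rows failing validation are dropped and counted in the log.

    Raises
    ------
    KeyError
        if a mandatory column cannot be resolved.
    ValueError
        if no rows survive parsing.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update({k.lower(): v for k, v in column_map.items()})

    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep=r"\s+", float_precision="round_trip")
    rename = {}
    for col in df.columns:
        key = col.lower()
        if key in cmap:
            rename[col] = cmap[key]
    df = df.rename(columns=rename)
    df = df.loc[:, ~df.columns.duplicated()]

    if "beta" not in df.columns and "odds_ratio" in df.columns:
        df["beta"] = np.log(pd.to_numeric(df["odds_ratio"], errors="coerce"))
    if ("beta" not in df.columns or "se" not in df.columns) and "z" in df.columns:
        for needed in ("eaf", "n_eff"):
            if needed not in df.columns:
                raise KeyError(
                    f"z-score input needs '{needed}' to recover beta/se")
        z = pd.to_numeric(df["z"], errors="coerce")
        p = pd.to_numeric(df["eaf"], errors="coerce")
        n = pd.to_numeric(df["n_eff"], errors="coerce")
        denom = np.sqrt(2.0 * p * (1.0 - p) * n)
        df["se"] = 1.0 / denom
        df["beta"] = z / denom
    if "pval" not in df.columns and {"beta", "se"} <= set(df.columns):
        df["pval"] = pvalues_from_z(
            pd.to_numeric(df["beta"], errors="coerce")
            / pd.to_numeric(df["se"], errors="coerce"))

    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise KeyError(f"missing mandatory column(s): {missing}")

    extra = [c for c in ("info",) if c in df.columns]
    df = df[CANONICAL_COLUMNS + extra]
    df = validate_sumstats(df)
    if len(df) == 0:
        raise ValueError(f"no valid rows parsed from {path}")
    return df


def validate_sumstats(df: pd.DataFrame) -> pd.DataFrame:
    """Coerce dtypes and drop rows violating the table invariants.

    Enforced: ACGT alleles, ``eaf`` strictly in (0, 1), ``se > 0``, ``pval``
    in (0, 1], finite beta, chrom in 1–22, positive position, no duplicate
    ``snp`` (first kept).  Drop counts are logged.
    """
    df = df.copy()
    n0 = len(df)
    for col in ("pos", "chrom"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("eaf", "beta", "se", "pval", "n_eff"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["snp"] = df["snp"].astype(str)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()

    ok = (
        df["effect_allele"].isin(_VALID_ALLELES)
        & df["other_allele"].isin(_VALID_ALLELES)
        & (df["effect_allele"] != df["other_allele"])
        & df["eaf"].between(0.0, 1.0, inclusive="neither")
        & (df["se"] > 0)
        & df["pval"].between(0.0, 1.0, inclusive="right")
        & np.isfinite(df["beta"])
        & df["chrom"].between(1, 22)
        & (df["pos"] >= 1)
        & (df["n_eff"] > 0)
    )
    df = df[ok.fillna(False)]
    dups = df["snp"].duplicated()
    if dups.any():
        logger.warning("dropping %d duplicated snp ids (first kept)", dups.sum())
        df = df[~dups]
    dropped = n0 - len(df)
    if dropped:
        logger.info("validate_sumstats: dropped %d of %d rows", dropped, n0)
    df["chrom"] = df["chrom"].astype(int)
    df["pos"] = df["pos"].astype(int)
    df["n_eff"] = df["n_eff"].astype(float)
    df["pval"] = df["pval"].clip(lower=P_FLOOR)
    return df.reset_index(drop=True)


def write_sumstats(table: pd.DataFrame, path: str | Path) -> None:
    """Write tab-delimited text; %.17g guarantees bit-for-bit float64
    round-trip through read_sumstats."""
    path = Path(path)
    opener = gzip.open(path, "wt") if path.suffix == ".gz" else open(path, "wt")
    with opener as fh:
        table.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def qc_filter(table: pd.DataFrame, maf_min: float = 0.01,
              info_min: float | None = None) -> pd.DataFrame:
    """Munging filter: drop SNPs with MAF below ``maf_min`` and, when an
    ``info`` column is present and ``info_min`` given, low imputation quality.

    Raises ``ValueError`` if nothing survives.
    """
    if not 0.0 <= maf_min < 0.5:
        raise ValueError("maf_min must be in [0, 0.5)")
    maf = np.minimum(table["eaf"], 1.0 - table["eaf"])
    keep = maf >= maf_min
    if info_min is not None and "info" in table.columns:
        keep &= table["info"] >= info_min
    out = table[keep].reset_index(drop=True)
    logger.info("qc_filter: retained %d of %d SNPs", len(out), len(table))
    if len(out) == 0:
        raise ValueError("qc_filter removed all rows")
    return out


def is_palindromic(effect: pd.Series, other: pd.Series) -> pd.Series:
    """A/T and C/G SNPs, whose strand cannot be resolved from alleles alone."""
    return effect.map(_COMPLEMENT) == other


def drop_ambiguous(table: pd.DataFrame) -> pd.DataFrame:
    """Drop strand-ambiguous (palindromic) SNPs — default munging policy."""
    keep = ~is_palindromic(table["effect_allele"], table["other_allele"])
    return table[keep].reset_index(drop=True)


@dataclass
class HarmonizationReport:
    n_matched: int
    n_sign_flipped: int
    n_strand_flipped: int
    n_palindromic_dropped: int
    n_irreconcilable: int


def harmonize_alleles(a: pd.DataFrame, b: pd.DataFrame,
                      drop_palindromic: bool = True,
                      ) -> tuple[pd.DataFrame, pd.DataFrame, HarmonizationReport]:
    """Align table ``b`` to the allele orientation of table ``a``.

    Returns the SNP intersection of both tables in ``a``'s row order, with
    ``b``'s beta sign and eaf flipped wherever its effect allele matches
    ``a``'s other allele, strand flips (A<->T, C<->G complement) resolved,
    palindromic SNPs optionally dropped, and irreconcilable allele pairs
    dropped (never silently kept).  ``|beta|`` and ``se`` are preserved
    exactly.  The operation is involutive: re-harmonizing the output is a
    no-op.
    """
    common = a.loc[a["snp"].isin(set(b["snp"])), "snp"]
    a_sub = a.set_index("snp").loc[common].reset_index()
    b_sub = b.set_index("snp").loc[common].reset_index()

    a_ea, a_oa = a_sub["effect_allele"], a_sub["other_allele"]
    b_ea, b_oa = b_sub["effect_allele"], b_sub["other_allele"]
    b_ea_c = b_ea.map(_COMPLEMENT)
    b_oa_c = b_oa.map(_COMPLEMENT)

    palin = is_palindromic(a_ea, a_oa) | is_palindromic(b_ea, b_oa)
    same = (b_ea == a_ea) & (b_oa == a_oa)
    swapped = (b_ea == a_oa) & (b_oa == a_ea)
    # strand flips only assessed for non-palindromic pairs: for A/T and C/G
    # SNPs "flipped" and "same" are indistinguishable
    flip_same = ~palin & (b_ea_c == a_ea) & (b_oa_c == a_oa)
    flip_swap = ~palin & (b_ea_c == a_oa) & (b_oa_c == a_ea)

    resolvable = same | swapped | flip_same | flip_swap
    keep = resolvable.copy()
    if drop_palindromic:
        keep &= ~palin
    n_palin_dropped = int((palin & resolvable).sum()) if drop_palindromic else 0
    n_irrec = int((~resolvable).sum())

    need_sign_flip = (swapped | flip_swap) & keep
    need_strand = (flip_same | flip_swap) & keep

    b_out = b_sub.copy()
    b_out.loc[need_strand, "effect_allele"] = b_ea_c[need_strand]
    b_out.loc[need_strand, "other_allele"] = b_oa_c[need_strand]
    b_out.loc[need_sign_flip, ["effect_allele", "other_allele"]] = (
        b_out.loc[need_sign_flip, ["other_allele", "effect_allele"]].to_numpy())
    b_out.loc[need_sign_flip, "beta"] = -b_out.loc[need_sign_flip, "beta"]
    b_out.loc[need_sign_flip, "eaf"] = 1.0 - b_out.loc[need_sign_flip, "eaf"]

    report = HarmonizationReport(
        n_matched=int(keep.sum()),
        n_sign_flipped=int(need_sign_flip.sum()),
        n_strand_flipped=int(need_strand.sum()),
        n_palindromic_dropped=n_palin_dropped,
        n_irreconcilable=n_irrec,
    )
    if n_irrec:
        logger.warning("harmonize_alleles: %d irreconcilable SNPs dropped", n_irrec)
    a_out = a_sub[keep.to_numpy()].reset_index(drop=True)
    b_out = b_out[keep.to_numpy()].reset_index(drop=True)
    return a_out, b_out, report


# ---------------------------------------------------------------------------
# LD score tables


@dataclass
class LDScoreTable:
    """Per-SNP LD scores plus the total SNP count ``M`` they were computed
    over (the denominator of the LD score regression slope scaling)."""

    table: pd.DataFrame  # columns: snp, ldscore
    M: int

    def __post_init__(self) -> None:
        if self.M < len(self.table):
            raise ValueError("M must be >= number of scored SNPs")
        if (self.table["ldscore"] < 0).any():
            raise ValueError("negative LD score")


def read_ldscores(path: str | Path, m_path: str | Path | None = None) -> LDScoreTable:
    """Read a tab-delimited LD score file (columns ``SNP``/``snp`` and
    ``L2``/``ldscore``) with a sidecar ``.M`` file holding the total count."""
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep=r"\s+")
    df = df.rename(columns={c: c.lower() for c in df.columns})
    df = df.rename(columns={"l2": "ldscore"})
    if m_path is None:
        m_path = str(path) + ".M"
    with open(m_path) as fh:
        M = int(float(fh.read().split()[0]))
    return LDScoreTable(table=df[["snp", "ldscore"]].copy(), M=M)


def write_ldscores(ld: LDScoreTable, path: str | Path) -> None:
    ld.table.to_csv(path, sep="\t", index=False)
    with open(str(path) + ".M", "wt") as fh:
        fh.write(f"{ld.M}\n")
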
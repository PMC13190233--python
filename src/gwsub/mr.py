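"""Bidirectional two-sample Mendelian randomisation.

Estimator battery: multiplicative random-effects inverse-variance weighting
(IVW, the primary method), MR-Egger regression (slope plus the intercept
test for directional pleiotropy), and the weighted and penalised weighted
median.  Diagnostics: Cochran's Q over per-instrument ratio estimates,
instrument F-statistics, the I^2_GX attenuation index, and leave-one-out
IVW re-estimates.  Instruments are genome-wide-significant clumped exposure
SNPs harmonized against the outcome GWAS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .subtraction import clump_hits
from .sumstats import harmonize_alleles

logger = logging.getLogger(__name__)


@dataclass
class MRInstrumentSet:
    """Harmonized per-variant exposure/outcome effects."""

    table: pd.DataFrame  # snp, beta_exposure, se_exposure, beta_outcome, se_outcome, eaf
    exposure: str = "exposure"
    outcome: str = "outcome"
    selection: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.table["snp"].duplicated().any():
            raise ValueError("duplicate instruments")

    def __len__(self) -> int:
        return len(self.table)

    def arrays(self):
        t = self.table
        return (t["beta_exposure"].to_numpy(dtype=float),
                t["se_exposure"].to_numpy(dtype=float),
                t["beta_outcome"].to_numpy(dtype=float),
                t["se_outcome"].to_numpy(dtype=float))

    def drop(self, snp: str) -> "MRInstrumentSet":
        return MRInstrumentSet(
            table=self.table[self.table["snp"] != snp].reset_index(drop=True),
            exposure=self.exposure, outcome=self.outcome,
            selection=self.selection)


@dataclass
class MREstimate:
    method: str
    beta: float
    se: float
    p: float
    n_snps: int
    extra: dict = field(default_factory=dict)

    def odds_ratio(self) -> dict:
        """Exponentiated estimate with 95% CI (binary-outcome reporting)."""
        lo = self.beta - 1.959963984540054 * self.se
        hi = self.beta + 1.959963984540054 * self.se
        return {"or": float(np.exp(self.beta)),
                "ci_low": float(np.exp(lo)), "ci_high": float(np.exp(hi))}

    def to_dict(self) -> dict:
        return {"method": self.method, "beta": self.beta, "se": self.se,
                "p": self.p, "n_snps": self.n_snps}


@dataclass
class MRDiagnostics:
    cochran_q: float
    q_df: int
    q_p: float
    egger_intercept: float
    egger_intercept_se: float
    egger_intercept_p: float
    mean_f: float
    i2_gx: float
    loo_table: pd.DataFrame


def select_instruments(exposure: pd.DataFrame, outcome: pd.DataFrame, ld,
                       p_threshold: float = 5e-8,
                       r2_threshold: float = 0.001, window_kb: int = 10_000,
                       drop_palindromic: bool = True,
                       exposure_label: str = "exposure",
                       outcome_label: str = "outcome") -> MRInstrumentSet:
    """Clump genome-wide-significant exposure SNPs, look up outcome effects.

    Harmonization runs first so every retained instrument has resolvable
    alleles in both GWAS; unresolvable variants are dropped with a count.
    Raises if fewer than 3 instruments remain (median methods undefined).
    """
    exp_h, out_h, report = harmonize_alleles(exposure, outcome,
                                             drop_palindromic=drop_palindromic)
    index_snps = clump_hits(exp_h, ld, p_threshold=p_threshold,
                            r2_threshold=r2_threshold, window_kb=window_kb)
    if len(index_snps) < 3:
        raise ValueError(
            f"only {len(index_snps)} instruments for {exposure_label} at "
            f"p < {p_threshold:g}; need >= 3")
    exp_i = exp_h.set_index("snp").loc[index_snps]
    out_i = out_h.set_index("snp").loc[index_snps]
    table = pd.DataFrame({
        "snp": index_snps,
        "beta_exposure": exp_i["beta"].to_numpy(dtype=float),
        "se_exposure": exp_i["se"].to_numpy(dtype=float),
        "beta_outcome": out_i["beta"].to_numpy(dtype=float),
        "se_outcome": out_i["se"].to_numpy(dtype=float),
        "eaf": exp_i["eaf"].to_numpy(dtype=float),
    })
    return MRInstrumentSet(
        table=table, exposure=exposure_label, outcome=outcome_label,
        selection={"p_threshold": p_threshold, "r2_threshold": r2_threshold,
                   "window_kb": window_kb,
                   "n_irreconcilable": report.n_irreconcilable,
                   "n_palindromic_dropped": report.n_palindromic_dropped})


def _ratio_statistics(inst: MRInstrumentSet):
    bx, sx, by, sy = inst.arrays()
    ratio = by / bx
    # first-order IVW weights on the ratio scale
    w = bx ** 2 / sy ** 2
    return ratio, w


def cochran_q(inst: MRInstrumentSet, beta: float) -> tuple[float, np.ndarray]:
    """Q = sum of per-instrument contributions w_j (ratio_j - beta)^2."""
    ratio, w = _ratio_statistics(inst)
    contrib = w * (ratio - beta) ** 2
    return float(contrib.sum()), contrib


class IVWEstimator(BaseEstimator):
    """Inverse-variance weighted estimate: weighted regression of outcome on
    exposure effects through the origin with weights 1/se_outcome^2.  The
    default multiplicative random-effects model inflates the SE by
    max(1, sqrt(Q/df)); ``fixed_effects=True`` disables the inflation.
    With a single instrument this reduces exactly to the Wald ratio."""

    def __init__(self, fixed_effects: bool = False):
        self.fixed_effects = fixed_effects

    def fit(self, inst: MRInstrumentSet, y=None):
        if len(inst) < 1:
            raise ValueError("need at least one instrument")
        bx, sx, by, sy = inst.arrays()
        w = 1.0 / sy ** 2
        beta = float((w * bx * by).sum() / (w * bx ** 2).sum())
        se_fixed = float(1.0 / np.sqrt((w * bx ** 2).sum()))
        q, _ = cochran_q(inst, beta)
        df = max(len(inst) - 1, 1)
        scale = 1.0 if self.fixed_effects else max(1.0, np.sqrt(q / df))
        se = se_fixed * scale
        p = float(2.0 * stats.norm.sf(abs(beta) / se)) if se > 0 else 0.0
        self.beta_, self.se_, self.p_ = beta, se, p
        self.q_, self.n_snps_ = q, len(inst)
        self.result_ = MREstimate(method="IVW", beta=beta, se=se, p=p,
                                  n_snps=len(inst), extra={"q": q})
        return self


class EggerRegression(BaseEstimator):
    """MR-Egger: weighted regression of outcome on exposure effects with a
    free intercept, all instruments re-signed so beta_exposure > 0.  The
    intercept estimates directional pleiotropy; slope inference uses a
    t(n-2) reference with multiplicative random-effects SE inflation."""

    def fit(self, inst: MRInstrumentSet, y=None):
        if len(inst) < 3:
            raise ValueError("MR-Egger needs >= 3 instruments")
        bx, sx, by, sy = inst.arrays()
        sign = np.sign(bx)
        sign[sign == 0] = 1.0
        bx, by = bx * sign, by * sign
        if np.ptp(bx) < 1e-12 * max(np.abs(bx).max(), 1e-300):
            raise ValueError("degenerate exposure-beta spread; "
                             "Egger slope unidentifiable")
        w = 1.0 / sy ** 2
        X = np.column_stack([np.ones_like(bx), bx])
        WX = X * w[:, None]
        A = X.T @ WX
        coef = np.linalg.solve(A, WX.T @ by)
        resid = by - X @ coef
        df = len(inst) - 2
        q_egger = float((w * resid ** 2).sum())
        scale = max(1.0, q_egger / df)
        cov = np.linalg.inv(A) * scale
        icept, slope = coef
        se_icept, se_slope = np.sqrt(np.diag(cov))
        p_slope = float(2.0 * stats.t.sf(abs(slope) / se_slope, df))
        p_icept = float(2.0 * stats.t.sf(abs(icept) / se_icept, df))
        self.slope_ = MREstimate(method="Egger-slope", beta=float(slope),
                                 se=float(se_slope), p=p_slope,
                                 n_snps=len(inst), extra={"q": q_egger})
        self.intercept_ = MREstimate(method="Egger-intercept",
                                     beta=float(icept), se=float(se_icept),
                                     p=p_icept, n_snps=len(inst))
        self.beta_, self.se_, self.p_ = float(slope), float(se_slope), p_slope
        return self


def weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weight-0.5 quantile of the ratio estimates.

    With equal weights and odd n this is the ordinary median; the quantile
    is linearly interpolated between order statistics at the standardized
    cumulative weights ``(cum_k - w_k/2) / sum(w)``.
    """
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum = cum / w.sum()
    if 0.5 <= cum[0]:
        return float(r[0])
    if 0.5 >= cum[-1]:
        return float(r[-1])
    return float(np.interp(0.5, cum, r))


class WeightedMedianEstimator(BaseEstimator):
    """Weighted median of per-instrument Wald ratios with inverse-variance
    weights (consistent when >= 50% of the weight lies on valid
    instruments).  ``penalized=True`` down-weights heterogeneous
    instruments by ``min(1, penalty * p_j)`` with ``p_j`` the chi-square(1)
    upper tail of the instrument's Q contribution at the unpenalized
    estimate.  The SE is a seeded parametric bootstrap."""

    def __init__(self, penalized: bool = False, penalty: float = 20.0,
                 n_boot: int = 1000, random_state: int = 0):
        self.penalized = penalized
        self.penalty = penalty
        self.n_boot = n_boot
        self.random_state = random_state

    @staticmethod
    def _ratio_weights(bx, sx, by, sy):
        ratio = by / bx
        var = sy ** 2 / bx ** 2 + by ** 2 * sx ** 2 / bx ** 4  # delta method
        return ratio, 1.0 / var

    def _point(self, bx, sx, by, sy):
        ratio, w = self._ratio_weights(bx, sx, by, sy)
        est = weighted_median_point(ratio, w)
        if self.penalized:
            q_contrib = w * (ratio - est) ** 2
            pen = np.minimum(1.0, self.penalty * stats.chi2.sf(q_contrib, df=1))
            est = weighted_median_point(ratio, w * pen)
        return est

    def fit(self, inst: MRInstrumentSet, y=None):
        if len(inst) < 3:
            raise ValueError("weighted median needs >= 3 instruments")
        bx, sx, by, sy = inst.arrays()
        beta = self._point(bx, sx, by, sy)
        rng = np.random.default_rng(self.random_state)
        boots = np.empty(self.n_boot)
        for b in range(self.n_boot):
            bx_b = bx + sx * rng.standard_normal(len(bx))
            by_b = by + sy * rng.standard_normal(len(by))
            boots[b] = self._point(bx_b, sx, by_b, sy)
        se = float(boots.std(ddof=1))
        p = float(2.0 * stats.norm.sf(abs(beta) / se)) if se > 0 else 0.0
        method = "penalized-weighted-median" if self.penalized else "weighted-median"
        self.beta_, self.se_, self.p_ = float(beta), se, p
        self.result_ = MREstimate(method=method, beta=float(beta), se=se,
                                  p=p, n_snps=len(inst))
        return self


# -- function wrappers -------------------------------------------------------

def ivw(inst: MRInstrumentSet, fixed_effects: bool = False) -> MREstimate:
    return IVWEstimator(fixed_effects=fixed_effects).fit(inst).result_


def egger(inst: MRInstrumentSet) -> tuple[MREstimate, MREstimate]:
    est = EggerRegression().fit(inst)
    return est.slope_, est.intercept_


def weighted_median(inst: MRInstrumentSet, penalized: bool = False,
                    random_state: int = 0, n_boot: int = 1000) -> MREstimate:
    return WeightedMedianEstimator(
        penalized=penalized, random_state=random_state,
        n_boot=n_boot).fit(inst).result_


def diagnostics(inst: MRInstrumentSet,
                est: MREstimate | None = None) -> MRDiagnostics:
    """Heterogeneity, pleiotropy and instrument-strength diagnostics.

    Cochran's Q is computed at the IVW estimate over ratio-scale weights
    (its per-instrument contributions sum to Q exactly); the Egger intercept
    is the directional-pleiotropy test; instrument strength is the mean
    F-statistic ``beta_exposure^2 / se_exposure^2`` and the attenuation
    index ``I^2_GX = max(0, (F - 1)/F)``; the leave-one-out table re-runs
    IVW dropping each variant in turn.
    """
    if est is None:
        est = ivw(inst)
    q, _ = cochran_q(inst, est.beta)
    df = len(inst) - 1
    q_p = float(stats.chi2.sf(q, df)) if df > 0 else 1.0
    bx, sx, _, _ = inst.arrays()
    f_stats = bx ** 2 / sx ** 2
    mean_f = float(f_stats.mean())
    i2_gx = max(0.0, (mean_f - 1.0) / mean_f)
    _, icept = egger(inst)
    loo_rows = []
    for snp in inst.table["snp"]:
        sub = ivw(inst.drop(snp))
        loo_rows.append({"snp_left_out": snp, "beta": sub.beta,
                         "se": sub.se, "p": sub.p})
    return MRDiagnostics(
        cochran_q=q, q_df=df, q_p=q_p,
        egger_intercept=icept.beta, egger_intercept_se=icept.se,
        egger_intercept_p=icept.p, mean_f=mean_f, i2_gx=i2_gx,
        loo_table=pd.DataFrame(loo_rows))


@dataclass
class MRDirectionResult:
    instruments: MRInstrumentSet | None
    estimates: list
    diagnostics: MRDiagnostics | None
    binary_outcome: bool = False
    flags: list = field(default_factory=list)
    error: str | None = None

    def estimates_frame(self) -> pd.DataFrame:
        rows = [e.to_dict() for e in self.estimates]
        df = pd.DataFrame(rows)
        if self.binary_outcome and len(df):
            ors = [e.odds_ratio() for e in self.estimates]
            for key in ("or", "ci_low", "ci_high"):
                df[key] = [o[key] for o in ors]
        return df


def _run_direction(exposure, outcome, ld, exposure_label, outcome_label,
                   binary_outcome, p_threshold, r2_threshold, window_kb,
                   random_state) -> MRDirectionResult:
    try:
        inst = select_instruments(
            exposure, outcome, ld, p_threshold=p_threshold,
            r2_threshold=r2_threshold, window_kb=window_kb,
            exposure_label=exposure_label, outcome_label=outcome_label)
    except ValueError as exc:
        return MRDirectionResult(instruments=None, estimates=[],
                                 diagnostics=None, error=str(exc))
    primary = ivw(inst)
    slope, icept = egger(inst)
    estimates = [
        primary, slope, icept,
        weighted_median(inst, penalized=False, random_state=random_state),
        weighted_median(inst, penalized=True, random_state=random_state),
    ]
    diag = diagnostics(inst, primary)
    flags = []
    ratio, _ = _ratio_statistics(inst)
    if np.ptp(ratio) < 1e-10 * max(1.0, np.abs(ratio).max()):
        flags.append("degenerate: all instrument ratios identical")
    return MRDirectionResult(instruments=inst, estimates=estimates,
                             diagnostics=diag, binary_outcome=binary_outcome,
                             flags=flags)


def bidirectional_run(a: pd.DataFrame, b: pd.DataFrame, ld,
                      labels: tuple = ("A", "B"),
                      binary: tuple = (False, False),
                      p_threshold: float = 5e-8,
                      r2_threshold: float = 0.001, window_kb: int = 10_000,
                      random_state: int = 0) -> dict:
    """Run the full estimator battery and diagnostics in both directions.

    ``binary`` flags whether each trait is binary; a binary *outcome* is
    additionally reported as OR = exp(beta) with a 95% CI.  One direction
    may fail (e.g. too few instruments) without aborting the other; the
    failure is recorded in that direction's ``error`` field.
    """
    la, lb = labels
    return {
        f"{la}_on_{lb}": _run_direction(
            a, b, ld, la, lb, binary[1], p_threshold, r2_threshold,
            window_kb, random_state),
        f"{lb}_on_{la}": _run_direction(
            b, a, ld, lb, la, binary[0], p_threshold, r2_threshold,
            window_kb, random_state),
    }
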
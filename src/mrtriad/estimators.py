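"""Univariable Mendelian-randomization estimators and diagnostics.

The causal effect of an exposure X on an outcome Y is estimated from
per-variant association pairs (beta_GX, beta_GY):

* Wald ratio (single instrument, "cis-MR"): beta = beta_GY / beta_GX with
  first-order delta-method SE = se_GY / |beta_GX|.
* Inverse-variance-weighted (IVW, "polygenic MR"): precision-weighted mean
  of per-instrument Wald ratios, with Cochran's Q heterogeneity statistic
  and an optional multiplicative random-effects SE inflation
  max(1, sqrt(Q/df)).
* MR-Egger: weighted regression of beta_GY on beta_GX with intercept; a
  non-zero intercept indicates directional pleiotropy.

Effects on binary outcomes are log odds ratios; ``effect_to_or_ci`` maps
(beta, se) to OR with 95% CI bounds exp(beta -/+ 1.96 se).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .instruments import (
    DEFAULT_R2_THRESHOLD,
    DEFAULT_WINDOW_BP,
    InstrumentSet,
    LdMatrix,
    get_level,
    ld_clump,
    screen_by_pvalue,
)
from .sumstats import PALINDROME_EAF_WINDOW, SummaryStatsTable, harmonize_tables

logger = logging.getLogger(__name__)

Z95 = 1.96  # normal quantile used for 95% intervals throughout


def effect_to_or_ci(beta: float, se: float) -> tuple[float, float, float]:
    """(OR, 95% CI low, high) from a log-odds effect and its SE."""
    if se <= 0:
        raise ValueError("se must be positive")
    return float(np.exp(beta)), float(np.exp(beta - Z95 * se)), float(np.exp(beta + Z95 * se))


def _normal_p(beta: float, se: float) -> float:
    return float(2.0 * stats.norm.sf(abs(beta) / se))


@dataclass
class HeterogeneityTest:
    """Cochran's Q over per-instrument ratio estimates."""

    Q: float
    df: int
    pval: float


@dataclass
class EggerTest:
    intercept: float
    intercept_se: float
    intercept_pval: float
    slope: float
    slope_se: float


@dataclass
class MrResult:
    """One causal-effect estimate with OR-scale summaries and diagnostics."""

    exposure_id: str
    outcome_id: str
    level: str
    method: str  # "wald_ratio" | "ivw" | "egger"
    nsnp: int
    beta: float
    se: float
    pval: float
    or_: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    q: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    p_pleio: float | None = None

    def __post_init__(self) -> None:
        self.or_, self.ci_low, self.ci_high = effect_to_or_ci(self.beta, self.se)

    def to_dict(self) -> dict:
        return {
            "exposure": self.exposure_id, "outcome": self.outcome_id,
            "method": self.method, "level": self.level, "nsnp": self.nsnp,
            "beta": self.beta, "se": self.se, "or": self.or_,
            "ci_low": self.ci_low, "ci_high": self.ci_high, "p_mr": self.pval,
            "Q": self.q, "Q_pval": self.q_pval,
            "egger_intercept": self.egger_intercept, "p_pleio": self.p_pleio,
        }


def wald_ratio(
    b_gx: float, se_gx: float, b_gy: float, se_gy: float,
    exposure_id: str = "exposure", outcome_id: str = "outcome",
    level: str = "", second_order: bool = False,
) -> MrResult:
    """Single-instrument causal estimate beta_GY / beta_GX.

    ``second_order=True`` adds the exposure-uncertainty term of the delta
    method: se^2 = se_GY^2/b_GX^2 + b_GY^2 se_GX^2 / b_GX^4.
    """
    if b_gx == 0:
        raise ZeroDivisionError("Wald ratio undefined for b_gx = 0")
    beta = b_gy / b_gx
    if second_order:
        se = float(np.sqrt(se_gy**2 / b_gx**2 + b_gy**2 * se_gx**2 / b_gx**4))
    else:
        se = se_gy / abs(b_gx)
    return MrResult(exposure_id, outcome_id, level, "wald_ratio", 1,
                    float(beta), float(se), _normal_p(beta, se))


def ivw_estimate(
    instruments: InstrumentSet, mode: str = "multiplicative_random",
) -> tuple[MrResult, HeterogeneityTest]:
    """Inverse-variance-weighted estimate over >= 2 instruments.

    Per-instrument ratios beta_i = b_GY,i / b_GX,i carry first-order SEs
    se_i = se_GY,i / |b_GX,i| and weights w_i = 1/se_i^2.  ``mode`` is
    ``"fixed"`` or ``"multiplicative_random"``; the random-effects SE is the
    fixed SE scaled by max(1, sqrt(Q/df)), never below the fixed SE.
    """
    if mode not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW mode {mode!r}")
    k = instruments.nsnp
    if k < 2:
        raise ValueError("IVW requires >= 2 instruments; use wald_ratio for one")
    if (instruments.b_gx == 0).any():
        raise ZeroDivisionError("IVW undefined with any b_gx = 0")
    ratios = instruments.b_gy / instruments.b_gx
    se_i = instruments.se_gy / np.abs(instruments.b_gx)
    w = 1.0 / se_i**2
    beta = float(np.sum(w * ratios) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    Q = float(np.sum(w * (ratios - beta) ** 2))
    df = k - 1
    het = HeterogeneityTest(Q=Q, df=df, pval=float(stats.chi2.sf(Q, df)))
    se = se_fixed
    if mode == "multiplicative_random":
        se = se_fixed * max(1.0, float(np.sqrt(Q / df)))
    result = MrResult(
        instruments.exposure_id, instruments.outcome_id, instruments.level,
        "ivw", k, beta, se, _normal_p(beta, se),
        q=Q, q_df=df, q_pval=het.pval,
    )
    return result, het


def egger_regression(instruments: InstrumentSet) -> EggerTest:
    """MR-Egger: WLS of b_GY on b_GX with intercept, weights 1/se_GY^2.

    Instrument pairs are first oriented so every exposure beta is
    non-negative (sign-flipping both members), which the intercept's
    directional-pleiotropy interpretation requires.  Intercept p-value is a
    two-sided normal test.
    """
    if instruments.nsnp < 3:
        raise ValueError("MR-Egger requires >= 3 instruments")
    sign = np.where(instruments.b_gx < 0, -1.0, 1.0)
    x = instruments.b_gx * sign
    y = instruments.b_gy * sign
    w = 1.0 / instruments.se_gy**2
    fit = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    intercept, slope = fit.params
    i_se, s_se = fit.bse
    return EggerTest(
        intercept=float(intercept), intercept_se=float(i_se),
        intercept_pval=_normal_p(float(intercept), float(i_se)),
        slope=float(slope), slope_se=float(s_se),
    )


def estimate_from_instruments(
    instruments: InstrumentSet, ivw_mode: str = "multiplicative_random",
) -> MrResult:
    """Dispatch one instrument set: Wald ratio (k=1) or IVW + Q (k>=2) with
    MR-Egger diagnostics when k >= 3; diagnostics stay None when
    inapplicable."""
    if instruments.nsnp == 0:
        raise ValueError("empty instrument set")
    if instruments.nsnp == 1:
        return wald_ratio(
            instruments.b_gx[0], instruments.se_gx[0],
            instruments.b_gy[0], instruments.se_gy[0],
            exposure_id=instruments.exposure_id,
            outcome_id=instruments.outcome_id, level=instruments.level,
        )
    result, _ = ivw_estimate(instruments, mode=ivw_mode)
    if instruments.nsnp >= 3:
        egger = egger_regression(instruments)
        result.egger_intercept = egger.intercept
        result.egger_intercept_se = egger.intercept_se
        result.p_pleio = egger.intercept_pval
    return result


def select_instruments(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    ld: LdMatrix,
    level,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    window_bp: int = DEFAULT_WINDOW_BP,
    palindrome_eaf_window: float = PALINDROME_EAF_WINDOW,
) -> InstrumentSet:
    """Screen -> clump -> harmonize one exposure against the outcome."""
    lv = get_level(level)
    screened = screen_by_pvalue(exposure, lv)
    clumped = ld_clump(screened, ld, r2_threshold=r2_threshold, window_bp=window_bp)
    harmonized = harmonize_tables(
        exposure, outcome, variant_ids=list(clumped["variant_id"]),
        palindrome_eaf_window=palindrome_eaf_window,
    )
    return InstrumentSet.from_harmonized(
        harmonized, exposure.trait_id, outcome.trait_id, lv.label)


def run_univariable_mr(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    ld: LdMatrix,
    levels=("e5", "e6", "e7", "e8"),
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    window_bp: int = DEFAULT_WINDOW_BP,
    palindrome_eaf_window: float = PALINDROME_EAF_WINDOW,
    ivw_mode: str = "multiplicative_random",
) -> list[MrResult]:
    """Univariable MR of one exposure on one outcome at each screening level.

    Levels with no surviving instrument are skipped with a log entry.
    """
    results: list[MrResult] = []
    for level in levels:
        iv = select_instruments(
            exposure, outcome, ld, level,
            r2_threshold=r2_threshold, window_bp=window_bp,
            palindrome_eaf_window=palindrome_eaf_window,
        )
        if iv.nsnp == 0:
            logger.info("level %s: no instruments for %s, skipped",
                        get_level(level).label, exposure.trait_id)
            continue
        results.append(estimate_from_instruments(iv, ivw_mode=ivw_mode))
    return results
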
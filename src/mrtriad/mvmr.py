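"""Multivariable Mendelian randomization (MVMR).

Direct effects of m exposures on the outcome are estimated jointly by
weighted least squares of the per-variant outcome betas on the m-column
matrix of exposure betas, without intercept, weighted by 1/se_GY^2.
Exposures are "retained" at the p < 0.1 rule used for mediator screening.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .estimators import MrResult, Z95, effect_to_or_ci
from .instruments import (
    DEFAULT_R2_THRESHOLD,
    DEFAULT_WINDOW_BP,
    LdMatrix,
    get_level,
    ld_clump,
    screen_by_pvalue,
)
from .sumstats import SummaryStatsTable, harmonize_tables

logger = logging.getLogger(__name__)

RETENTION_P = 0.1


class CollinearityError(ValueError):
    """Raised when the exposure-beta design matrix is rank deficient."""


@dataclass
class MvmrDesign:
    """Per-variant exposure-beta matrix plus outcome effects."""

    outcome_id: str
    exposure_ids: list[str]
    variant_ids: list[str]
    bx: np.ndarray  # (n_variants, m)
    by: np.ndarray
    se_by: np.ndarray

    def __post_init__(self) -> None:
        self.bx = np.atleast_2d(np.asarray(self.bx, dtype=float))
        self.by = np.asarray(self.by, dtype=float)
        self.se_by = np.asarray(self.se_by, dtype=float)
        n, m = self.bx.shape
        if m != len(self.exposure_ids):
            raise ValueError("bx columns must match exposure_ids")
        if len(self.by) != n or len(self.se_by) != n:
            raise ValueError("by/se_by length must match bx rows")
        if (self.se_by <= 0).any():
            raise ValueError("outcome SEs must be positive")
        if n and (self.bx == 0).all(axis=1).any():
            raise ValueError("variant rows with all-zero exposure betas are not allowed")


@dataclass
class MvmrResult:
    """Joint direct-effect estimates; one row per exposure."""

    outcome_id: str
    table: pd.DataFrame  # index: exposure_id; beta, se, pval, or, ci_low, ci_high, retained

    def coefficient(self, exposure_id: str) -> pd.Series:
        return self.table.loc[exposure_id]


def _check_rank(xw: np.ndarray, exposure_ids: list[str]) -> None:
    m = xw.shape[1]
    if np.linalg.matrix_rank(xw) < m:
        # name the most collinear pair for the error message
        c = np.corrcoef(xw, rowvar=False)
        worst, pair = 0.0, tuple(exposure_ids[:2])
        for i in range(m):
            for j in range(i + 1, m):
                if abs(c[i, j]) > worst:
                    worst, pair = abs(c[i, j]), (exposure_ids[i], exposure_ids[j])
        raise CollinearityError(
            f"rank-deficient MVMR design; most collinear exposures: {pair[0]}, {pair[1]}"
        )


def mvmr_fit(design: MvmrDesign, retention_p: float = RETENTION_P) -> MvmrResult:
    """Weighted least squares of outcome betas on exposure betas (no intercept)."""
    n, m = design.bx.shape
    if n <= m:
        raise ValueError(f"MVMR needs more variants ({n}) than exposures ({m})")
    w = 1.0 / design.se_by**2
    xw = design.bx * np.sqrt(w)[:, None]
    _check_rank(xw, design.exposure_ids)
    fit = sm.WLS(design.by, design.bx, weights=w).fit()
    beta = np.asarray(fit.params, dtype=float)
    se = np.asarray(fit.bse, dtype=float)
    pval = 2.0 * stats.norm.sf(np.abs(beta) / se)
    rows = []
    for b, s, p in zip(beta, se, pval):
        or_, lo, hi = effect_to_or_ci(b, s)
        rows.append({"beta": b, "se": s, "pval": p, "or": or_,
                     "ci_low": lo, "ci_high": hi, "retained": p < retention_p})
    table = pd.DataFrame(rows, index=pd.Index(design.exposure_ids, name="exposure"))
    return MvmrResult(outcome_id=design.outcome_id, table=table)


def build_mvmr_design(
    exposure_tables: dict[str, SummaryStatsTable],
    outcome: SummaryStatsTable,
    ld: LdMatrix,
    level="e5",
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> MvmrDesign:
    """Union-of-instruments MVMR design.

    Each exposure is screened and clumped on its own; the union of selected
    variants is re-clumped jointly (ranking each variant by its best p-value
    across exposures).  Exposure betas are looked up for every union variant
    and aligned, with the outcome, to the first contributing exposure's
    effect allele; variants missing from any exposure table are dropped and
    counted in the log.
    """
    lv = get_level(level)
    exposure_ids = list(exposure_tables)
    union_rows = {}
    for eid in exposure_ids:
        screened = screen_by_pvalue(exposure_tables[eid], lv)
        clumped = ld_clump(screened, ld, r2_threshold, window_bp)
        for _, row in clumped.iterrows():
            vid = row["variant_id"]
            if vid not in union_rows or row["pval"] < union_rows[vid]["pval"]:
                union_rows[vid] = row
    if not union_rows:
        raise ValueError("no instruments selected for any exposure")
    union = pd.DataFrame(list(union_rows.values())).reset_index(drop=True)
    union = ld_clump(union, ld, r2_threshold, window_bp)
    union_ids = list(union["variant_id"])

    # align outcome and every exposure to the union variants
    ref = exposure_tables[exposure_ids[0]]
    outcome_h = harmonize_tables(ref, outcome, variant_ids=union_ids)
    aligned: dict[str, pd.DataFrame] = {}
    for eid in exposure_ids:
        h = harmonize_tables(ref, exposure_tables[eid], variant_ids=union_ids)
        aligned[eid] = h.set_index("variant_id")
    out_idx = outcome_h.set_index("variant_id")
    shared = [v for v in union_ids
              if v in out_idx.index and all(v in aligned[e].index for e in exposure_ids)]
    dropped = len(union_ids) - len(shared)
    if dropped:
        logger.info("MVMR design: %d union variants dropped (missing in a table)", dropped)
    bx = np.column_stack([aligned[e].loc[shared, "b_gy"].to_numpy() for e in exposure_ids])
    return MvmrDesign(
        outcome_id=outcome.trait_id,
        exposure_ids=exposure_ids,
        variant_ids=shared,
        bx=bx,
        by=out_idx.loc[shared, "b_gy"].to_numpy(),
        se_by=out_idx.loc[shared, "se_gy"].to_numpy(),
    )


def mvmr_adjusted_effect(
    primary_exposure: str,
    adjust_for: list[str],
    exposure_tables: dict[str, SummaryStatsTable],
    outcome: SummaryStatsTable,
    ld: LdMatrix,
    level="e5",
    **design_kwargs,
) -> MrResult:
    """Primary exposure's direct effect adjusted for the listed exposures.

    Fits the joint model containing the primary exposure plus ``adjust_for``
    and returns the primary coefficient as an MrResult.
    """
    if primary_exposure in adjust_for:
        raise CollinearityError("cannot adjust an exposure for itself")
    ids = [primary_exposure] + list(adjust_for)
    tables = {eid: exposure_tables[eid] for eid in ids}
    design = build_mvmr_design(tables, outcome, ld, level=level, **design_kwargs)
    res = mvmr_fit(design)
    row = res.coefficient(primary_exposure)
    pval = float(2.0 * stats.norm.sf(abs(row["beta"]) / row["se"]))
    return MrResult(
        exposure_id=primary_exposure, outcome_id=outcome.trait_id,
        level=get_level(level).label, method="mvmr", nsnp=len(design.variant_ids),
        beta=float(row["beta"]), se=float(row["se"]), pval=pval,
    )
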
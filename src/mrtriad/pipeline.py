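"""Full analysis pipeline: screen -> MR -> filter -> Bonferroni ->
mediation -> MVMR -> colocalization.

The decision rules mirror a systematic exposure-wide MR screen against a
binary disease outcome: univariable MR at each screening level, retention of
results with MR p < 0.05 and no evidence of heterogeneity or pleiotropy
(Q p > 0.05, Egger intercept p > 0.05, with either diagnostic treated as a
pass when the instrument count is too small for it to apply), Bonferroni
correction of single-instrument (cis) results over the exposure family,
bi-directional mediation among survivors, multivariable MR for exposures
with several mediators, and colocalization around the top cis instrument.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coloc import (
    DEFAULT_P1, DEFAULT_P2, DEFAULT_P12,
    coloc_posteriors, region_pair_from_tables,
)
from .estimators import MrResult, run_univariable_mr, select_instruments
from .instruments import DEFAULT_R2_THRESHOLD, DEFAULT_WINDOW_BP, LdMatrix
from .mediation import bidirectional_scan, mediation_report
from .mvmr import build_mvmr_design, mvmr_fit
from .sumstats import PALINDROME_EAF_WINDOW, SummaryStatsTable

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds and knobs for one full pipeline run."""

    levels: tuple[str, ...] = ("e5", "e6", "e7", "e8")
    p_mr: float = 0.05
    q_pval: float = 0.05
    p_pleio: float = 0.05
    bonferroni_family_size: int | None = None  # default: number of exposures
    mvmr_retention_p: float = 0.1
    mediation_level: str = "e5"
    mediation_alpha: float = 0.05
    coloc_p1: float = DEFAULT_P1
    coloc_p2: float = DEFAULT_P2
    coloc_p12: float = DEFAULT_P12
    coloc_window_bp: int = 50_000
    r2_threshold: float = DEFAULT_R2_THRESHOLD
    window_bp: int = DEFAULT_WINDOW_BP
    palindrome_eaf_window: float = PALINDROME_EAF_WINDOW
    ivw_mode: str = "multiplicative_random"
    outdir: str | None = None
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_mr", "q_pval", "p_pleio", "mvmr_retention_p",
                     "mediation_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.bonferroni_family_size is not None and self.bonferroni_family_size < 1:
            raise ValueError("bonferroni_family_size must be >= 1")


@dataclass
class PipelineOutputs:
    mr_results: pd.DataFrame
    mediation: pd.DataFrame
    mvmr: pd.DataFrame
    coloc: pd.DataFrame
    log: list[str] = field(default_factory=list)


def apply_significance_filter(
    results: list[MrResult],
    p_mr: float = 0.05,
    q_pval: float = 0.05,
    p_pleio: float = 0.05,
) -> list[MrResult]:
    """Keep results with MR p below threshold and no het/pleio evidence.

    A missing diagnostic (instrument count too small for Q or Egger) counts
    as a pass, matching how single-instrument results carry NA diagnostics.
    Order-independent and idempotent.
    """
    kept = []
    for r in results:
        if not r.pval < p_mr:
            continue
        if r.q_pval is not None and not r.q_pval > q_pval:
            continue
        if r.p_pleio is not None and not r.p_pleio > p_pleio:
            continue
        kept.append(r)
    return kept


def bonferroni_adjust(raw_p: float, family_size: int) -> float:
    """min(1, raw_p * family_size)."""
    if not 0.0 < raw_p <= 1.0:
        raise ValueError("raw_p must be in (0, 1]")
    if family_size < 1 or int(family_size) != family_size:
        raise ValueError("family_size must be a positive integer")
    return min(1.0, raw_p * family_size)


def _results_frame(results: list[MrResult]) -> pd.DataFrame:
    cols = ["exposure", "outcome", "method", "level", "nsnp", "beta", "se",
            "or", "ci_low", "ci_high", "p_mr", "Q", "Q_pval",
            "egger_intercept", "p_pleio"]
    return pd.DataFrame([r.to_dict() for r in results], columns=cols)


def run_full(
    exposures: dict[str, SummaryStatsTable],
    outcome: SummaryStatsTable,
    ld: LdMatrix,
    config: PipelineConfig | None = None,
) -> PipelineOutputs:
    """Run every stage in order and (optionally) write the report tables.

    Deterministic given the inputs and config.  Empty inputs produce empty
    report tables and succeed.
    """
    config = config or PipelineConfig()
    config.validate()
    log: list[str] = []

    def stage(msg: str) -> None:
        logger.info(msg)
        log.append(msg)

    # ---- univariable MR over all exposures and levels -------------------
    all_results: list[MrResult] = []
    for eid, table in exposures.items():
        all_results.extend(run_univariable_mr(
            table, outcome, ld, levels=config.levels,
            r2_threshold=config.r2_threshold, window_bp=config.window_bp,
            palindrome_eaf_window=config.palindrome_eaf_window,
            ivw_mode=config.ivw_mode,
        ))
    stage(f"stage=univariable_mr exposures={len(exposures)} "
          f"levels={len(config.levels)} results={len(all_results)}")

    # ---- significance / heterogeneity / pleiotropy filter ---------------
    filtered = apply_significance_filter(
        all_results, config.p_mr, config.q_pval, config.p_pleio)
    stage(f"stage=filter in={len(all_results)} kept={len(filtered)} "
          f"p_mr<{config.p_mr} Q_p>{config.q_pval} pleio_p>{config.p_pleio}")

    # ---- Bonferroni over single-instrument (cis) results ----------------
    family = config.bonferroni_family_size or max(len(exposures), 1)
    mr_df = _results_frame(all_results)
    kept_keys = {(r.exposure_id, r.level, r.method) for r in filtered}
    mr_df["passed_filter"] = [
        (e, l, m) in kept_keys
        for e, l, m in zip(mr_df["exposure"], mr_df["level"], mr_df["method"])
    ]
    mr_df["bonferroni_p"] = [
        bonferroni_adjust(p, family) if method == "wald_ratio" else np.nan
        for p, method in zip(mr_df["p_mr"], mr_df["method"])
    ]
    n_cis = int((mr_df["method"] == "wald_ratio").sum())
    stage(f"stage=bonferroni family_size={family} cis_results={n_cis}")

    # ---- bi-directional mediation among survivors -----------------------
    survivors = sorted({r.exposure_id for r in filtered})
    tables = dict(exposures)
    tables[outcome.trait_id] = outcome
    triangles = []
    if len(survivors) >= 2:
        triangles = bidirectional_scan(
            survivors, survivors, outcome.trait_id, tables, ld,
            level=config.mediation_level, alpha=config.mediation_alpha,
            r2_threshold=config.r2_threshold, window_bp=config.window_bp,
            palindrome_eaf_window=config.palindrome_eaf_window,
            ivw_mode=config.ivw_mode,
        )
    mediation_df = mediation_report(triangles)
    stage(f"stage=mediation survivors={len(survivors)} "
          f"triangles={len(triangles)} reported={len(mediation_df)}")

    # ---- MVMR for exposures with several mediators -----------------------
    mediators_by_exposure: dict[str, list[str]] = {}
    for t in triangles:
        if t.direction_flag == "ambiguous":
            continue
        mediators_by_exposure.setdefault(t.exposure_id, []).append(t.mediator_id)
    mvmr_rows = []
    for eid, meds in sorted(mediators_by_exposure.items()):
        if len(meds) < 2:
            continue
        ids = [eid] + sorted(set(meds))
        try:
            design = build_mvmr_design(
                {i: tables[i] for i in ids}, outcome, ld,
                level=config.mediation_level,
                r2_threshold=config.r2_threshold, window_bp=config.window_bp)
            fit = mvmr_fit(design, retention_p=config.mvmr_retention_p)
        except ValueError as err:
            stage(f"stage=mvmr exposure={eid} skipped ({err})")
            continue
        for trait, row in fit.table.iterrows():
            mvmr_rows.append({
                "primary_exposure": eid, "trait": trait,
                "role": "primary" if trait == eid else "mediator",
                "beta": row["beta"], "se": row["se"], "pval": row["pval"],
                "or": row["or"], "ci_low": row["ci_low"],
                "ci_high": row["ci_high"], "retained": row["retained"],
            })
    mvmr_df = pd.DataFrame(mvmr_rows, columns=[
        "primary_exposure", "trait", "role", "beta", "se", "pval",
        "or", "ci_low", "ci_high", "retained"])
    stage(f"stage=mvmr models={len({r['primary_exposure'] for r in mvmr_rows})} "
          f"rows={len(mvmr_rows)}")

    # ---- colocalization around the top cis instrument --------------------
    coloc_rows = []
    cis = mr_df.loc[mr_df["passed_filter"] & (mr_df["method"] == "wald_ratio")]
    if not cis.empty:
        top = cis.sort_values(["bonferroni_p", "exposure"]).iloc[0]
        iv = select_instruments(
            exposures[top["exposure"]], outcome, ld, top["level"],
            r2_threshold=config.r2_threshold, window_bp=config.window_bp,
            palindrome_eaf_window=config.palindrome_eaf_window)
        if iv.nsnp == 1:
            lead = iv.variant_ids[0]
            try:
                region = region_pair_from_tables(
                    exposures[top["exposure"]], outcome, lead,
                    window_bp=config.coloc_window_bp)
                res = coloc_posteriors(region, config.coloc_p1,
                                       config.coloc_p2, config.coloc_p12)
                coloc_rows.append({
                    "exposure": top["exposure"], "outcome": outcome.trait_id,
                    "lead_variant": lead, "n_variants": res.n_variants,
                    **res.pp,
                })
            except ValueError as err:
                stage(f"stage=coloc skipped ({err})")
    coloc_df = pd.DataFrame(coloc_rows, columns=[
        "exposure", "outcome", "lead_variant", "n_variants",
        "PP.H0", "PP.H1", "PP.H2", "PP.H3", "PP.H4"])
    stage(f"stage=coloc regions={len(coloc_df)}")

    out = PipelineOutputs(mr_results=mr_df, mediation=mediation_df,
                          mvmr=mvmr_df, coloc=coloc_df, log=log)
    if config.outdir:
        os.makedirs(config.outdir, exist_ok=True)
        mr_df.to_csv(os.path.join(config.outdir, "mr_results.tsv"),
                     sep="\t", index=False, na_rep="NA")
        mediation_df.to_csv(os.path.join(config.outdir, "mediation_triangles.tsv"),
                            sep="\t", index=False, na_rep="NA")
        mvmr_df.to_csv(os.path.join(config.outdir, "mvmr_results.tsv"),
                       sep="\t", index=False, na_rep="NA")
        coloc_df.to_csv(os.path.join(config.outdir, "coloc_results.tsv"),
                        sep="\t", index=False, na_rep="NA")
        with open(os.path.join(config.outdir, "run_log.txt"), "w") as fh:
            fh.write("\n".join(log) + "\n")
    return out
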
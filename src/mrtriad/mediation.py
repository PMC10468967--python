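"""Bi-directional mediation MR and the proportion-mediated computation.

For an exposure E, mediator M and outcome O, each edge effect is itself a
univariable MR estimate; the proportion of the total effect of E on O that
is transmitted through M is the product-of-coefficients ratio

    rho_M = (beta_EM * beta_MO) / beta_EO

where beta_EM * beta_MO is the indirect effect and beta_EO the total effect.
A triangle is assembled when all three edges are significant; the scan also
runs each candidate pair in reverse (M -> E) and flags pairs significant in
both directions as ambiguous rather than filtering them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import pandas as pd

from .estimators import MrResult, run_univariable_mr
from .instruments import LdMatrix
from .sumstats import SummaryStatsTable

logger = logging.getLogger(__name__)

EDGE_ALPHA = 0.05  # unadjusted significance gate for triangle edges


class InconsistentMediationWarning(UserWarning):
    """Proportion mediated outside [0, 1] (sign-discordant indirect path)."""


@dataclass
class MediationTriangle:
    """One E -> M -> O mediation relationship."""

    exposure_id: str
    mediator_id: str
    outcome_id: str
    beta_EM: float
    beta_MO: float
    beta_EO: float
    rho_M: float
    direction_flag: str  # "forward" | "reverse" | "ambiguous"


def mediation_proportion(beta_EM: float, beta_MO: float, beta_EO: float) -> float:
    """Proportion mediated (fraction): indirect effect over total effect.

    Values outside [0, 1] (inconsistent mediation) are returned with an
    ``InconsistentMediationWarning`` rather than suppressed.
    """
    if beta_EO == 0:
        raise ZeroDivisionError("proportion mediated undefined for zero total effect")
    rho = beta_EM * beta_MO / beta_EO
    if not 0.0 <= rho <= 1.0:
        warnings.warn(
            f"proportion mediated {rho:.3f} outside [0, 1] (inconsistent mediation)",
            InconsistentMediationWarning,
            stacklevel=2,
        )
    return rho


def _best_result(results: list[MrResult]) -> MrResult | None:
    """The result used for an edge: first level with instruments."""
    return results[0] if results else None


def bidirectional_scan(
    traits_a: list[str],
    traits_b: list[str],
    outcome_id: str,
    tables: dict[str, SummaryStatsTable],
    ld: LdMatrix,
    level="e5",
    alpha: float = EDGE_ALPHA,
    **mr_kwargs,
) -> list[MediationTriangle]:
    """Scan ordered cross-pairs of two trait lists for mediation triangles.

    For every pair (A, B) with A in ``traits_a`` and B in ``traits_b``, MR is
    run in both directions.  A triangle E -> M -> O is assembled whenever the
    three edges E->M, M->O and E->O all reach p < ``alpha``; its flag is
    ``forward`` when E comes from ``traits_a``, ``reverse`` when E comes from
    ``traits_b``, and ``ambiguous`` when the pair is significant in both
    directions (such triangles are excluded from the mediation summary).
    Instrument overlap between exposure and mediator is logged, not filtered.
    """
    outcome = tables[outcome_id]

    def mr(x_id: str, y_id: str) -> MrResult | None:
        return _best_result(run_univariable_mr(
            tables[x_id], tables[y_id], ld, levels=[level], **mr_kwargs))

    to_outcome: dict[str, MrResult | None] = {}
    for tid in set(traits_a) | set(traits_b):
        to_outcome[tid] = mr(tid, outcome_id)

    triangles: list[MediationTriangle] = []
    seen: set[frozenset] = set()  # overlapping lists: visit each pair once
    for a in traits_a:
        for b in traits_b:
            if a == b:
                continue
            key = frozenset((a, b))
            if key in seen:
                continue
            seen.add(key)
            res_ab = mr(a, b)
            res_ba = mr(b, a)
            sig_ab = res_ab is not None and res_ab.pval < alpha
            sig_ba = res_ba is not None and res_ba.pval < alpha
            for exp_id, med_id, em, flag in (
                (a, b, res_ab, "forward"),
                (b, a, res_ba, "reverse"),
            ):
                em_sig = sig_ab if flag == "forward" else sig_ba
                if not em_sig:
                    continue
                mo = to_outcome[med_id]
                eo = to_outcome[exp_id]
                if mo is None or eo is None:
                    continue
                if mo.pval >= alpha or eo.pval >= alpha or eo.beta == 0:
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", InconsistentMediationWarning)
                    rho = mediation_proportion(em.beta, mo.beta, eo.beta)
                triangles.append(MediationTriangle(
                    exposure_id=exp_id, mediator_id=med_id, outcome_id=outcome_id,
                    beta_EM=em.beta, beta_MO=mo.beta, beta_EO=eo.beta,
                    rho_M=rho,
                    direction_flag="ambiguous" if (sig_ab and sig_ba) else flag,
                ))
    logger.info("bidirectional scan: %d triangles over %d x %d traits",
                len(triangles), len(traits_a), len(traits_b))
    return triangles


def mediation_report(
    triangles: list[MediationTriangle], include_ambiguous: bool = False,
) -> pd.DataFrame:
    """One row per triangle; proportion mediated as a percent to one decimal.

    Ambiguous (bidirectional) triangles are excluded from the summary unless
    requested; inconsistent proportions (outside [0, 1]) are kept but marked.
    """
    rows = []
    for t in triangles:
        if t.direction_flag == "ambiguous" and not include_ambiguous:
            continue
        rows.append({
            "exposure": t.exposure_id, "mediator": t.mediator_id,
            "outcome": t.outcome_id,
            "beta_EM": t.beta_EM, "beta_MO": t.beta_MO, "beta_EO": t.beta_EO,
            "rho_M_pct": f"{100.0 * t.rho_M:.1f}%",
            "direction_flag": t.direction_flag,
            "consistent": bool(0.0 <= t.rho_M <= 1.0),
        })
    return pd.DataFrame(rows, columns=[
        "exposure", "mediator", "outcome", "beta_EM", "beta_MO", "beta_EO",
        "rho_M_pct", "direction_flag", "consistent",
    ])
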
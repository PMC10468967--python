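"""Approximate-Bayes-factor colocalization over a two-trait region.

Under a single-causal-variant assumption per trait, each variant's evidence
of association is summarized by the Wakefield approximate Bayes factor
computed from (beta, se) with a normal effect prior N(0, prior_sd^2):

    log ABF = 0.5 * log(V / (V + W)) + z^2 W / (2 (V + W)),

with V = se^2, W = prior_sd^2, z = beta/se.  Regional evidence for the five
hypotheses (H0 no association, H1/H2 association with one trait only,
H3 two distinct causal variants, H4 one shared causal variant) combines the
per-variant ABFs with per-variant priors p1, p2 and p12, all accumulated in
log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .sumstats import SummaryStatsTable

DEFAULT_P1 = 1e-4
DEFAULT_P2 = 1e-4
DEFAULT_P12 = 1e-5
DEFAULT_WINDOW_BP = 50_000

#: effect-size prior SD by trait type (log-odds for binary traits)
DEFAULT_PRIOR_SD = {"quantitative": 0.2, "binary": 0.15}


@dataclass
class RegionPair:
    """Aligned per-variant (beta, se) vectors for two traits over one region."""

    variant_ids: list[str]
    beta1: np.ndarray
    se1: np.ndarray
    beta2: np.ndarray
    se2: np.ndarray
    trait_types: tuple[str, str] = ("quantitative", "quantitative")
    lead_variant_id: str | None = None
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        k = len(self.variant_ids)
        for name in ("beta1", "se1", "beta2", "se2"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (k,):
                raise ValueError(f"{name} must have length {k} (aligned variant lists)")
        if (self.se1 <= 0).any() or (self.se2 <= 0).any():
            raise ValueError("standard errors must be positive")
        if self.lead_variant_id is not None and self.lead_variant_id not in self.variant_ids:
            raise ValueError("window must contain the lead variant")

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)


@dataclass
class ColocResult:
    """Posterior probabilities of the five colocalization hypotheses."""

    pp: dict[str, float]  # keys PP.H0 .. PP.H4, summing to 1
    priors: dict[str, float]
    n_variants: int
    log_abf: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        total = sum(self.pp.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"posteriors sum to {total}, not 1")


def wakefield_abf(beta, se, prior_sd: float) -> np.ndarray:
    """Log approximate Bayes factor(s) for association at one variant.

    Vectorized over ``beta``/``se``; strictly increasing in |beta/se| at
    fixed se and prior_sd.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if (se <= 0).any():
        raise ValueError("se must be positive")
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    V = se**2
    W = prior_sd**2
    z2 = (beta / se) ** 2
    return 0.5 * np.log(V / (V + W)) + z2 * W / (2.0 * (V + W))


def _logdiffexp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a >= b; -inf when the difference underflows."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_posteriors(
    region: RegionPair,
    p1: float = DEFAULT_P1,
    p2: float = DEFAULT_P2,
    p12: float = DEFAULT_P12,
    prior_sd: tuple[float, float] | None = None,
) -> ColocResult:
    """Posterior probabilities PP.H0..PP.H4 for one region.

    Hypothesis sums over per-variant Bayes factors BF1, BF2 (log-sum-exp
    arithmetic throughout):

        H0: 1                H1: p1 * sum BF1        H2: p2 * sum BF2
        H3: p1 p2 * (sum BF1 * sum BF2 - sum BF1*BF2)
        H4: p12 * sum BF1*BF2
    """
    if region.n_variants < 2:
        raise ValueError("colocalization requires >= 2 shared variants")
    for p, name in ((p1, "p1"), (p2, "p2"), (p12, "p12")):
        if not 0 < p < 1:
            raise ValueError(f"{name} must be in (0, 1)")
    if prior_sd is None:
        prior_sd = (DEFAULT_PRIOR_SD[region.trait_types[0]],
                    DEFAULT_PRIOR_SD[region.trait_types[1]])
    labf1 = wakefield_abf(region.beta1, region.se1, prior_sd[0])
    labf2 = wakefield_abf(region.beta2, region.se2, prior_sd[1])
    s1 = float(logsumexp(labf1))
    s2 = float(logsumexp(labf2))
    s12 = float(logsumexp(labf1 + labf2))
    lh = np.array([
        0.0,
        np.log(p1) + s1,
        np.log(p2) + s2,
        np.log(p1) + np.log(p2) + _logdiffexp(s1 + s2, s12),
        np.log(p12) + s12,
    ])
    pp = np.exp(lh - logsumexp(lh))
    pp /= pp.sum()
    labels = ["PP.H0", "PP.H1", "PP.H2", "PP.H3", "PP.H4"]
    table = pd.DataFrame({
        "variant_id": region.variant_ids, "log_abf1": labf1, "log_abf2": labf2,
    })
    return ColocResult(
        pp=dict(zip(labels, map(float, pp))),
        priors={"p1": p1, "p2": p2, "p12": p12,
                "prior_sd1": prior_sd[0], "prior_sd2": prior_sd[1]},
        n_variants=region.n_variants,
        log_abf=table,
    )


def extract_region(table: SummaryStatsTable, lead_variant_id: str,
                   window_bp: int = DEFAULT_WINDOW_BP) -> pd.DataFrame:
    """Variants on the lead's chromosome within +/- window_bp (closed
    interval), sorted by position."""
    lead = table.data.loc[table.data["variant_id"] == lead_variant_id]
    if lead.empty:
        raise KeyError(f"lead variant {lead_variant_id} not in {table.trait_id}")
    chrom = lead.iloc[0]["chrom"]
    pos = int(lead.iloc[0]["pos"])
    df = table.data
    mask = (df["chrom"] == chrom) & ((df["pos"] - pos).abs() <= window_bp)
    return df.loc[mask].sort_values("pos", kind="mergesort").reset_index(drop=True)


def region_pair_from_tables(
    trait1: SummaryStatsTable,
    trait2: SummaryStatsTable,
    lead_variant_id: str,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> RegionPair:
    """Build an aligned RegionPair from two tables around a lead variant.

    Effect orientation does not matter for the ABF (it depends on z^2), so
    variants are matched by id without allele harmonization.
    """
    r1 = extract_region(trait1, lead_variant_id, window_bp).set_index("variant_id")
    r2 = trait2.data.set_index("variant_id")
    shared = [v for v in r1.index if v in r2.index]
    if len(shared) < 2:
        raise ValueError("fewer than 2 shared variants in the region")
    return RegionPair(
        variant_ids=shared,
        beta1=r1.loc[shared, "beta"].to_numpy(),
        se1=r1.loc[shared, "se"].to_numpy(),
        beta2=r2.loc[shared, "beta"].to_numpy(),
        se2=r2.loc[shared, "se"].to_numpy(),
        trait_types=(trait1.trait_type, trait2.trait_type),
        lead_variant_id=lead_variant_id,
        positions=r1.loc[shared, "pos"].to_numpy(),
    )
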
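"""GWAS summary-statistics I/O and exposure-outcome harmonization.

Tables are tab-delimited text with a fixed canonical schema (one row per
variant): ``variant_id, chrom, pos, effect_allele, other_allele, eaf, beta,
se, pval, n`` with ``NA`` for missing values.  Betas for binary traits are on
the log-odds scale.  Harmonization aligns an outcome association to the
exposure's effect allele, resolving allele swaps and strand flips, and drops
palindromic (A/T, C/G) variants whose orientation cannot be resolved from the
effect-allele frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]
MANDATORY_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "beta", "se", "pval",
]
VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default half-width of the EAF window around 0.5 inside which a
#: palindromic variant's strand cannot be resolved and it is dropped
PALINDROME_EAF_WINDOW = 0.08


class SumstatsFormatError(ValueError):
    """Raised when a summary-statistics file is structurally unusable."""


@dataclass(frozen=True)
class VariantAssoc:
    """One variant's association with one trait."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: float | None = None

    def is_palindromic(self) -> bool:
        return self.other_allele == COMPLEMENT[self.effect_allele]


@dataclass
class SummaryStatsTable:
    """Summary statistics for one trait over a panel of variants."""

    trait_id: str
    data: pd.DataFrame
    trait_type: str = "quantitative"  # or "binary"
    case_fraction: float | None = None
    n_rejected: int = 0

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        missing = [c for c in CANONICAL_COLUMNS if c not in self.data.columns]
        if missing:
            raise SumstatsFormatError(f"missing columns: {missing}")
        if self.data["variant_id"].duplicated().any():
            dups = self.data.loc[self.data["variant_id"].duplicated(), "variant_id"]
            raise SumstatsFormatError(
                f"duplicate variant_id in {self.trait_id}: {sorted(set(dups))[:5]}"
            )

    def __len__(self) -> int:
        return len(self.data)

    def row(self, variant_id: str) -> VariantAssoc:
        sub = self.data.loc[self.data["variant_id"] == variant_id]
        if sub.empty:
            raise KeyError(f"{variant_id} not in table {self.trait_id}")
        return _row_to_assoc(sub.iloc[0])

    def lookup(self) -> dict[str, VariantAssoc]:
        """variant_id -> VariantAssoc map over the whole table."""
        return {r.variant_id: r for r in (_row_to_assoc(t) for _, t in self.data.iterrows())}


def _row_to_assoc(row: pd.Series) -> VariantAssoc:
    eaf = row["eaf"]
    n = row["n"]
    return VariantAssoc(
        variant_id=str(row["variant_id"]),
        chrom=str(row["chrom"]),
        pos=int(row["pos"]),
        effect_allele=str(row["effect_allele"]),
        other_allele=str(row["other_allele"]),
        beta=float(row["beta"]),
        se=float(row["se"]),
        pval=float(row["pval"]),
        eaf=None if pd.isna(eaf) else float(eaf),
        n=None if pd.isna(n) else float(n),
    )


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Split rows into (valid, n_rejected), logging each rejection reason."""
    reasons = pd.Series("", index=df.index)
    bad_allele = (~df["effect_allele"].isin(VALID_ALLELES)
                  | ~df["other_allele"].isin(VALID_ALLELES))
    reasons[bad_allele] = "invalid allele"
    reasons[(reasons == "") & (df["effect_allele"] == df["other_allele"])] = "identical alleles"
    reasons[(reasons == "") & ~(df["se"] > 0)] = "non-positive se"
    reasons[(reasons == "") & (~(df["pval"] > 0) | (df["pval"] > 1))] = "pval outside (0,1]"
    eaf_bad = df["eaf"].notna() & ((df["eaf"] < 0) | (df["eaf"] > 1))
    reasons[(reasons == "") & eaf_bad] = "eaf outside [0,1]"
    rejected = reasons != ""
    for vid, why in zip(df.loc[rejected, "variant_id"], reasons[rejected]):
        logger.warning("rejecting variant %s: %s", vid, why)
    return df.loc[~rejected].copy(), int(rejected.sum())


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_id: str | None = None,
    trait_type: str = "quantitative",
    case_fraction: float | None = None,
) -> SummaryStatsTable:
    """Read a tab-delimited summary-statistics file.

    ``column_map`` maps file headers to canonical field names (e.g.
    ``{"BETA": "beta"}``).  Rows violating per-variant invariants (se <= 0,
    p outside (0,1], malformed alleles) are dropped and counted in
    ``n_rejected``; row order is otherwise preserved.
    """
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "chrom": str},
                     na_values=["NA"], keep_default_na=True)
    if column_map:
        df = df.rename(columns=dict(column_map))
        if "chrom" in df.columns:
            df["chrom"] = df["chrom"].astype(str)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SumstatsFormatError(f"{path}: missing mandatory columns {missing}")
    for optional in ("eaf", "n"):
        if optional not in df.columns:
            df[optional] = np.nan
    df = df[CANONICAL_COLUMNS]
    df = df.astype({"pos": "int64", "eaf": float, "beta": float,
                    "se": float, "pval": float, "n": float})
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
    valid, n_rejected = _validate_rows(df)
    valid = valid.reset_index(drop=True)
    return SummaryStatsTable(
        trait_id=trait_id or str(path),
        data=valid,
        trait_type=trait_type,
        case_fraction=case_fraction,
        n_rejected=n_rejected,
    )


def write_sumstats(table: SummaryStatsTable, path) -> str:
    """Write a table in the canonical tab-delimited format ('NA' = missing)."""
    table.data[CANONICAL_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")
    return str(path)


@dataclass(frozen=True)
class HarmonizationResult:
    """Outcome of aligning one outcome association to the exposure allele.

    ``status`` is ``"ok"`` (aligned pair returned), ``"drop_palindromic"``
    (ambiguous strand) or ``"incompatible"`` (allele sets irreconcilable).
    """

    status: str
    exposure: VariantAssoc | None = None
    outcome: VariantAssoc | None = None
    reason: str = ""

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def _swap(v: VariantAssoc) -> VariantAssoc:
    return replace(
        v,
        effect_allele=v.other_allele,
        other_allele=v.effect_allele,
        beta=-v.beta,
        eaf=None if v.eaf is None else 1.0 - v.eaf,
    )


def _strand_flip(v: VariantAssoc) -> VariantAssoc:
    return replace(
        v,
        effect_allele=COMPLEMENT[v.effect_allele],
        other_allele=COMPLEMENT[v.other_allele],
    )


def harmonize_pair(
    exposure: VariantAssoc,
    outcome: VariantAssoc,
    palindrome_eaf_window: float = PALINDROME_EAF_WINDOW,
) -> HarmonizationResult:
    """Align ``outcome`` to the exposure's effect allele.

    Handles direct matches, allele swaps (outcome beta sign flips), strand
    flips (A<->T, C<->G relabelling) and swapped strand flips.  Palindromic
    variants are oriented by comparing which side of 0.5 the two EAFs fall
    on, and dropped when either EAF is missing or the exposure EAF lies
    within ``palindrome_eaf_window`` of 0.5.
    """
    if exposure.variant_id != outcome.variant_id:
        raise ValueError("harmonize_pair requires the same variant_id")

    exp_pair = (exposure.effect_allele, exposure.other_allele)

    if exposure.is_palindromic():
        if exposure.eaf is None or abs(exposure.eaf - 0.5) <= palindrome_eaf_window:
            return HarmonizationResult(
                "drop_palindromic",
                reason="exposure EAF missing or too close to 0.5",
            )
        out = outcome
        if (out.effect_allele, out.other_allele) == (exp_pair[1], exp_pair[0]):
            out = _swap(out)
        elif (out.effect_allele, out.other_allele) != exp_pair:
            return HarmonizationResult(
                "incompatible", reason="allele sets differ for palindromic variant"
            )
        if out.eaf is None or abs(out.eaf - 0.5) <= palindrome_eaf_window:
            return HarmonizationResult(
                "drop_palindromic",
                reason="outcome EAF missing or too close to 0.5",
            )
        # same strand iff minor/major sides agree; otherwise the outcome was
        # reported on the opposite strand, which for a palindrome is a swap
        if (exposure.eaf < 0.5) != (out.eaf < 0.5):
            out = _swap(out)
            out = _strand_flip(out)  # restore allele labels after the swap
        return HarmonizationResult("ok", exposure=exposure, outcome=out)

    out_pair = (outcome.effect_allele, outcome.other_allele)
    if set(out_pair) != set(exp_pair):
        flipped = _strand_flip(outcome)
        if {flipped.effect_allele, flipped.other_allele} != set(exp_pair):
            return HarmonizationResult(
                "incompatible",
                reason=f"alleles {out_pair} irreconcilable with {exp_pair}",
            )
        outcome = flipped
        out_pair = (outcome.effect_allele, outcome.other_allele)
    if out_pair == exp_pair:
        return HarmonizationResult("ok", exposure=exposure, outcome=outcome)
    return HarmonizationResult("ok", exposure=exposure, outcome=_swap(outcome))


def harmonize_tables(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    variant_ids=None,
    palindrome_eaf_window: float = PALINDROME_EAF_WINDOW,
) -> pd.DataFrame:
    """Harmonize shared variants of two tables into a paired effect frame.

    Returns a DataFrame with columns ``variant_id, chrom, pos, effect_allele,
    other_allele, b_gx, se_gx, pval_gx, eaf_gx, b_gy, se_gy, pval_gy`` for
    every shared variant that survives harmonization, in exposure order.
    """
    out_lookup = {vid: i for i, vid in enumerate(outcome.data["variant_id"])}
    rows = []
    exp_df = exposure.data
    if variant_ids is not None:
        keep = set(variant_ids)
        exp_df = exp_df.loc[exp_df["variant_id"].isin(keep)]
    for _, exp_row in exp_df.iterrows():
        vid = exp_row["variant_id"]
        idx = out_lookup.get(vid)
        if idx is None:
            continue
        res = harmonize_pair(
            _row_to_assoc(exp_row),
            _row_to_assoc(outcome.data.iloc[idx]),
            palindrome_eaf_window=palindrome_eaf_window,
        )
        if not res.ok:
            logger.debug("variant %s dropped in harmonization: %s", vid, res.reason)
            continue
        e, o = res.exposure, res.outcome
        rows.append({
            "variant_id": e.variant_id, "chrom": e.chrom, "pos": e.pos,
            "effect_allele": e.effect_allele, "other_allele": e.other_allele,
            "b_gx": e.beta, "se_gx": e.se, "pval_gx": e.pval,
            "eaf_gx": np.nan if e.eaf is None else e.eaf,
            "b_gy": o.beta, "se_gy": o.se, "pval_gy": o.pval,
        })
    return pd.DataFrame(
        rows,
        columns=["variant_id", "chrom", "pos", "effect_allele", "other_allele",
                 "b_gx", "se_gx", "pval_gx", "eaf_gx", "b_gy", "se_gy", "pval_gy"],
    )
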
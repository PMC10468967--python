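"""Instrument screening and LD clumping.

Candidate instruments are screened at four genome-wide significance levels
(p < 1e-5 .. 1e-8, strict inequality) and then reduced to linkage-
disequilibrium-independent representatives by greedy clumping: the most
significant remaining candidate is kept and every other candidate with
r^2 at or above the threshold within the window is removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sumstats import SummaryStatsTable

DEFAULT_R2_THRESHOLD = 0.001
DEFAULT_WINDOW_BP = 10_000_000


@dataclass(frozen=True)
class ScreeningLevel:
    """A p-value screening level, e.g. e5 = p < 1e-5."""

    label: str
    threshold: float


LEVELS: dict[str, ScreeningLevel] = {
    "e5": ScreeningLevel("e5", 1e-5),
    "e6": ScreeningLevel("e6", 1e-6),
    "e7": ScreeningLevel("e7", 1e-7),
    "e8": ScreeningLevel("e8", 1e-8),
}


def get_level(level: "str | ScreeningLevel") -> ScreeningLevel:
    if isinstance(level, ScreeningLevel):
        return level
    try:
        return LEVELS[level]
    except KeyError:
        raise KeyError(f"unknown screening level {level!r}; expected one of {list(LEVELS)}")


@dataclass
class LdMatrix:
    """Squared-correlation (r^2) matrix over an ordered variant panel."""

    variant_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.variant_ids = list(self.variant_ids)
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.variant_ids)
        if self.r2.shape != (n, n):
            raise ValueError(f"r2 shape {self.r2.shape} does not match {n} variants")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise ValueError("r2 matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise ValueError("r2 diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise ValueError("r2 values must lie in [0, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def value(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    def to_file(self, path) -> str:
        df = pd.DataFrame(self.r2, index=self.variant_ids, columns=self.variant_ids)
        df.to_csv(path, sep="\t", index_label="variant_id")
        return str(path)

    @classmethod
    def from_file(cls, path) -> "LdMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns), df.to_numpy())


def screen_by_pvalue(table: SummaryStatsTable, level) -> pd.DataFrame:
    """Rows with exposure p strictly below the level threshold, in order."""
    lv = get_level(level)
    return table.data.loc[table.data["pval"] < lv.threshold].copy()


def ld_clump(
    candidates: pd.DataFrame,
    ld: LdMatrix,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> pd.DataFrame:
    """Greedy LD clumping of candidate rows (canonical sumstats columns).

    Repeatedly keeps the remaining candidate with the smallest p-value
    (ties broken by smaller chrom/pos) and removes every other candidate on
    the same chromosome within ``window_bp`` whose r^2 with it is at or
    above ``r2_threshold``.  Output preserves the input row order.
    """
    if candidates.empty:
        return candidates.copy()
    missing = [v for v in candidates["variant_id"] if v not in ld]
    if missing:
        raise KeyError(f"candidates absent from LD matrix: {missing[:5]}")

    df = candidates.reset_index(drop=True)
    order = df.sort_values(
        ["pval", "chrom", "pos", "variant_id"], kind="mergesort"
    ).index
    alive = np.ones(len(df), dtype=bool)
    kept: list[int] = []
    vids = df["variant_id"].to_numpy()
    chroms = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy()
    for i in order:
        if not alive[i]:
            continue
        kept.append(i)
        same = alive & (chroms == chroms[i]) & (np.abs(pos - pos[i]) <= window_bp)
        same[i] = False
        if same.any():
            li = ld._index[vids[i]]
            lj = np.array([ld._index[v] for v in vids[same]])
            high = ld.r2[li, lj] >= r2_threshold
            idx = np.flatnonzero(same)[high]
            alive[idx] = False
        alive[i] = False
    return df.iloc[sorted(kept)].copy()


@dataclass
class InstrumentSet:
    """Harmonized exposure/outcome effects for a set of selected instruments."""

    exposure_id: str
    outcome_id: str
    level: str
    variant_ids: list[str]
    b_gx: np.ndarray
    se_gx: np.ndarray
    b_gy: np.ndarray
    se_gy: np.ndarray

    def __post_init__(self) -> None:
        self.b_gx = np.asarray(self.b_gx, dtype=float)
        self.se_gx = np.asarray(self.se_gx, dtype=float)
        self.b_gy = np.asarray(self.b_gy, dtype=float)
        self.se_gy = np.asarray(self.se_gy, dtype=float)
        k = len(self.variant_ids)
        for name in ("b_gx", "se_gx", "b_gy", "se_gy"):
            if getattr(self, name).shape != (k,):
                raise ValueError(f"{name} must have length {k}")
        if (self.se_gx <= 0).any() or (self.se_gy <= 0).any():
            raise ValueError("standard errors must be positive")

    @property
    def nsnp(self) -> int:
        return len(self.variant_ids)

    @classmethod
    def from_harmonized(cls, harmonized: pd.DataFrame, exposure_id: str,
                        outcome_id: str, level: str) -> "InstrumentSet":
        return cls(
            exposure_id=exposure_id,
            outcome_id=outcome_id,
            level=level,
            variant_ids=list(harmonized["variant_id"]),
            b_gx=harmonized["b_gx"].to_numpy(),
            se_gx=harmonized["se_gx"].to_numpy(),
            b_gy=harmonized["b_gy"].to_numpy(),
            se_gy=harmonized["se_gy"].to_numpy(),
        )
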
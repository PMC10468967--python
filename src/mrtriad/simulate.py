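"""Synthetic two-sample GWAS summary statistics with known causal truth.

Summary statistics are simulated directly at the summary level (no
individual-level genotypes): an observed per-variant beta is its true
marginal effect plus normal noise at the analytic standard error

    quantitative trait:  se = 1 / sqrt(2 p (1-p) n)
    binary trait:        se = 1 / sqrt(2 p (1-p) n cf (1-cf))

with p the effect-allele frequency, n the GWAS sample size and cf the case
fraction (log-odds scale betas).  This yields the correct two-sample
sampling distributions at desk scale.

The default study emulates the shape of a microbiome/metabolome-to-disease
MR design at roughly 1/100 of its size: 20 exposure traits with 2-26
instruments each (instrument GWAS n = 18,473), one binary outcome
(n = 1,388,342, case fraction 5101/1,388,342), a handful of truly causal
exposures (theta = 0.5 on the log-odds scale), one planted
exposure->exposure chain for mediation, block-AR(1) LD with satellite
variants around each instrument so that clumping has work to do, and random
allele orientation of the outcome table so that harmonization has work to
do.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .coloc import RegionPair
from .instruments import LdMatrix
from .sumstats import CANONICAL_COLUMNS, SummaryStatsTable, write_sumstats

ALLELE_PAIRS = [(a, b) for a in "ACGT" for b in "ACGT" if a != b]


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for a synthetic two-sample MR study."""

    n_exposures: int = 20
    n_causal: int = 5
    theta_causal: float = 0.5
    k_min: int = 2                      # instruments per exposure, inclusive range
    k_max: int = 26
    n_satellites: int = 2               # high-LD companions per instrument
    n_null_variants: int = 50           # panel-wide sub-threshold filler
    rho: float = 0.9                    # AR(1) correlation within an LD block
    exposure_n: int = 18_473
    mediator_n: int = 7_824
    outcome_n: int = 1_388_342
    case_fraction: float = 5101 / 1_388_342
    pleiotropy: str = "none"            # none | balanced | directional
    pleiotropy_scale: float = 0.0
    instrument_effect_range: tuple[float, float] = (0.045, 0.13)
    eaf_range: tuple[float, float] = (0.05, 0.95)
    #: planted chains (source exposure index, target exposure index, theta_EM)
    chains: tuple[tuple[int, int, float], ...] = ((0, 1, 0.5),)
    # colocalization-region parameters
    coloc_n_variants: int = 200
    coloc_n: int = 50_000
    coloc_beta: float = 0.05
    coloc_causal_index: int = 100
    coloc_causal_index2: int = 160
    seed: int = 0

    def validate(self) -> None:
        if self.n_exposures < 1 or self.k_min < 1 or self.k_max < self.k_min:
            raise ValueError("invalid exposure/instrument counts")
        if not 0 <= self.n_causal <= self.n_exposures:
            raise ValueError("n_causal must be within [0, n_exposures]")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")
        if not 0.0 < self.case_fraction < 1.0:
            raise ValueError("case_fraction must be in (0, 1)")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy model {self.pleiotropy!r}")
        lo, hi = self.instrument_effect_range
        if not 0 < lo <= hi:
            raise ValueError("invalid instrument effect range")
        lo, hi = self.eaf_range
        if not 0 < lo <= hi < 1:
            raise ValueError("invalid eaf range")
        for src, tgt, _ in self.chains:
            if not (0 <= src < self.n_exposures and 0 <= tgt < self.n_exposures):
                raise ValueError("chain indices out of range")
            if src == tgt:
                raise ValueError("chain source and target must differ")


@dataclass
class TruthSet:
    """Ground truth behind one simulated dataset."""

    theta_direct: dict[str, float]
    theta_total: dict[str, float]
    instruments: dict[str, list[str]]
    chains: list[tuple[str, str, float]]
    triangles: list[dict]
    seed: int

    def to_json(self, path) -> str:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
        return str(path)


@dataclass
class SimulatedStudy:
    exposures: dict[str, SummaryStatsTable]
    outcome: SummaryStatsTable
    ld: LdMatrix
    truth: TruthSet
    config: SimConfig


def _se_quantitative(eaf: np.ndarray, n: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)


def _se_binary(eaf: np.ndarray, n: float, case_fraction: float) -> np.ndarray:
    return 1.0 / np.sqrt(
        2.0 * eaf * (1.0 - eaf) * n * case_fraction * (1.0 - case_fraction))


def _observed(true_beta: np.ndarray, se: np.ndarray, rng: np.random.Generator):
    beta_hat = true_beta + rng.normal(0.0, se)
    pval = 2.0 * stats.norm.sf(np.abs(beta_hat) / se)
    return beta_hat, np.clip(pval, np.finfo(float).tiny, 1.0)


def _panel_frame(vids, chroms, pos, alleles, eaf) -> pd.DataFrame:
    return pd.DataFrame({
        "variant_id": vids, "chrom": chroms, "pos": pos,
        "effect_allele": [a for a, _ in alleles],
        "other_allele": [b for _, b in alleles],
        "eaf": eaf,
    })


def _table_from_panel(trait_id, panel, beta_hat, se, pval, n, trait_type,
                      case_fraction=None) -> SummaryStatsTable:
    df = panel.copy()
    df["beta"] = beta_hat
    df["se"] = se
    df["pval"] = pval
    df["n"] = float(n)
    return SummaryStatsTable(trait_id=trait_id, data=df[CANONICAL_COLUMNS],
                             trait_type=trait_type, case_fraction=case_fraction)


def _scramble_orientation(panel: pd.DataFrame, beta: np.ndarray,
                          rng: np.random.Generator):
    """Randomly re-orient each variant (swap / strand-flip / keep) so that
    harmonization against the generating orientation is exercised."""
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    out = panel.copy()
    beta = beta.copy()
    mode = rng.integers(0, 3, size=len(panel))
    ea = out["effect_allele"].to_numpy(object)
    oa = out["other_allele"].to_numpy(object)
    eaf = out["eaf"].to_numpy(float)
    for i, m in enumerate(mode):
        if m == 1:  # allele swap
            ea[i], oa[i] = oa[i], ea[i]
            beta[i] = -beta[i]
            eaf[i] = 1.0 - eaf[i]
        elif m == 2:  # strand flip
            ea[i], oa[i] = comp[ea[i]], comp[oa[i]]
    out["effect_allele"] = ea
    out["other_allele"] = oa
    out["eaf"] = eaf
    return out, beta


def simulate_exposure_outcome(config: SimConfig) -> SimulatedStudy:
    """Simulate the full study: exposure tables, outcome table, LD, truth.

    Exposures are named ``exposure_01`` ...; the first ``n_causal`` carry a
    direct log-odds effect ``theta_causal`` on the outcome.  Planted chains
    add ``theta_EM *`` (source instrument effects) to the target exposure, so
    the source's total outcome effect is ``theta_src + theta_EM * theta_tgt``.
    Every trait table covers the whole variant panel; the outcome table's
    allele orientation is randomly scrambled.  Deterministic given
    ``config`` (the seed lives inside it).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    E = config.n_exposures
    exposure_ids = [f"exposure_{i + 1:02d}" for i in range(E)]
    block = 1 + config.n_satellites

    vids, chroms, pos, alleles, eaf_list = [], [], [], [], []
    own_effect_rows = []  # (variant index, exposure index, true effect)
    instruments: dict[str, list[str]] = {eid: [] for eid in exposure_ids}
    pleio = []  # per-variant pleiotropic outcome effect
    counter = 0
    lo, hi = config.instrument_effect_range
    for e in range(E):
        k = int(rng.integers(config.k_min, config.k_max + 1))
        chrom = str(e % 22 + 1)
        pos_offset = (e // 22) * 1_000_000_000
        for i in range(k):
            sign = float(rng.choice([-1.0, 1.0]))
            a = sign * float(rng.uniform(lo, hi))
            # pleiotropic outcome effects are defined relative to the
            # exposure-increasing allele (hence the sign alignment), which is
            # what a directional Egger intercept measures
            if config.pleiotropy == "balanced":
                alpha = float(rng.normal(0.0, config.pleiotropy_scale))
            elif config.pleiotropy == "directional":
                alpha = sign * float(rng.normal(config.pleiotropy_scale,
                                                config.pleiotropy_scale / 2.0))
            else:
                alpha = 0.0
            block_eaf = float(rng.uniform(*config.eaf_range))
            base = pos_offset + 1_000_000 + i * 20_000_000
            for d in range(block):
                vid = f"rs{counter + 1}"
                counter += 1
                vids.append(vid)
                chroms.append(chrom)
                pos.append(base + d * 1_000)
                alleles.append(ALLELE_PAIRS[rng.integers(0, len(ALLELE_PAIRS))])
                eaf_list.append(block_eaf)
                attenuation = config.rho ** d
                own_effect_rows.append((len(vids) - 1, e, a * attenuation))
                pleio.append(alpha * attenuation)
                if d == 0:
                    instruments[exposure_ids[e]].append(vid)
    for j in range(config.n_null_variants):
        vids.append(f"rs{counter + 1}")
        counter += 1
        chroms.append("0")
        pos.append(1_000_000 + j * 20_000_000)
        alleles.append(ALLELE_PAIRS[rng.integers(0, len(ALLELE_PAIRS))])
        eaf_list.append(float(rng.uniform(*config.eaf_range)))
        pleio.append(0.0)

    n_var = len(vids)
    panel = _panel_frame(vids, chroms, np.asarray(pos, dtype=np.int64),
                         alleles, np.asarray(eaf_list))
    B_own = np.zeros((n_var, E))
    for v, e, a in own_effect_rows:
        B_own[v, e] = a
    B = B_own.copy()
    for src, tgt, theta_em in config.chains:
        B[:, tgt] += theta_em * B_own[:, src]

    theta_direct = np.zeros(E)
    theta_direct[: config.n_causal] = config.theta_causal
    outcome_true = B @ theta_direct + np.asarray(pleio)

    # block-diagonal AR(1) LD over instrument blocks; null variants independent
    r2 = np.eye(n_var)
    n_blocks = (n_var - config.n_null_variants) // block
    for bidx in range(n_blocks):
        s = bidx * block
        for i in range(block):
            for j in range(block):
                r2[s + i, s + j] = config.rho ** (2 * abs(i - j))
    ld = LdMatrix(vids, r2)

    eaf_arr = panel["eaf"].to_numpy()
    exposures: dict[str, SummaryStatsTable] = {}
    for e, eid in enumerate(exposure_ids):
        se = _se_quantitative(eaf_arr, config.exposure_n)
        beta_hat, pval = _observed(B[:, e], se, rng)
        exposures[eid] = _table_from_panel(
            eid, panel, beta_hat, se, pval, config.exposure_n, "quantitative")

    se_out = _se_binary(eaf_arr, config.outcome_n, config.case_fraction)
    beta_out, pval_out = _observed(outcome_true, se_out, rng)
    out_panel, beta_out = _scramble_orientation(panel, beta_out, rng)
    outcome = _table_from_panel(
        "severe_outcome", out_panel, beta_out, se_out, pval_out,
        config.outcome_n, "binary", case_fraction=config.case_fraction)

    totals = {}
    for e, eid in enumerate(exposure_ids):
        total = theta_direct[e]
        for src, tgt, theta_em in config.chains:
            if src == e:
                total += theta_em * theta_direct[tgt]
        totals[eid] = float(total)
    triangles = []
    chain_records = []
    for src, tgt, theta_em in config.chains:
        src_id, tgt_id = exposure_ids[src], exposure_ids[tgt]
        chain_records.append((src_id, tgt_id, float(theta_em)))
        indirect = theta_em * theta_direct[tgt]
        total = totals[src_id]
        triangles.append({
            "exposure": src_id, "mediator": tgt_id, "outcome": "severe_outcome",
            "theta_EM": float(theta_em),
            "theta_MO": float(theta_direct[tgt]),
            "theta_dir": float(theta_direct[src]),
            "implied_rho": float(indirect / total) if total != 0 else float("nan"),
        })
    truth = TruthSet(
        theta_direct={eid: float(theta_direct[e]) for e, eid in enumerate(exposure_ids)},
        theta_total=totals,
        instruments=instruments,
        chains=chain_records,
        triangles=triangles,
        seed=config.seed,
    )
    return SimulatedStudy(exposures=exposures, outcome=outcome, ld=ld,
                          truth=truth, config=config)


def simulate_mediation_triangle(
    theta_EM: float, theta_MO: float, theta_dir: float, config: SimConfig,
    k_exposure: int | None = None, k_mediator: int | None = None,
) -> SimulatedStudy:
    """Three-trait chain: exposure -> mediator -> binary outcome.

    The mediator inherits ``theta_EM`` times the exposure's instrument
    effects and has its own instruments; the outcome receives ``theta_MO``
    times every mediator effect plus a direct path ``theta_dir`` from the
    exposure.  Implied true proportion mediated:
    ``theta_EM*theta_MO / (theta_EM*theta_MO + theta_dir)``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    k_e = k_exposure or int(rng.integers(config.k_min, config.k_max + 1))
    k_m = k_mediator or int(rng.integers(config.k_min, config.k_max + 1))
    lo, hi = config.instrument_effect_range

    vids, chroms, pos, alleles, eafs = [], [], [], [], []
    a_e = np.zeros(k_e + k_m)   # effect on exposure
    a_m = np.zeros(k_e + k_m)   # own effect on mediator
    instruments = {"exposure": [], "mediator": []}
    for i in range(k_e + k_m):
        vids.append(f"rs{i + 1}")
        chroms.append("1" if i < k_e else "2")
        pos.append(1_000_000 + (i % max(k_e, k_m)) * 20_000_000)
        alleles.append(ALLELE_PAIRS[rng.integers(0, len(ALLELE_PAIRS))])
        eafs.append(float(rng.uniform(*config.eaf_range)))
        effect = float(rng.choice([-1.0, 1.0]) * rng.uniform(lo, hi))
        if i < k_e:
            a_e[i] = effect
            instruments["exposure"].append(vids[-1])
        else:
            a_m[i] = effect
            instruments["mediator"].append(vids[-1])
    panel = _panel_frame(vids, chroms, np.asarray(pos, dtype=np.int64),
                         alleles, np.asarray(eafs))
    eaf_arr = panel["eaf"].to_numpy()

    true_E = a_e
    true_M = theta_EM * a_e + a_m
    true_O = theta_MO * true_M + theta_dir * a_e

    se_e = _se_quantitative(eaf_arr, config.exposure_n)
    se_m = _se_quantitative(eaf_arr, config.mediator_n)
    se_o = _se_binary(eaf_arr, config.outcome_n, config.case_fraction)
    b_e, p_e = _observed(true_E, se_e, rng)
    b_m, p_m = _observed(true_M, se_m, rng)
    b_o, p_o = _observed(true_O, se_o, rng)

    tables = {
        "exposure": _table_from_panel("exposure", panel, b_e, se_e, p_e,
                                      config.exposure_n, "quantitative"),
        "mediator": _table_from_panel("mediator", panel, b_m, se_m, p_m,
                                      config.mediator_n, "quantitative"),
    }
    outcome = _table_from_panel("severe_outcome", panel, b_o, se_o, p_o,
                                config.outcome_n, "binary",
                                case_fraction=config.case_fraction)
    ld = LdMatrix(vids, np.eye(len(vids)))
    indirect = theta_EM * theta_MO
    total = indirect + theta_dir
    truth = TruthSet(
        theta_direct={"exposure": float(theta_dir), "mediator": float(theta_MO)},
        theta_total={"exposure": float(total), "mediator": float(theta_MO)},
        instruments=instruments,
        chains=[("exposure", "mediator", float(theta_EM))],
        triangles=[{
            "exposure": "exposure", "mediator": "mediator",
            "outcome": "severe_outcome",
            "theta_EM": float(theta_EM), "theta_MO": float(theta_MO),
            "theta_dir": float(theta_dir),
            "implied_rho": float(indirect / total) if total != 0 else float("nan"),
        }],
        seed=config.seed,
    )
    return SimulatedStudy(exposures=tables, outcome=outcome, ld=ld,
                          truth=truth, config=config)


def simulate_coloc_region(
    shared: bool, config: SimConfig, causal_beta: float | None = None,
) -> tuple[RegionPair, dict]:
    """Two-trait region under AR(1) LD with one causal variant per trait.

    Marginal effects propagate through LD (z-score model: z has mean
    ``sqrt(n) R b`` and covariance R); standardized betas are z/sqrt(n) with
    se 1/sqrt(n).  ``causal_beta=0`` gives a null region.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    q = config.coloc_n_variants
    n = config.coloc_n
    b = config.coloc_beta if causal_beta is None else causal_beta
    idx1 = config.coloc_causal_index
    idx2 = idx1 if shared else config.coloc_causal_index2
    ii = np.arange(q)
    R = config.rho ** np.abs(ii[:, None] - ii[None, :])
    L = np.linalg.cholesky(R + 1e-10 * np.eye(q))

    def trait_betas(causal_idx: int) -> tuple[np.ndarray, np.ndarray]:
        bvec = np.zeros(q)
        if b != 0.0:
            bvec[causal_idx] = b
        z = np.sqrt(n) * R @ bvec + L @ rng.standard_normal(q)
        return z / np.sqrt(n), np.full(q, 1.0 / np.sqrt(n))

    beta1, se1 = trait_betas(idx1)
    beta2, se2 = trait_betas(idx2)
    vids = [f"rg{i + 1}" for i in range(q)]
    positions = 500_000 + 500 * ii
    region = RegionPair(
        variant_ids=vids, beta1=beta1, se1=se1, beta2=beta2, se2=se2,
        trait_types=("quantitative", "quantitative"),
        lead_variant_id=vids[idx1], positions=positions,
    )
    truth = {
        "shared": bool(shared and b != 0.0),
        "null": b == 0.0,
        "causal_variant_trait1": None if b == 0.0 else vids[idx1],
        "causal_variant_trait2": None if b == 0.0 else vids[idx2],
        "seed": config.seed,
    }
    return region, truth


def write_study(study: SimulatedStudy, outdir) -> dict[str, str]:
    """Write a simulated study as the canonical text artifacts."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for eid, table in study.exposures.items():
        paths[eid] = write_sumstats(table, os.path.join(outdir, f"{eid}.tsv"))
    paths["outcome"] = write_sumstats(study.outcome, os.path.join(outdir, "outcome.tsv"))
    paths["ld"] = study.ld.to_file(os.path.join(outdir, "ld.tsv"))
    paths["truth"] = study.truth.to_json(os.path.join(outdir, "truth.json"))
    cfg_path = os.path.join(outdir, "config.json")
    with open(cfg_path, "w") as fh:
        json.dump(dataclasses.asdict(study.config), fh, indent=2)
    paths["config"] = cfg_path
    return paths
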
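"""LD-structured summary-statistics simulator.

Summary statistics are drawn directly from the multivariate-normal model
for marginal z-scores (the RSS model): with locus LD matrix R, joint
(conditional) causal effects β on the standardised scale, and sample
size n, the marginal effects are b = R·β and the observed z-vector is

    z ~ MVN( b / se, R ),    se = 1/√n  (quantitative)
                             se = 1/√(n·φ(1−φ))  (binary, case fraction φ).

Causal architectures link the exposure (pQTL/eQTL) and outcome loci:
``shared`` (outcome marginal effects are θ times the exposure's — one
shared causal variant), ``distinct`` (outcome has its own causal
variants), ``pleiotropy`` (shared effect plus direct SNP→outcome
effects) and ``reverse`` (the outcome is causal and the exposure
inherits φ_rev times its effects). Sampling noise for the two traits is
independent, as in two-sample MR.

Defaults emulate the study conditions this package is designed around: a
plasma-proteome pQTL panel of ~35.6k individuals, a blood eQTL panel of
~31.9k, and a binary disease outcome with effective sample ~139.9k at
case fraction 0.147; a 200-SNP AR(1) ρ=0.95 locus with MAF ∈ (0.05, 0.5)
and a cis effect of 0.15 SD per allele.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

from .sumstats import (
    GeneRegion,
    LDBlock,
    SumStatRecord,
    read_gene_regions,
    read_ld,
    read_sumstats,
    write_gene_regions,
    write_ld,
    write_sumstats,
)

_MIN_P = 1e-320  # keep p in (0, 1] even for extreme z

_NONPALINDROMIC_PAIRS = (
    ("A", "G"), ("G", "A"), ("A", "C"), ("C", "A"),
    ("T", "G"), ("G", "T"), ("T", "C"), ("C", "T"),
)


@dataclass(frozen=True)
class Scenario:
    """Full parameterisation of one synthetic locus."""

    n_snps: int = 200
    ld_model: str = "ar1"  # ar1 | block
    rho: float = 0.95
    block_sizes: tuple[int, ...] | None = None
    block_r: float = 0.8
    causal_exposure: tuple[tuple[int, float], ...] = ((100, 0.15),)
    theta: float = 0.0
    architecture: str = "shared"  # shared | distinct | pleiotropy | reverse
    outcome_causal: tuple[tuple[int, float], ...] | None = None
    pleiotropy_effects: tuple[tuple[int, float], ...] | None = None
    reverse_phi: float = 0.0
    n_exposure: int = 35_559
    n_outcome: int = 139_900
    outcome_case_fraction: float | None = 0.147  # None -> quantitative outcome
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0
    chrom: str = "1"
    start_pos: int = 1_000_000
    pos_step: int = 5_000
    gene_id: str = "GENE1"
    druggability_tier: str = "1"

    def __post_init__(self):
        for idx, _ in self.causal_exposure:
            if not 0 <= idx < self.n_snps:
                raise ValueError("causal index outside locus")
        for lst in (self.outcome_causal, self.pleiotropy_effects):
            for idx, _ in lst or ():
                if not 0 <= idx < self.n_snps:
                    raise ValueError("causal index outside locus")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("AR(1) rho must lie in (-1, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.architecture not in ("shared", "distinct", "pleiotropy", "reverse"):
            raise ValueError(f"unknown architecture {self.architecture!r}")


@dataclass
class SimulatedLocus:
    ld: LDBlock
    exposure_stats: list[SumStatRecord]
    outcome_stats: list[SumStatRecord]
    truth: dict
    region: GeneRegion


def ar1_matrix(n: int, rho: float) -> np.ndarray:
    idx = np.arange(n)
    return rho ** np.abs(np.subtract.outer(idx, idx))


def block_matrix(sizes: tuple[int, ...], within_r: float) -> np.ndarray:
    n = sum(sizes)
    R = np.eye(n)
    start = 0
    for s in sizes:
        R[start : start + s, start : start + s] = within_r
        start += s
    np.fill_diagonal(R, 1.0)
    return R


def build_ld_matrix(s: Scenario) -> np.ndarray:
    if s.ld_model == "ar1":
        return ar1_matrix(s.n_snps, s.rho)
    if s.ld_model == "block":
        sizes = s.block_sizes or (s.n_snps,)
        if sum(sizes) != s.n_snps:
            raise ValueError("block sizes must sum to n_snps")
        return block_matrix(sizes, s.block_r)
    raise ValueError(f"unknown ld_model {s.ld_model!r}")


@lru_cache(maxsize=32)
def _cached_chol(key: tuple) -> np.ndarray:
    model, n, rho, sizes, within = key
    if model == "ar1":
        R = ar1_matrix(n, rho)
    else:
        R = block_matrix(sizes, within)
    try:
        return np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        # near-singular LD (|rho| -> 1): jitter the diagonal
        import logging

        logging.getLogger(__name__).info("LD matrix near-singular; adding 1e-8 diagonal jitter")
        return np.linalg.cholesky(R + 1e-8 * np.eye(n))


def _chol(s: Scenario) -> np.ndarray:
    return _cached_chol((s.ld_model, s.n_snps, s.rho, s.block_sizes, s.block_r))


def _joint_to_marginal(R: np.ndarray, effects, n_snps: int) -> np.ndarray:
    beta = np.zeros(n_snps)
    for idx, eff in effects or ():
        beta[idx] += eff
    return R @ beta


def marginal_effects(s: Scenario) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic marginal (LD-convolved) effects (b_exposure, b_outcome)."""
    R = build_ld_matrix(s)
    if s.architecture == "reverse":
        gamma = s.outcome_causal if s.outcome_causal is not None else s.causal_exposure
        b_out = _joint_to_marginal(R, gamma, s.n_snps)
        b_exp = s.reverse_phi * b_out
        return b_exp, b_out
    b_exp = _joint_to_marginal(R, s.causal_exposure, s.n_snps)
    if s.architecture == "shared":
        b_out = s.theta * b_exp
    elif s.architecture == "distinct":
        b_out = _joint_to_marginal(R, s.outcome_causal, s.n_snps)
    else:  # pleiotropy
        b_out = s.theta * b_exp + _joint_to_marginal(R, s.pleiotropy_effects, s.n_snps)
    return b_exp, b_out


def outcome_se_unit(s: Scenario) -> float:
    """Per-SNP outcome SE implied by the sample size (and case fraction)."""
    if s.outcome_case_fraction is None:
        return 1.0 / np.sqrt(s.n_outcome)
    v = s.outcome_case_fraction * (1.0 - s.outcome_case_fraction)
    return 1.0 / np.sqrt(s.n_outcome * v)


def _records(
    s: Scenario,
    z: np.ndarray,
    se: float,
    n: int,
    trait_type: str,
    n_cases: int | None,
    snp_ids: list[str],
    positions: np.ndarray,
    eaf: np.ndarray,
    ea: list[str],
    oa: list[str],
) -> list[SumStatRecord]:
    beta = z * se
    pval = np.maximum(2.0 * stats.norm.sf(np.abs(z)), _MIN_P)
    return [
        SumStatRecord(
            snp_id=snp_ids[i],
            chrom=s.chrom,
            pos=int(positions[i]),
            effect_allele=ea[i],
            other_allele=oa[i],
            eaf=float(eaf[i]),
            beta=float(beta[i]),
            se=float(se),
            pval=float(pval[i]),
            n=float(n),
            n_cases=n_cases,
            trait_type=trait_type,
        )
        for i in range(s.n_snps)
    ]


def simulate_locus(s: Scenario, rng: np.random.Generator | None = None) -> SimulatedLocus:
    """Draw one locus of exposure and outcome summary statistics.

    A ``rng`` may be supplied to share a stream across replicates;
    otherwise ``s.seed`` initialises a fresh generator.
    """
    rng = np.random.default_rng(s.seed) if rng is None else rng
    n = s.n_snps
    R = build_ld_matrix(s)
    L = _chol(s)
    b_exp, b_out = marginal_effects(s)

    se_exp = 1.0 / np.sqrt(s.n_exposure)
    se_out = outcome_se_unit(s)
    z_exp = b_exp / se_exp + L @ rng.standard_normal(n)
    z_out = b_out / se_out + L @ rng.standard_normal(n)

    mafs = rng.uniform(s.maf_range[0], s.maf_range[1], size=n)
    flip = rng.random(n) < 0.5
    eaf = np.where(flip, 1.0 - mafs, mafs)
    pair_idx = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=n)
    ea = [_NONPALINDROMIC_PAIRS[i][0] for i in pair_idx]
    oa = [_NONPALINDROMIC_PAIRS[i][1] for i in pair_idx]

    width = len(str(n))
    snp_ids = [f"snp{i:0{width}d}" for i in range(n)]
    positions = s.start_pos + np.arange(n) * s.pos_step

    mid = n // 2
    region = GeneRegion(
        s.gene_id,
        s.chrom,
        int(positions[mid]) - s.pos_step,
        int(positions[mid]) + s.pos_step,
        s.druggability_tier,
    )

    trait_out = "quantitative" if s.outcome_case_fraction is None else "binary"
    n_cases = (
        None
        if s.outcome_case_fraction is None
        else int(round(s.outcome_case_fraction * s.n_outcome))
    )
    exposure = _records(
        s, z_exp, se_exp, s.n_exposure, "quantitative", None, snp_ids, positions, eaf, ea, oa
    )
    outcome = _records(
        s, z_out, se_out, s.n_outcome, trait_out, n_cases, snp_ids, positions, eaf, ea, oa
    )

    def _jsonable(x):
        if isinstance(x, tuple):
            return [_jsonable(v) for v in x]
        return x

    # tuples become lists so that truth round-trips unchanged through JSON
    truth = {k: _jsonable(v) for k, v in dataclasses.asdict(s).items()}
    truth["marginal_b_exposure"] = [float(x) for x in b_exp]
    truth["marginal_b_outcome"] = [float(x) for x in b_out]
    return SimulatedLocus(LDBlock(snp_ids, R), exposure, outcome, truth, region)


def redraw_outcome(
    locus: SimulatedLocus, s: Scenario, rng: np.random.Generator
) -> list[SumStatRecord]:
    """Fresh outcome sampling noise on an existing locus's SNP panel.

    Reuses the locus's SNP ids, positions, alleles and frequencies (a
    phenotype catalogue shares one genotyping panel) while drawing a new
    outcome z-vector under scenario ``s``'s causal architecture.
    """
    _, b_out = marginal_effects(s)
    se_out = outcome_se_unit(s)
    z = b_out / se_out + _chol(s) @ rng.standard_normal(s.n_snps)
    beta = z * se_out
    pval = np.maximum(2.0 * stats.norm.sf(np.abs(z)), _MIN_P)
    return [
        dataclasses.replace(
            rec,
            beta=float(beta[i]),
            se=float(se_out),
            pval=float(pval[i]),
            n=float(s.n_outcome),
        )
        for i, rec in enumerate(locus.outcome_stats)
    ]


def write_fixture(locus: SimulatedLocus, out_dir, force: bool = False) -> None:
    """Write exposure.tsv, outcome.tsv, ld.txt, genes.bed and truth.json."""
    os.makedirs(out_dir, exist_ok=True)
    if os.listdir(out_dir) and not force:
        raise FileExistsError(f"{out_dir} is not empty (use force=True to overwrite)")
    write_sumstats(locus.exposure_stats, os.path.join(out_dir, "exposure.tsv"))
    write_sumstats(locus.outcome_stats, os.path.join(out_dir, "outcome.tsv"))
    write_ld(locus.ld, os.path.join(out_dir, "ld.txt"))
    write_gene_regions([locus.region], os.path.join(out_dir, "genes.bed"))
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(locus.truth, fh, indent=1)


def read_fixture(in_dir) -> SimulatedLocus:
    exposure = read_sumstats(os.path.join(in_dir, "exposure.tsv"))
    outcome = read_sumstats(os.path.join(in_dir, "outcome.tsv"))
    ld = read_ld(os.path.join(in_dir, "ld.txt"))
    region = read_gene_regions(os.path.join(in_dir, "genes.bed"))[0]
    with open(os.path.join(in_dir, "truth.json")) as fh:
        truth = json.load(fh)
    return SimulatedLocus(ld, exposure, outcome, truth, region)
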
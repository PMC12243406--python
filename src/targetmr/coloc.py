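"""Bayesian colocalisation of two association signals at a locus.

Each SNP's evidence of association with a trait is summarised by a
Wakefield approximate Bayes factor computed from the estimated effect,
its standard error and a normal effect-size prior N(0, W):

    log ABF = ½·log(V/(V+W)) + (z²/2)·W/(V+W),   V = se², z = beta/se.

Assuming at most one causal variant per trait, the locus-level evidence
for the five hypotheses — H0 no association, H1/H2 association with one
trait only, H3 two distinct causal variants, H4 one shared causal
variant — reduces to sums of per-SNP (products of) Bayes factors
weighted by the prior probabilities p1, p2, p12 that a SNP is causal for
trait 1, trait 2, or both. All sums run in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .sumstats import SumStatRecord

DEFAULT_PRIORS = (1e-4, 1e-4, 1e-5)  # p1, p2, p12
PRIOR_SD_QUANTITATIVE = 0.15
PRIOR_SD_BINARY = 0.20


@dataclass
class ColocResult:
    gene_id: str
    pp_h0: float
    pp_h1: float
    pp_h2: float
    pp_h3: float
    pp_h4: float
    n_snps: int
    priors: tuple[float, float, float]

    @property
    def pp(self) -> tuple[float, ...]:
        return (self.pp_h0, self.pp_h1, self.pp_h2, self.pp_h3, self.pp_h4)

    def colocalises(self, pph4_threshold: float = 0.7) -> bool:
        return self.pp_h4 > pph4_threshold


def log_abf(record: SumStatRecord, prior_sd: float) -> float:
    """Wakefield log approximate Bayes factor for one SNP."""
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    V = record.se**2
    W = prior_sd**2
    z = record.beta / record.se
    return 0.5 * math.log(V / (V + W)) + (z * z / 2.0) * (W / (V + W))


def _log_abf_vec(records: list[SumStatRecord], prior_sd: float) -> np.ndarray:
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    se = np.array([r.se for r in records])
    beta = np.array([r.beta for r in records])
    V = se**2
    W = prior_sd**2
    return 0.5 * np.log(V / (V + W)) + (beta / se) ** 2 / 2.0 * (W / (V + W))


def default_prior_sd(trait_type: str) -> float:
    return PRIOR_SD_BINARY if trait_type == "binary" else PRIOR_SD_QUANTITATIVE


def posteriors_from_log_abf(
    l1: np.ndarray,
    l2: np.ndarray,
    priors: tuple[float, float, float] = DEFAULT_PRIORS,
    gene_id: str = "",
) -> ColocResult:
    """Five-hypothesis posteriors from per-SNP log-ABF vectors (same SNP order)."""
    l1 = np.asarray(l1, dtype=float)
    l2 = np.asarray(l2, dtype=float)
    if l1.shape != l2.shape:
        raise ValueError("trait log-ABF vectors must cover the same SNP set")
    p1, p2, p12 = priors
    logS1 = float(logsumexp(l1))
    logS2 = float(logsumexp(l2))
    logS12 = float(logsumexp(l1 + l2))
    logL = np.empty(5)
    logL[0] = 0.0
    logL[1] = math.log(p1) + logS1
    logL[2] = math.log(p2) + logS2
    # S1·S2 − S12 = Σ_{i≠j} BF1_i·BF2_j ≥ 0, zero only for a single SNP
    gap = logS12 - (logS1 + logS2)
    if gap >= 0.0:
        logL[3] = -np.inf
    else:
        logL[3] = math.log(p1) + math.log(p2) + logS1 + logS2 + math.log1p(-math.exp(gap))
    logL[4] = math.log(p12) + logS12
    pp = np.exp(logL - logsumexp(logL))
    pp /= pp.sum()
    return ColocResult(gene_id, *[float(x) for x in pp], n_snps=l1.size, priors=(p1, p2, p12))


def coloc_posteriors(
    trait1: list[SumStatRecord],
    trait2: list[SumStatRecord],
    priors: tuple[float, float, float] = DEFAULT_PRIORS,
    prior_sds: tuple[float | None, float | None] = (None, None),
    gene_id: str = "",
) -> ColocResult:
    """Colocalise two harmonised record lists covering the same SNPs, in order.

    ``prior_sds`` are the per-trait effect priors; ``None`` selects 0.2
    for binary and 0.15 for quantitative traits.
    """
    if len(trait1) != len(trait2) or any(
        a.snp_id != b.snp_id for a, b in zip(trait1, trait2)
    ):
        raise ValueError("trait SNP sets must be identical and aligned")
    if len(trait1) < 2:
        import logging

        logging.getLogger(__name__).warning(
            "coloc with < 2 SNPs: H3 is degenerate and posteriors uninformative"
        )
    sd1 = prior_sds[0] if prior_sds[0] is not None else default_prior_sd(trait1[0].trait_type)
    sd2 = prior_sds[1] if prior_sds[1] is not None else default_prior_sd(trait2[0].trait_type)
    return posteriors_from_log_abf(
        _log_abf_vec(trait1, sd1), _log_abf_vec(trait2, sd2), priors, gene_id
    )
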
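"""Summary-data-based MR (SMR) and the HEIDI linkage test.

SMR tests whether gene expression mediates a GWAS signal using the top
cis-eQTL as the instrument: b_smr = b_gwas / b_eqtl, with the test
statistic

    T_smr = z_gwas² · z_eqtl² / (z_gwas² + z_eqtl²)

referred to chi-square(1). T_smr is bounded by the smaller of the two
chi-squares, so a gene is only significant when both the eQTL and the
GWAS signal are strong.

A significant SMR hit can still be driven by two distinct causal
variants in LD rather than one shared variant. HEIDI (heterogeneity in
dependent instruments) tests this: under a single shared causal variant
the ratio b_gwas/b_eqtl is the same at every SNP in LD with it, so the
differences d_i = b_smr(i) − b_smr(top) across nearby SNPs should be
jointly zero. The d-vector's covariance follows from the LD matrix and
per-SNP standard errors by the delta method; the sum of squared
standardised differences is calibrated against its correlated-null
distribution by Satterthwaite moment matching on the eigenvalues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .sumstats import LDBlock, SumStatRecord

log = logging.getLogger(__name__)

#: eQTL eligibility significance for HEIDI SNPs: chi-square(1) = 10
HEIDI_ELIGIBILITY_P = 1.57e-3


@dataclass
class SMRResult:
    gene_id: str
    top_snp: str
    b_smr: float
    se_smr: float
    p_smr: float
    or_smr: float
    ci_low: float
    ci_high: float
    p_heidi: float | None
    n_heidi_snps: int
    flag: str  # pass | heidi_pleiotropy | insufficient_snps


def smr_test(eqtl: SumStatRecord, gwas: SumStatRecord) -> tuple[float, float, float]:
    """Return (b_smr, se_smr, p_smr) for one harmonised eQTL/GWAS pair."""
    if eqtl.beta == 0.0:
        raise ValueError("smr_test undefined for zero eQTL beta")
    z_e, z_g = eqtl.z, gwas.z
    b = gwas.beta / eqtl.beta
    t = (z_g**2 * z_e**2) / (z_g**2 + z_e**2)
    p = float(stats.chi2.sf(t, df=1))
    se = abs(b) / np.sqrt(t) if t > 0 else float("inf")
    return b, se, p


def heidi_test(
    eqtl_block: list[SumStatRecord],
    gwas_block: list[SumStatRecord],
    ld: LDBlock,
    top_snp: str,
    r2_window: tuple[float, float] = (0.05, 0.9),
    max_snps: int = 20,
    eligibility_p: float = HEIDI_ELIGIBILITY_P,
) -> tuple[float | None, int]:
    """HEIDI test around ``top_snp``; returns (p_heidi, n_snps_used).

    Eligible SNPs have r² with the top SNP strictly inside ``r2_window``
    and eQTL p below ``eligibility_p``; the ``max_snps`` most significant
    eQTL SNPs are used. Fewer than 3 eligible SNPs → (None, n).
    """
    eqtl_by_id = {r.snp_id: r for r in eqtl_block}
    gwas_by_id = {r.snp_id: r for r in gwas_block}
    if top_snp not in eqtl_by_id or top_snp not in gwas_by_id or top_snp not in ld:
        raise ValueError(f"top SNP {top_snp} missing from a source")
    lo, hi = r2_window
    eligible = [
        s
        for s in eqtl_by_id
        if s != top_snp
        and s in gwas_by_id
        and s in ld
        and lo < ld.r2(s, top_snp) < hi
        and eqtl_by_id[s].pval < eligibility_p
    ]
    eligible.sort(key=lambda s: (eqtl_by_id[s].pval, s))
    eligible = eligible[:max_snps]
    m = len(eligible)
    if m < 3:
        return None, m

    snps = eligible + [top_snp]
    bE = np.array([eqtl_by_id[s].beta for s in snps])
    sE = np.array([eqtl_by_id[s].se for s in snps])
    bG = np.array([gwas_by_id[s].beta for s in snps])
    sG = np.array([gwas_by_id[s].se for s in snps])
    R = ld.submatrix(snps)
    t = m  # index of the top SNP in the stacked vectors

    d = bG[:m] / bE[:m] - bG[t] / bE[t]

    # delta-method Jacobians of d wrt (bG, bE); GWAS and eQTL samples independent
    A = np.zeros((m, m + 1))
    B = np.zeros((m, m + 1))
    rows = np.arange(m)
    A[rows, rows] = 1.0 / bE[:m]
    A[:, t] = -1.0 / bE[t]
    B[rows, rows] = -bG[:m] / bE[:m] ** 2
    B[:, t] = bG[t] / bE[t] ** 2
    covG = R * np.outer(sG, sG)
    covE = R * np.outer(sE, sE)
    V = A @ covG @ A.T + B @ covE @ B.T

    sd = np.sqrt(np.diag(V))
    zd = d / sd
    T = float(np.sum(zd**2))
    C = V / np.outer(sd, sd)
    lam = np.linalg.eigvalsh(C)
    lam = lam[lam > 1e-12]
    s1, s2 = float(np.sum(lam)), float(np.sum(lam**2))
    c = s2 / s1  # Satterthwaite scale
    f = s1**2 / s2  # effective degrees of freedom
    p = float(stats.chi2.sf(T / c, df=f))
    return p, m


def smr_gene_scan(
    genes,
    eqtl_source,
    gwas_source,
    ld_source,
    window_kb: int = 1000,
    p_threshold: float = 5e-8,
    maf_min: float = 0.01,
    af_diff_threshold: float = 0.2,
    heidi_call_threshold: float = 0.01,
    r2_window: tuple[float, float] = (0.05, 0.9),
    max_snps: int = 20,
    eligibility_p: float = HEIDI_ELIGIBILITY_P,
) -> list[SMRResult]:
    """Run SMR + HEIDI for each gene.

    ``eqtl_source``, ``gwas_source`` and ``ld_source`` are callables
    mapping a GeneRegion to the locus records / LDBlock. Per gene: drop
    SNPs with MAF ≤ ``maf_min`` or eQTL/GWAS allele-frequency difference
    above ``af_diff_threshold`` (after orientation), take the most
    significant cis-eQTL with p < ``p_threshold`` within ±``window_kb``
    as the instrument, run ``smr_test`` and ``heidi_test``. Genes with
    no qualifying eQTL are omitted with a logged reason.
    """
    from .instruments import select_cis
    from .sumstats import harmonise_many

    results: list[SMRResult] = []
    for region in genes:
        eqtl = eqtl_source(region)
        gwas = gwas_source(region)
        ld = ld_source(region)
        pairs = harmonise_many(eqtl, gwas, af_diff_threshold=af_diff_threshold)
        pairs = [p for p in pairs if p.retained and p.exposure.maf > maf_min]
        if not pairs:
            log.info("%s: no harmonised SNPs surviving MAF/AF filters", region.gene_id)
            continue
        eqtl_block = [p.exposure for p in pairs]
        gwas_block = [p.outcome for p in pairs]
        candidates = select_cis(eqtl_block, region, window_kb, p_threshold)
        if not candidates:
            log.info("%s: no cis-eQTL at p < %g, gene omitted", region.gene_id, p_threshold)
            continue
        top = min(candidates, key=lambda r: (r.pval, r.snp_id))
        gwas_top = next(g for g in gwas_block if g.snp_id == top.snp_id)
        b, se, p_smr = smr_test(top, gwas_top)
        p_heidi, n_used = heidi_test(
            eqtl_block, gwas_block, ld, top.snp_id, r2_window, max_snps, eligibility_p
        )
        if p_heidi is None:
            flag = "insufficient_snps"
        elif p_heidi < heidi_call_threshold:
            flag = "heidi_pleiotropy"
        else:
            flag = "pass"
        results.append(
            SMRResult(
                gene_id=region.gene_id,
                top_snp=top.snp_id,
                b_smr=b,
                se_smr=se,
                p_smr=p_smr,
                or_smr=float(np.exp(b)),
                ci_low=float(np.exp(b - 1.96 * se)),
                ci_high=float(np.exp(b + 1.96 * se)),
                p_heidi=p_heidi,
                n_heidi_snps=n_used,
                flag=flag,
            )
        )
    return results
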
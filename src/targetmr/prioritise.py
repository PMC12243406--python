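"""Evidence collation: tier classification, endophenotype MR, MR-PheWAS.

A drug-target candidate must first be causal at the protein level
(FDR-significant proteome-wide MR). On top of that, two further lines of
evidence are assessed: transcriptome-wide SMR with a direction
consistent with the protein effect (and no HEIDI linkage call), and
colocalisation of the protein and disease signals (PPH4 above
threshold). Tier 1 targets carry both extra lines, tier 2 exactly one,
tier 3 neither; a transcript effect pointing the opposite way from the
protein effect excludes the target outright.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .coloc import ColocResult
from .mr import MRResult, bh_fdr
from .pipeline import LocusData, PipelineConfig, run_gene_mr
from .smr import SMRResult
from .sumstats import SumStatRecord

log = logging.getLogger(__name__)


@dataclass
class EvidenceRow:
    """Per-gene collation of MR, SMR/HEIDI and coloc results."""

    gene_id: str
    druggability_tier: str
    mr: MRResult
    smr: SMRResult | None = None
    coloc: ColocResult | None = None

    @property
    def direction_consistent(self) -> bool | None:
        """Sign agreement of the transcript and protein effects; None without SMR."""
        if self.smr is None:
            return None
        return math.copysign(1, self.smr.b_smr) == math.copysign(1, self.mr.beta_mr)


@dataclass
class TierCall:
    gene_id: str
    tier: str  # "1" | "2" | "3" | "excluded" | "not_significant"
    reasons: list[str] = field(default_factory=list)


def classify_tier(
    row: EvidenceRow,
    mr_alpha_fdr: float = 0.05,
    smr_alpha: float = 0.05,
    pph4_threshold: float = 0.7,
    heidi_call: float = 0.01,
    heidi_gates_smr: bool = True,
    missing_heidi_passes: bool = True,
) -> TierCall:
    """Assign the three-tier evidence class for one gene.

    Criterion A (protein MR) is the entry gate; B is a consistent,
    HEIDI-clean transcript-level SMR signal; C is colocalisation.
    Tier 1 = B and C, tier 2 = exactly one, tier 3 = neither. An SMR
    signal significant in the opposite direction excludes the gene.
    """
    reasons: list[str] = []
    if row.mr.p_fdr is None:
        raise ValueError(f"{row.gene_id}: MR p_fdr not computed")
    if row.mr.p_fdr >= mr_alpha_fdr:
        return TierCall(row.gene_id, "not_significant", [f"MR p_fdr={row.mr.p_fdr:.3g}"])

    smr_significant = row.smr is not None and row.smr.p_smr < smr_alpha
    if smr_significant and row.direction_consistent is False:
        return TierCall(
            row.gene_id,
            "excluded",
            ["transcript and protein effects have inconsistent directions"],
        )

    if row.smr is None:
        b = False
        reasons.append("no available gene expression data")
    elif not smr_significant:
        b = False
        reasons.append(f"SMR p={row.smr.p_smr:.3g} not significant")
    else:
        b = True
        if heidi_gates_smr:
            if row.smr.p_heidi is None:
                if not missing_heidi_passes:
                    b = False
                    reasons.append("HEIDI not evaluable (insufficient SNPs)")
            elif row.smr.p_heidi < heidi_call:
                b = False
                reasons.append(f"HEIDI p={row.smr.p_heidi:.3g} indicates linkage")

    if row.coloc is None:
        c = False
        reasons.append("no colocalisation evidence")
    else:
        c = row.coloc.pp_h4 > pph4_threshold
        if not c:
            reasons.append(f"PPH4={row.coloc.pp_h4:.3f} below threshold")

    tier = "1" if (b and c) else ("2" if (b or c) else "3")
    return TierCall(row.gene_id, tier, reasons)


def classify_tiers(rows: list[EvidenceRow], config: PipelineConfig | None = None) -> list[TierCall]:
    cfg = config or PipelineConfig()
    return [
        classify_tier(
            row,
            mr_alpha_fdr=cfg.mr_alpha_fdr,
            smr_alpha=cfg.smr_alpha,
            pph4_threshold=cfg.pph4_threshold,
            heidi_call=cfg.heidi_call,
        )
        for row in rows
    ]


def endophenotype_mr(
    targets: list[LocusData],
    outcomes: dict[str, dict[str, list[SumStatRecord]]],
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """MR of each target protein against quantitative endophenotypes.

    ``outcomes`` maps outcome name -> gene_id -> outcome records for that
    gene's locus. Effects are reported as betas with 95% CIs (the
    outcomes are continuous, so no OR scale). Targets with no surviving
    instruments yield a flagged row rather than disappearing.
    """
    cfg = config or PipelineConfig()
    rows = []
    for outcome_name, per_gene in outcomes.items():
        for locus in targets:
            inst, res = run_gene_mr(locus, per_gene[locus.gene_id], cfg)
            if res is None:
                rows.append(
                    {
                        "gene_id": locus.gene_id,
                        "outcome": outcome_name,
                        "method": None,
                        "n_snps": 0,
                        "beta": None,
                        "se": None,
                        "ci_low": None,
                        "ci_high": None,
                        "pval": None,
                        "significant": False,
                        "flag": "no_surviving_instruments",
                    }
                )
                continue
            rows.append(
                {
                    "gene_id": locus.gene_id,
                    "outcome": outcome_name,
                    "method": res.method,
                    "n_snps": res.n_snps,
                    "beta": res.beta_mr,
                    "se": res.se_mr,
                    "ci_low": res.beta_mr - 1.96 * res.se_mr,
                    "ci_high": res.beta_mr + 1.96 * res.se_mr,
                    "pval": res.pval,
                    "significant": res.pval < cfg.endo_alpha,
                    "flag": "",
                }
            )
    return pd.DataFrame(rows)


@dataclass
class PhenotypeOutcome:
    """One catalogue entry for a PheWAS scan (records at the locus SNPs)."""

    phenotype_id: str
    category: str
    n_cases: int
    records: list[SumStatRecord]


@dataclass
class PheWASRow:
    phenotype_id: str
    category: str
    n_cases: int
    mr: MRResult | None
    p_fdr: float | None
    flag: str = ""


def phewas_scan(
    target: LocusData,
    outcome_catalogue: list[PhenotypeOutcome],
    case_min: int = 500,
    config: PipelineConfig | None = None,
) -> list[PheWASRow]:
    """MR of one target against a phenotype catalogue with BH FDR control.

    Phenotypes with ``n_cases`` not strictly greater than ``case_min``
    are excluded before scanning; ``p_fdr`` is adjusted across the
    scanned set only. Per-row raw p-values do not depend on the rest of
    the catalogue.
    """
    cfg = config or PipelineConfig()
    scanned = [o for o in outcome_catalogue if o.n_cases > case_min]
    rows: list[PheWASRow] = []
    for o in scanned:
        _, res = run_gene_mr(target, o.records, cfg)
        flag = "" if res is not None else "no_surviving_instruments"
        rows.append(PheWASRow(o.phenotype_id, o.category, o.n_cases, res, None, flag))
    with_res = [r for r in rows if r.mr is not None]
    if with_res:
        q = bh_fdr([r.mr.pval for r in with_res])
        for r, qi in zip(with_res, q):
            r.p_fdr = float(qi)
    return rows


def direction_concordance(discovery: pd.DataFrame, replication: pd.DataFrame) -> dict:
    """Direction-concordance report between two MR result tables.

    Both tables need ``gene_id`` and ``beta`` columns. Reports the
    fraction of shared genes whose effect directions agree — a
    qualitative replication check, not a formal meta-analysis.
    """
    merged = discovery.merge(replication, on="gene_id", suffixes=("_disc", "_repl"))
    if merged.empty:
        return {"n_shared": 0, "n_concordant": 0, "concordance": float("nan")}
    agree = (merged["beta_disc"] * merged["beta_repl"]) > 0
    return {
        "n_shared": int(len(merged)),
        "n_concordant": int(agree.sum()),
        "concordance": float(agree.mean()),
    }
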
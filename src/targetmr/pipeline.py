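"""Pipeline orchestration: configuration, per-gene MR runs, run manifests."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

from . import __version__
from .instruments import InstrumentSet, select_instruments
from .mr import MRResult, attach_fdr, fit_mr
from .sumstats import GeneRegion, LDBlock, SumStatRecord


@dataclass
class PipelineConfig:
    """Thresholds and switches; defaults follow the standard cis-MR recipe."""

    window_kb: int = 1000
    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_kb: int = 10_000
    p_outcome_threshold: float | None = 5e-5  # None disables the filter
    f_min: float = 10.0
    steiger: bool = True
    steiger_formula: str = "z2"  # z2 | af
    drop_palindromic: bool = True
    af_diff_threshold: float | None = None  # MR stage; SMR stage uses smr_af_diff
    smr_af_diff: float = 0.2
    maf_min: float = 0.01
    smr_alpha: float = 0.05
    heidi_eligibility_p: float = 1.57e-3
    heidi_call: float = 0.01
    heidi_r2_window: tuple[float, float] = (0.05, 0.9)
    heidi_max_snps: int = 20
    coloc_priors: tuple[float, float, float] = (1e-4, 1e-4, 1e-5)
    coloc_prior_sd_quantitative: float = 0.15
    coloc_prior_sd_binary: float = 0.20
    pph4_threshold: float = 0.7
    mr_alpha_fdr: float = 0.05
    endo_alpha: float = 0.05
    phewas_case_min: int = 500
    phewas_alpha_fdr: float = 0.05


@dataclass
class LocusData:
    """One gene's locus: region, LD reference and exposure summary stats."""

    gene_id: str
    region: GeneRegion
    ld: LDBlock
    exposure: list[SumStatRecord]


def run_gene_mr(
    locus: LocusData,
    outcome: list[SumStatRecord],
    config: PipelineConfig | None = None,
) -> tuple[InstrumentSet, MRResult | None]:
    """Instrument selection followed by Wald-ratio/IVW MR for one gene.

    Returns the instrument set (with its filter log) and the MR result,
    or ``None`` when no instrument survives.
    """
    cfg = config or PipelineConfig()
    inst = select_instruments(
        locus.gene_id,
        locus.exposure,
        outcome,
        locus.region,
        locus.ld,
        window_kb=cfg.window_kb,
        p_threshold=cfg.p_threshold,
        clump_r2=cfg.clump_r2,
        clump_kb=cfg.clump_kb,
        p_outcome_threshold=cfg.p_outcome_threshold,
        f_min=cfg.f_min,
        steiger=cfg.steiger,
        steiger_formula=cfg.steiger_formula,
        af_diff_threshold=cfg.af_diff_threshold,
        drop_palindromic=cfg.drop_palindromic,
    )
    if not inst.pairs:
        return inst, None
    return inst, fit_mr(inst.pairs, locus.gene_id)


def run_mr_scan(
    loci: list[LocusData],
    outcomes: dict[str, list[SumStatRecord]],
    config: PipelineConfig | None = None,
) -> tuple[list[MRResult], dict[str, InstrumentSet]]:
    """MR across genes against one outcome keyed by gene_id, with BH FDR."""
    results, instruments = [], {}
    for locus in loci:
        inst, res = run_gene_mr(locus, outcomes[locus.gene_id], config)
        instruments[locus.gene_id] = inst
        if res is not None:
            results.append(res)
    attach_fdr(results)
    return results, instruments


def run_manifest(config: PipelineConfig, instruments: dict[str, InstrumentSet], seed=None) -> dict:
    """JSON-serialisable record of the run: version, thresholds, filter counts."""
    counts: dict[str, int] = {}
    for inst in instruments.values():
        for _, reason in inst.filter_log:
            counts[reason] = counts.get(reason, 0) + 1
    return {
        "package": "targetmr",
        "version": __version__,
        "seed": seed,
        "config": dataclasses.asdict(config),
        "filter_counts": counts,
        "n_genes": len(instruments),
        "n_instruments": {g: len(i) for g, i in instruments.items()},
    }


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)
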
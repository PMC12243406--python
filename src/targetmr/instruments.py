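"""Cis instrumental-variable selection and filtering.

The instrument-selection pass mirrors the standard cis-MR recipe:
significant SNPs in a window around the gene, LD clumping to
approximately independent index SNPs, harmonisation against the outcome,
Steiger directionality filtering, exclusion of SNPs directly associated
with the outcome, and a per-SNP F-statistic strength floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .sumstats import GeneRegion, HarmonisedPair, LDBlock, SumStatRecord, harmonise

log = logging.getLogger(__name__)


@dataclass
class InstrumentSet:
    """Filtered cis instruments for one gene, with a removal audit trail."""

    gene_id: str
    pairs: list[HarmonisedPair]
    filter_log: list[tuple[str, str]]  # (snp_id, filter_name), in removal order
    window_kb: int
    p_threshold: float

    @property
    def snp_ids(self) -> list[str]:
        return [p.snp_id for p in self.pairs]

    def __len__(self) -> int:
        return len(self.pairs)


def select_cis(
    records: list[SumStatRecord],
    region: GeneRegion,
    window_kb: int = 1000,
    p_threshold: float = 5e-8,
) -> list[SumStatRecord]:
    """SNPs within ``region ± window_kb`` (inclusive) with p strictly below threshold."""
    lo = region.start - window_kb * 1000
    hi = region.end + window_kb * 1000
    return [
        r
        for r in records
        if r.chrom == region.chrom and lo <= r.pos <= hi and r.pval < p_threshold
    ]


def clump(
    records: list[SumStatRecord],
    ld: LDBlock,
    clump_r2: float = 0.001,
    clump_kb: int = 10_000,
    removed: list[str] | None = None,
) -> list[SumStatRecord]:
    """Greedy LD clumping: most significant unclaimed SNP becomes an index,
    claiming every unclaimed SNP within ``clump_kb`` at r² ≥ ``clump_r2``.

    Ties in p are broken lexicographically by snp_id so the result does not
    depend on input order. Index SNPs are returned in genomic order. SNPs
    absent from the LD reference are dropped with a warning (and recorded in
    ``removed`` as well, if supplied).
    """
    present = []
    for r in records:
        if r.snp_id in ld:
            present.append(r)
        else:
            log.warning("clump: %s absent from LD reference, dropped", r.snp_id)
            if removed is not None:
                removed.append(r.snp_id)
    order = sorted(present, key=lambda r: (r.pval, r.snp_id))
    unclaimed = {r.snp_id for r in present}
    indices: list[SumStatRecord] = []
    for idx in order:
        if idx.snp_id not in unclaimed:
            continue
        indices.append(idx)
        unclaimed.discard(idx.snp_id)
        for other in present:
            if (
                other.snp_id in unclaimed
                and abs(other.pos - idx.pos) <= clump_kb * 1000
                and ld.r2(idx.snp_id, other.snp_id) >= clump_r2
            ):
                unclaimed.discard(other.snp_id)
                if removed is not None:
                    removed.append(other.snp_id)
    return sorted(indices, key=lambda r: (r.pos, r.snp_id))


def exclude_outcome_associated(
    pairs: list[HarmonisedPair], p_outcome_threshold: float = 5e-5
) -> list[HarmonisedPair]:
    """Drop instruments directly associated with the outcome (p < threshold)."""
    return [p for p in pairs if p.outcome.pval >= p_outcome_threshold]


def _steiger_r2(z: float, n: float) -> float:
    # variance-explained proxy from the z statistic
    return z * z / (z * z + n - 2.0)


def _af_r2(rec: SumStatRecord) -> float:
    return 2.0 * rec.maf * (1.0 - rec.maf) * rec.beta**2


def steiger_filter(
    pairs: list[HarmonisedPair],
    formula: str = "z2",
    dropped: list[str] | None = None,
) -> list[HarmonisedPair]:
    """Retain instruments explaining at least as much variance in the
    exposure as in the outcome (reverse-causation guard); ties retained.

    ``formula='z2'`` uses r² = z²/(z² + n − 2); ``formula='af'`` uses the
    allele-frequency proxy 2·MAF·(1−MAF)·β².
    """
    kept = []
    for p in pairs:
        if formula == "af":
            r2_exp, r2_out = _af_r2(p.exposure), _af_r2(p.outcome)
        else:
            if p.exposure.n <= 2 or p.outcome.n <= 2:
                log.warning("steiger: %s dropped (sample size ≤ 2)", p.snp_id)
                if dropped is not None:
                    dropped.append(p.snp_id)
                continue
            r2_exp = _steiger_r2(p.exposure.z, p.exposure.n)
            r2_out = _steiger_r2(p.outcome.z, p.outcome.n)
        if r2_exp >= r2_out:
            kept.append(p)
        elif dropped is not None:
            dropped.append(p.snp_id)
    return kept


def f_statistic(pair: HarmonisedPair) -> float:
    """Single-SNP instrument strength F = (β/SE)² on the exposure."""
    return pair.exposure.z ** 2


def f_statistic_filter(pairs: list[HarmonisedPair], f_min: float = 10.0) -> list[HarmonisedPair]:
    return [p for p in pairs if f_statistic(p) >= f_min]


def select_instruments(
    gene_id: str,
    exposure: list[SumStatRecord],
    outcome: list[SumStatRecord],
    region: GeneRegion,
    ld: LDBlock,
    window_kb: int = 1000,
    p_threshold: float = 5e-8,
    clump_r2: float = 0.001,
    clump_kb: int = 10_000,
    p_outcome_threshold: float | None = 5e-5,
    f_min: float = 10.0,
    steiger: bool = True,
    steiger_formula: str = "z2",
    af_diff_threshold: float | None = None,
    drop_palindromic: bool = True,
) -> InstrumentSet:
    """Full cis-instrument selection pass for one gene.

    Filter order: cis window + significance → LD clump → harmonise →
    Steiger → outcome-association exclusion → F-statistic. Every SNP
    removed after the cis/significance step appears in ``filter_log``,
    so ``len(cis set) == len(pairs) + len(filter_log)``.
    """
    flog: list[tuple[str, str]] = []
    cis = select_cis(exposure, region, window_kb, p_threshold)

    removed: list[str] = []
    clumped = clump(cis, ld, clump_r2, clump_kb, removed=removed)
    for snp in removed:
        flog.append((snp, "missing_ld" if snp not in ld else "clump"))

    outcome_by_id = {r.snp_id: r for r in outcome}
    pairs: list[HarmonisedPair] = []
    for rec in clumped:
        if rec.snp_id not in outcome_by_id:
            flog.append((rec.snp_id, "no_outcome_record"))
            continue
        pair = harmonise(rec, outcome_by_id[rec.snp_id], af_diff_threshold, drop_palindromic)
        if pair.retained:
            pairs.append(pair)
        else:
            flog.append((pair.snp_id, pair.status))

    if steiger:
        dropped: list[str] = []
        pairs = steiger_filter(pairs, formula=steiger_formula, dropped=dropped)
        flog.extend((s, "steiger") for s in dropped)

    if p_outcome_threshold is not None:
        kept = exclude_outcome_associated(pairs, p_outcome_threshold)
        kept_ids = {p.snp_id for p in kept}
        flog.extend((p.snp_id, "outcome_associated") for p in pairs if p.snp_id not in kept_ids)
        pairs = kept

    kept = f_statistic_filter(pairs, f_min)
    kept_ids = {p.snp_id for p in kept}
    flog.extend((p.snp_id, "weak_instrument") for p in pairs if p.snp_id not in kept_ids)

    assert len(cis) == len(kept) + len(flog), "filter log does not account for all removals"
    return InstrumentSet(gene_id, kept, flog, window_kb, p_threshold)
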
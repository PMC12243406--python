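"""Summary-statistic containers, file I/O and allele harmonisation.

GWAS/QTL summary statistics arrive as tab-delimited tables of per-SNP
marginal associations (effect-allele oriented betas). This module
validates them into :class:`SumStatRecord` objects, reads the auxiliary
inputs the pipeline needs (gene regions with druggability tiers, LD
correlation matrices), and harmonises exposure/outcome record pairs onto
a shared effect-allele orientation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

VALID_ALLELES = frozenset({"A", "C", "G", "T"})
_PALINDROMIC = (frozenset({"A", "T"}), frozenset({"C", "G"}))

#: canonical field name -> default column name in files
DEFAULT_DIALECT = {
    "snp": "snp",
    "chr": "chr",
    "pos": "pos",
    "ea": "ea",
    "oa": "oa",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "n",
    "n_cases": "n_cases",
}

REQUIRED_FIELDS = ("snp", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "pval", "n")


@dataclass(frozen=True)
class SumStatRecord:
    """One SNP's marginal association for one trait.

    ``beta`` is the effect per copy of ``effect_allele``: a log odds
    ratio for binary traits, SD units for quantitative traits.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: float
    n_cases: int | None = None
    trait_type: str = "quantitative"

    @property
    def z(self) -> float:
        return self.beta / self.se

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)

    def validate(self) -> None:
        """Raise ``ValueError`` on any violated field invariant."""
        if self.se <= 0 or not math.isfinite(self.se):
            raise ValueError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"{self.snp_id}: eaf outside [0, 1]: {self.eaf}")
        if not (0.0 < self.pval <= 1.0):
            raise ValueError(f"{self.snp_id}: pval outside (0, 1]: {self.pval}")
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise ValueError(
                f"{self.snp_id}: alleles must be single-base A/C/G/T "
                f"({self.effect_allele}/{self.other_allele})"
            )
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele identical")
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: pos must be a 1-based coordinate")
        if self.trait_type not in ("binary", "quantitative"):
            raise ValueError(f"{self.snp_id}: unknown trait_type {self.trait_type!r}")
        if not math.isfinite(self.beta):
            raise ValueError(f"{self.snp_id}: non-finite beta")
        if not _pval_consistent(self.beta, self.se, self.pval):
            raise ValueError(
                f"{self.snp_id}: pval {self.pval} inconsistent with z={self.z:.3f}"
            )


def _pval_consistent(beta: float, se: float, pval: float, rtol: float = 0.10) -> bool:
    # normal-approximation cross-check; skipped where the tail underflows
    expected = 2.0 * stats.norm.sf(abs(beta / se))
    if expected < 5e-300 or pval < 5e-300:
        return True
    return abs(pval - expected) <= rtol * max(pval, expected)


@dataclass(frozen=True)
class GeneRegion:
    """A gene footprint (1-based inclusive) with its druggability tier."""

    gene_id: str
    chrom: str
    start: int
    end: int
    druggability_tier: str = "none"

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.druggability_tier not in ("1", "2", "3A", "3B", "none"):
            raise ValueError(f"{self.gene_id}: bad druggability tier {self.druggability_tier!r}")


class LDBlock:
    """SNP-indexed square correlation matrix for one locus."""

    def __init__(self, snp_ids: list[str], R: np.ndarray):
        R = np.asarray(R, dtype=float)
        if R.ndim != 2 or R.shape[0] != R.shape[1] or R.shape[0] != len(snp_ids):
            raise ValueError("R must be square with one row per snp_id")
        if not np.allclose(np.diag(R), 1.0, atol=1e-6):
            raise ValueError("LD matrix diagonal must be 1")
        if not np.allclose(R, R.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        if np.any(np.abs(R) > 1.0 + 1e-8):
            raise ValueError("LD correlations must lie in [-1, 1]")
        self.snp_ids = list(snp_ids)
        self.R = R
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def __len__(self) -> int:
        return len(self.snp_ids)

    def index(self, snp_id: str) -> int:
        return self._index[snp_id]

    def r(self, a: str, b: str) -> float:
        return float(self.R[self._index[a], self._index[b]])

    def r2(self, a: str, b: str) -> float:
        return self.r(a, b) ** 2

    def submatrix(self, snp_ids: list[str]) -> np.ndarray:
        idx = [self._index[s] for s in snp_ids]
        return self.R[np.ix_(idx, idx)]


@dataclass(frozen=True)
class HarmonisedPair:
    """Exposure/outcome records re-oriented to a common effect allele."""

    snp_id: str
    exposure: SumStatRecord
    outcome: SumStatRecord
    status: str  # kept | flipped | dropped_palindromic | dropped_allele_mismatch | dropped_af_diff

    @property
    def retained(self) -> bool:
        return self.status in ("kept", "flipped")


def harmonise(
    exposure: SumStatRecord,
    outcome: SumStatRecord,
    af_diff_threshold: float | None = None,
    drop_palindromic: bool = True,
) -> HarmonisedPair:
    """Orient ``outcome`` onto ``exposure``'s effect allele.

    A reversed allele pair flips the outcome beta's sign and replaces its
    eaf by 1-eaf. Palindromic (A/T, C/G) sites are dropped by default
    because strand cannot be resolved from two summary files alone. If
    ``af_diff_threshold`` is given, pairs whose oriented allele
    frequencies differ by more than it are dropped.
    """
    if exposure.snp_id != outcome.snp_id:
        raise ValueError("harmonise requires records for the same SNP")
    ea, oa = exposure.effect_allele, exposure.other_allele
    if {ea, oa} != {outcome.effect_allele, outcome.other_allele}:
        return HarmonisedPair(exposure.snp_id, exposure, outcome, "dropped_allele_mismatch")
    if drop_palindromic and frozenset({ea, oa}) in _PALINDROMIC:
        return HarmonisedPair(exposure.snp_id, exposure, outcome, "dropped_palindromic")
    status = "kept"
    if outcome.effect_allele != ea:
        outcome = replace(
            outcome,
            effect_allele=ea,
            other_allele=oa,
            beta=-outcome.beta,
            eaf=1.0 - outcome.eaf,
        )
        status = "flipped"
    if af_diff_threshold is not None and abs(exposure.eaf - outcome.eaf) > af_diff_threshold:
        return HarmonisedPair(exposure.snp_id, exposure, outcome, "dropped_af_diff")
    return HarmonisedPair(exposure.snp_id, exposure, outcome, status)


def harmonise_many(
    exposures: list[SumStatRecord],
    outcomes: list[SumStatRecord],
    af_diff_threshold: float | None = None,
    drop_palindromic: bool = True,
) -> list[HarmonisedPair]:
    """Harmonise by snp_id; exposure SNPs absent from the outcome are skipped."""
    by_id = {r.snp_id: r for r in outcomes}
    out = []
    for exp in exposures:
        if exp.snp_id in by_id:
            out.append(harmonise(exp, by_id[exp.snp_id], af_diff_threshold, drop_palindromic))
    return out


# ---------------------------------------------------------------------------
# file I/O


def _fmt(x: float) -> str:
    return "%.17g" % float(x)


def read_sumstats(
    path,
    dialect: dict[str, str] | None = None,
    trait_type: str = "quantitative",
) -> list[SumStatRecord]:
    """Read a tab-delimited summary-statistics file.

    ``dialect`` maps canonical field names (see ``DEFAULT_DIALECT``) to
    the file's column names. Rows violating record invariants (zero SE,
    indels, inconsistent p-values, ...) are skipped with a logged count;
    a missing required column is fatal.
    """
    d = dict(DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    df = pd.read_csv(
        path, sep="\t", dtype={d["chr"]: str, d["snp"]: str}, float_precision="round_trip"
    )
    missing = [f for f in REQUIRED_FIELDS if d[f] not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(d[f] for f in missing)}")
    has_cases = d["n_cases"] in df.columns
    records: list[SumStatRecord] = []
    skipped = 0
    for row in df.itertuples(index=False):
        row = row._asdict()
        try:
            n_cases = None
            if has_cases and not pd.isna(row[d["n_cases"]]):
                n_cases = int(row[d["n_cases"]])
            rec = SumStatRecord(
                snp_id=str(row[d["snp"]]),
                chrom=str(row[d["chr"]]),
                pos=int(row[d["pos"]]),
                effect_allele=str(row[d["ea"]]).upper(),
                other_allele=str(row[d["oa"]]).upper(),
                eaf=float(row[d["eaf"]]),
                beta=float(row[d["beta"]]),
                se=float(row[d["se"]]),
                pval=float(row[d["pval"]]),
                n=float(row[d["n"]]),
                n_cases=n_cases,
                trait_type="binary" if (n_cases is not None or trait_type == "binary") else "quantitative",
            )
            rec.validate()
        except (ValueError, TypeError) as e:
            skipped += 1
            log.warning("skipping row (%s)", e)
            continue
        records.append(rec)
    if skipped:
        log.info("read_sumstats: %d record(s) read, %d row(s) skipped", len(records), skipped)
    return records


def write_sumstats(records: list[SumStatRecord], path) -> None:
    """Write records in the canonical tab-delimited layout (full float precision)."""
    cols = ["snp", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "pval", "n", "n_cases"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.snp_id,
                        r.chrom,
                        str(r.pos),
                        r.effect_allele,
                        r.other_allele,
                        _fmt(r.eaf),
                        _fmt(r.beta),
                        _fmt(r.se),
                        _fmt(r.pval),
                        _fmt(r.n),
                        "" if r.n_cases is None else str(r.n_cases),
                    ]
                )
                + "\n"
            )


def read_gene_regions(path) -> list[GeneRegion]:
    """Read a headerless BED-like TSV: gene_id, chrom, start, end[, tier]."""
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"gene region line has fewer than 4 columns: {line!r}")
            tier = parts[4] if len(parts) > 4 and parts[4] else "none"
            regions.append(GeneRegion(parts[0], parts[1], int(parts[2]), int(parts[3]), tier))
    return regions


def write_gene_regions(regions: list[GeneRegion], path) -> None:
    with open(path, "w") as fh:
        for g in regions:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\t{g.druggability_tier}\n")


def read_ld(path) -> LDBlock:
    """Read a plain-text LD matrix: an index line of SNP ids, then the rows."""
    with open(path) as fh:
        snp_ids = fh.readline().rstrip("\n").split("\t")
        R = np.loadtxt(fh, ndmin=2)
    return LDBlock(snp_ids, R)


def write_ld(ld: LDBlock, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ld.snp_ids) + "\n")
        for row in ld.R:
            fh.write("\t".join(_fmt(x) for x in row) + "\n")
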
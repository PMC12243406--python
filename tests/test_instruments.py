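"""Cis-window selection, LD clumping and instrument filters."""

import itertools

import numpy as np
import pytest

from targetmr import (
    LDBlock,
    PipelineConfig,
    Scenario,
    clump,
    exclude_outcome_associated,
    f_statistic_filter,
    select_cis,
    select_instruments,
    simulate_locus,
    steiger_filter,
)
from targetmr.simulate import ar1_matrix
from targetmr.sumstats import GeneRegion

from conftest import make_pair, make_record

REGION = GeneRegion("G1", "1", 5_000_000, 5_050_000, "1")


class TestSelectCis:
    @pytest.mark.parametrize(
        "pos,pval,expected",
        [
            (REGION.start - 1_000_000, 1e-9, True),   # boundary inclusive
            (REGION.start - 1_000_001, 1e-9, False),  # one bp outside
            (REGION.start + 100, 5.0e-8, False),      # threshold is strict <
            (REGION.end + 1_000_000, 1e-9, True),
            (REGION.start + 100, 4.9e-8, True),
        ],
    )
    def test_window_and_threshold_boundaries(self, pos, pval, expected):
        rec = make_record(snp_id="rs1", pos=pos, pval=pval, beta=0.1, se=0.018)
        kept = select_cis([rec], REGION, window_kb=1000, p_threshold=5e-8)
        assert (len(kept) == 1) is expected

    def test_other_chromosome_excluded(self):
        rec = make_record(snp_id="rs1", chrom="2", pos=REGION.start, pval=1e-9, se=0.016)
        assert select_cis([rec], REGION) == []


def _ld(n, rho):
    return LDBlock([f"rs{i}" for i in range(n)], ar1_matrix(n, rho))


def _brute_force_check(kept, removed_set, records, ld, r2, kb):
    """Oracle: kept SNPs pairwise r² < r2 within kb; every removed SNP is
    claimed by a kept SNP that is more significant (or tied, earlier id)."""
    by_id = {r.snp_id: r for r in records}
    for a, b in itertools.combinations(kept, 2):
        if abs(a.pos - b.pos) <= kb * 1000:
            assert ld.r2(a.snp_id, b.snp_id) < r2
    for snp in removed_set:
        r = by_id[snp]
        claimers = [
            k
            for k in kept
            if abs(k.pos - r.pos) <= kb * 1000
            and ld.r2(k.snp_id, snp) >= r2
            and (k.pval, k.snp_id) < (r.pval, r.snp_id)
        ]
        assert claimers, f"{snp} removed but not claimed by any kept index"


class TestClump:
    def test_correlated_pair_keeps_most_significant(self):
        ld = LDBlock(["rs0", "rs1"], np.array([[1.0, np.sqrt(0.5)], [np.sqrt(0.5), 1.0]]))
        a = make_record(snp_id="rs0", pos=100, pval=1e-10, beta=0.13, se=0.02)
        b = make_record(snp_id="rs1", pos=200, pval=1e-9, beta=0.12, se=0.02)
        kept = clump([a, b], ld, clump_r2=0.001, clump_kb=10_000)
        assert [r.snp_id for r in kept] == ["rs0"]

    def test_independent_pair_both_kept(self):
        ld = LDBlock(["rs0", "rs1"], np.eye(2))
        a = make_record(snp_id="rs0", pos=100, pval=1e-10, beta=0.13, se=0.02)
        b = make_record(snp_id="rs1", pos=200, pval=1e-9, beta=0.12, se=0.02)
        assert len(clump([a, b], ld, 0.001, 10_000)) == 2

    def test_distance_window_limits_claiming(self):
        # identical LD but 11 Mb apart: both kept at clump_kb=10,000
        ld = LDBlock(["rs0", "rs1"], np.array([[1.0, 0.9], [0.9, 1.0]]))
        a = make_record(snp_id="rs0", pos=1, pval=1e-10, beta=0.13, se=0.02)
        b = make_record(snp_id="rs1", pos=11_000_002, pval=1e-9, beta=0.12, se=0.02)
        assert len(clump([a, b], ld, 0.001, 10_000)) == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_greedy_output_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        ld = _ld(n, 0.9)
        records = [
            make_record(
                snp_id=f"rs{i}",
                pos=1000 + 5000 * i,
                beta=float(rng.uniform(0.05, 0.2)) * (1 if rng.random() < 0.5 else -1),
                se=0.01,
            )
            for i in range(n)
        ]
        kept = clump(records, ld, clump_r2=0.001, clump_kb=10_000)
        removed = {r.snp_id for r in records} - {k.snp_id for k in kept}
        _brute_force_check(kept, removed, records, ld, 0.001, 10_000)

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(42)
        n = 15
        ld = _ld(n, 0.8)
        records = [
            make_record(snp_id=f"rs{i}", pos=1000 + 2000 * i,
                        beta=float(rng.uniform(0.05, 0.2)), se=0.012)
            for i in range(n)
        ]
        ref = [r.snp_id for r in clump(records, ld, 0.01, 10_000)]
        for _ in range(5):
            rng.shuffle(records)
            assert [r.snp_id for r in clump(records, ld, 0.01, 10_000)] == ref

    def test_single_causal_locus_clumps_to_one_snp(self):
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            s = Scenario(theta=0.0, n_exposure=50_000, n_outcome=50_000,
                         outcome_case_fraction=None, seed=seed)
            loc = simulate_locus(s)
            sig = select_cis(loc.exposure_stats, loc.region, 1000, 5e-8)
            kept = clump(sig, loc.ld, 0.001, 10_000)
            hits += len(kept) == 1
        assert hits / n_rep >= 0.95


class TestPairFilters:
    def test_outcome_association_boundary(self):
        strong = make_pair(0.1, 0.02, 0.09, 0.018)          # outcome p ~ 6e-7
        weak = make_pair(0.1, 0.02, 0.01, 0.02)             # outcome p = 0.617
        kept = exclude_outcome_associated([strong, weak], 5e-5)
        assert kept == [weak]
        # outcome p exactly at the threshold is retained (removal is strict <)
        import dataclasses

        base = make_pair(0.1, 0.02, 0.073, 0.018)
        exact = dataclasses.replace(base, outcome=dataclasses.replace(base.outcome, pval=5e-5))
        assert exclude_outcome_associated([exact], 5e-5) == [exact]
        assert exclude_outcome_associated([], 5e-5) == []

    @pytest.mark.parametrize(
        "z_exp,z_out,retained",
        [(10.0, 2.0, True), (2.0, 10.0, False), (4.0, 4.0, True)],  # ties retained
    )
    def test_steiger_directionality(self, z_exp, z_out, retained):
        pair = make_pair(z_exp * 0.02, 0.02, z_out * 0.02, 0.02, n=10_000)
        assert (steiger_filter([pair]) == [pair]) is retained

    def test_steiger_small_n_dropped(self):
        pair = make_pair(0.2, 0.02, 0.04, 0.02, n=2)
        dropped = []
        assert steiger_filter([pair], dropped=dropped) == []
        assert dropped == ["rs1"]

    def test_steiger_af_formula_switch(self):
        # same z-ratio but eaf-weighted variance favours the exposure
        pair = make_pair(0.5, 0.05, 0.1, 0.05, eaf=0.3)
        assert steiger_filter([pair], formula="af") == [pair]

    @pytest.mark.parametrize(
        "beta,se,f_expected,kept",
        [(0.5, 0.05, 100.0, True), (0.3, 0.1, 9.0, False), (0.0, 0.1, 0.0, False)],
    )
    def test_f_statistic_floor(self, beta, se, f_expected, kept):
        pair = make_pair(beta, se, 0.01, 0.02)
        from targetmr.instruments import f_statistic

        assert f_statistic(pair) == pytest.approx(f_expected)
        assert (f_statistic_filter([pair], 10.0) == [pair]) is kept


class TestFullSelectionPass:
    def test_filter_log_accounts_for_every_removal(self):
        s = Scenario(theta=0.1, n_exposure=50_000, n_outcome=50_000,
                     outcome_case_fraction=None, seed=3)
        loc = simulate_locus(s)
        inst = select_instruments(
            "G1", loc.exposure_stats, loc.outcome_stats, loc.region, loc.ld
        )
        n_cis = len(select_cis(loc.exposure_stats, loc.region, 1000, 5e-8))
        assert n_cis == len(inst.pairs) + len(inst.filter_log)

    def test_retained_instruments_satisfy_set_invariants(self):
        s = Scenario(theta=0.0, n_exposure=50_000, n_outcome=50_000,
                     outcome_case_fraction=None, seed=9,
                     causal_exposure=((50, 0.12), (150, 0.12)))
        loc = simulate_locus(s)
        inst = select_instruments(
            "G1", loc.exposure_stats, loc.outcome_stats, loc.region, loc.ld
        )
        lo = loc.region.start - 1000 * 1000
        hi = loc.region.end + 1000 * 1000
        for p in inst.pairs:
            assert lo <= p.exposure.pos <= hi
            assert p.exposure.pval < 5e-8
            assert p.exposure.effect_allele == p.outcome.effect_allele
        for a, b in itertools.combinations(inst.pairs, 2):
            assert loc.ld.r2(a.snp_id, b.snp_id) < 0.001
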
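"""Tier classification, endophenotype MR and the PheWAS scan."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from targetmr import (
    ColocResult,
    EvidenceRow,
    LocusData,
    MRResult,
    PhenotypeOutcome,
    PipelineConfig,
    Scenario,
    SMRResult,
    classify_tier,
    direction_concordance,
    endophenotype_mr,
    phewas_scan,
    simulate_locus,
)


def _mr(beta=-0.15, p_fdr=0.01):
    return MRResult("G", "ivw", 2, beta, 0.03, 1e-6, float(np.exp(beta)),
                    float(np.exp(beta - 0.06)), float(np.exp(beta + 0.06)), p_fdr=p_fdr)


def _smr(b=-0.6, p=0.001, p_heidi=0.5):
    return SMRResult("G", "snp100", b, 0.2, p, float(np.exp(b)), 0.2, 0.9,
                     p_heidi, 10, "pass")


def _coloc(pp4):
    rest = (1 - pp4) / 4
    return ColocResult("G", rest, rest, rest, rest, pp4, 200, (1e-4, 1e-4, 1e-5))


class TestClassifyTier:
    def test_full_evidence_is_tier1(self):
        # MR pass + consistent SMR + PPH4=0.940: the strongest pattern
        row = EvidenceRow("G", "3A", _mr(), _smr(), _coloc(0.940))
        assert classify_tier(row).tier == "1"

    def test_mr_and_coloc_only_is_tier2(self):
        # SMR evaluated but not significant; PPH4=0.706 passes
        row = EvidenceRow("G", "1", _mr(), _smr(p=0.4), _coloc(0.706))
        call = classify_tier(row)
        assert call.tier == "2"
        assert any("SMR" in r for r in call.reasons)

    def test_mr_and_smr_only_is_tier2(self):
        row = EvidenceRow("G", "1", _mr(), _smr(), _coloc(0.30))
        assert classify_tier(row).tier == "2"

    def test_mr_only_is_tier3(self):
        # coloc evaluated but weak, no expression data at all
        row = EvidenceRow("G", "3B", _mr(), None, _coloc(0.447))
        call = classify_tier(row)
        assert call.tier == "3"
        assert "no available gene expression data" in call.reasons

    def test_missing_coloc_counts_as_failed_criterion(self):
        row = EvidenceRow("G", "3B", _mr(), _smr(), None)
        call = classify_tier(row)
        assert call.tier == "2"
        assert "no colocalisation evidence" in call.reasons

    def test_opposite_smr_direction_excludes(self):
        # transcript effect significant but opposite in sign to the protein
        row = EvidenceRow("G", "2", _mr(beta=-0.15), _smr(b=+0.6), _coloc(0.940))
        call = classify_tier(row)
        assert call.tier == "excluded"
        assert row.direction_consistent is False

    def test_nonsignificant_mr_blocks_everything(self):
        row = EvidenceRow("G", "1", _mr(p_fdr=0.2), _smr(), _coloc(0.94))
        assert classify_tier(row).tier == "not_significant"

    def test_heidi_failure_demotes_smr_criterion(self):
        row = EvidenceRow("G", "1", _mr(), _smr(p_heidi=0.001), _coloc(0.94))
        call = classify_tier(row)
        assert call.tier == "2"
        assert any("HEIDI" in r for r in call.reasons)

    def test_pph4_threshold_boundary_is_strict(self):
        row = EvidenceRow("G", "1", _mr(), None, _coloc(0.70))
        assert classify_tier(row).tier == "3"  # 0.70 is not > 0.70

    def test_pure_function_and_monotone_in_coloc_evidence(self):
        base = EvidenceRow("G", "1", _mr(), _smr(p=0.4), None)
        first = classify_tier(base)
        assert classify_tier(base).tier == first.tier
        upgraded = EvidenceRow("G", "1", _mr(), _smr(p=0.4), _coloc(0.95))
        order = {"3": 0, "2": 1, "1": 2}
        assert order[classify_tier(upgraded).tier] >= order[first.tier]


def _quant_locus(theta, seed, n=30_000):
    s = Scenario(theta=theta, n_exposure=n, n_outcome=n,
                 outcome_case_fraction=None, seed=seed)
    loc = simulate_locus(s)
    return LocusData(s.gene_id, loc.region, loc.ld, loc.exposure_stats), loc.outcome_stats


class TestEndophenotypeMR:
    def test_recovers_negative_effect_on_quantitative_outcome(self):
        cfg = PipelineConfig(p_outcome_threshold=None)
        covered, n_rep = 0, 200
        for seed in range(n_rep):
            locus, outcome = _quant_locus(-0.2, seed)
            table = endophenotype_mr([locus], {"iop": {locus.gene_id: outcome}}, cfg)
            row = table.iloc[0]
            if row.flag == "" and row.ci_low <= -0.2 <= row.ci_high:
                covered += 1
        assert covered / n_rep >= 0.90

    def test_null_effect_type_I_error_near_nominal(self):
        cfg = PipelineConfig(p_outcome_threshold=None)
        sig, evaluated = 0, 0
        for seed in range(300):
            locus, outcome = _quant_locus(0.0, seed + 1000)
            table = endophenotype_mr([locus], {"rnfl": {locus.gene_id: outcome}}, cfg)
            row = table.iloc[0]
            if row.flag == "":
                evaluated += 1
                sig += bool(row.significant)
        assert 0.02 <= sig / evaluated <= 0.08

    def test_single_instrument_reports_wald_ratio(self):
        cfg = PipelineConfig(p_outcome_threshold=None)
        locus, outcome = _quant_locus(-0.2, 7)
        table = endophenotype_mr([locus], {"iop": {locus.gene_id: outcome}}, cfg)
        row = table.iloc[0]
        assert row.n_snps >= 1
        if row.n_snps == 1:
            assert row.method == "wald_ratio"

    def test_target_without_instruments_gets_flagged_row(self):
        locus, outcome = _quant_locus(0.0, 3)
        starved = dataclasses.replace(locus)
        starved.exposure = []
        table = endophenotype_mr([starved], {"iop": {locus.gene_id: outcome}})
        assert table.iloc[0].flag == "no_surviving_instruments"


class TestPheWAS:
    def test_case_count_filter_strictly_greater(self):
        locus, outcome = _quant_locus(0.0, 5)
        at = PhenotypeOutcome("at_min", "c", 500, outcome)
        above = PhenotypeOutcome("above_min", "c", 501, outcome)
        rows = phewas_scan(locus, [at, above], case_min=500,
                           config=PipelineConfig(p_outcome_threshold=None))
        assert [r.phenotype_id for r in rows] == ["above_min"]

    def test_raw_p_independent_of_catalogue_composition(self):
        cfg = PipelineConfig(p_outcome_threshold=None)
        locus, outcome = _quant_locus(0.1, 6)
        _, other = _quant_locus(0.0, 66)
        solo = phewas_scan(locus, [PhenotypeOutcome("a", "c", 1000, outcome)], config=cfg)
        duo = phewas_scan(
            locus,
            [PhenotypeOutcome("a", "c", 1000, outcome), PhenotypeOutcome("b", "c", 1000, other)],
            config=cfg,
        )
        assert solo[0].mr.pval == duo[0].mr.pval
        assert solo[0].p_fdr != duo[0].p_fdr or len(duo) == 1

    def test_true_effect_ranks_first_among_nulls(self):
        cfg = PipelineConfig(p_outcome_threshold=None)
        wins, n_rep = 0, 100
        for seed in range(n_rep):
            locus, causal_outcome = _quant_locus(0.3, seed + 5000)
            _, null1 = _quant_locus(0.0, seed + 6000)
            _, null2 = _quant_locus(0.0, seed + 7000)
            rows = phewas_scan(
                locus,
                [
                    PhenotypeOutcome("causal", "c", 1000, causal_outcome),
                    PhenotypeOutcome("null1", "c", 1000, null1),
                    PhenotypeOutcome("null2", "c", 1000, null2),
                ],
                config=cfg,
            )
            ranked = sorted((r for r in rows if r.mr is not None), key=lambda r: r.mr.pval)
            wins += bool(ranked) and ranked[0].phenotype_id == "causal"
        assert wins / n_rep >= 0.90


class TestDirectionConcordance:
    def test_reports_sign_agreement_fraction(self):
        disc = pd.DataFrame({"gene_id": ["a", "b", "c"], "beta": [0.2, -0.1, 0.3]})
        repl = pd.DataFrame({"gene_id": ["a", "b", "c", "d"], "beta": [0.1, -0.4, -0.2, 1.0]})
        rep = direction_concordance(disc, repl)
        assert rep == {"n_shared": 3, "n_concordant": 2, "concordance": pytest.approx(2 / 3)}

    def test_empty_overlap(self):
        disc = pd.DataFrame({"gene_id": ["a"], "beta": [0.2]})
        repl = pd.DataFrame({"gene_id": ["x"], "beta": [0.1]})
        assert direction_concordance(disc, repl)["n_shared"] == 0
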
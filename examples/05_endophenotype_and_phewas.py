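"""Endophenotype MR and a mini phenome-wide scan for one target protein.

The protein truly lowers a quantitative endophenotype (think intraocular
pressure, theta = -0.2) and has no effect on two null phenotypes; the
scan should rank the true effect first and BH-FDR should keep the nulls
quiet.
"""

import dataclasses

import numpy as np

from targetmr import (
    LocusData,
    PhenotypeOutcome,
    PipelineConfig,
    Scenario,
    endophenotype_mr,
    phewas_scan,
    redraw_outcome,
    simulate_locus,
)

config = PipelineConfig(p_outcome_threshold=None)

scenario = Scenario(theta=-0.2, n_exposure=35_559, n_outcome=29_578,
                    outcome_case_fraction=None, seed=2)
locus = simulate_locus(scenario)
target = LocusData(scenario.gene_id, locus.region, locus.ld, locus.exposure_stats)
iop_outcome = locus.outcome_stats

# null outcomes on the same SNP panel, independent sampling noise
rng = np.random.default_rng(30)
null_scenario = dataclasses.replace(scenario, theta=0.0)
null1 = redraw_outcome(locus, null_scenario, rng)
null2 = redraw_outcome(locus, null_scenario, rng)
table = endophenotype_mr([target], {"IOP": {target.gene_id: iop_outcome}}, config)
row = table.iloc[0]
print("endophenotype MR:")
print(f"  beta on IOP = {row.beta:.3f} SD (95% CI {row.ci_low:.3f} to {row.ci_high:.3f}),"
      f" p={row.pval:.2e}  [true -0.2]")

catalogue = [
    PhenotypeOutcome("true_effect_trait", "ocular", 2_000, iop_outcome),
    PhenotypeOutcome("null_trait_A", "other", 5_000, null1),
    PhenotypeOutcome("null_trait_B", "other", 800, null2),
    PhenotypeOutcome("underpowered_trait", "other", 400, null2),  # <= 500 cases: skipped
]
print("\nPheWAS scan (case minimum 500):")
for r in phewas_scan(target, catalogue, case_min=500, config=config):
    print(f"  {r.phenotype_id:20s} p={r.mr.pval:.2e}  p_fdr={r.p_fdr:.3f}")
# Only phenotypes with > 500 cases are scanned; p_fdr is BH-adjusted across
# the scanned set, so a lone true effect stays significant while nulls do not.
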
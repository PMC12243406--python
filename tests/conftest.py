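import numpy as np
import pytest
from scipy import stats

from targetmr import (
    HarmonisedPair,
    LocusData,
    PipelineConfig,
    Scenario,
    SumStatRecord,
    harmonise,
    simulate_locus,
)


def make_record(
    snp_id="rs1",
    beta=0.1,
    se=0.02,
    n=50_000,
    eaf=0.3,
    pos=1_000_000,
    chrom="1",
    ea="A",
    oa="G",
    trait_type="quantitative",
    n_cases=None,
    pval=None,
):
    """Build a record whose p-value is consistent with beta/se by default."""
    if pval is None:
        pval = max(2.0 * stats.norm.sf(abs(beta / se)), 1e-320)
    return SumStatRecord(
        snp_id=snp_id,
        chrom=chrom,
        pos=pos,
        effect_allele=ea,
        other_allele=oa,
        eaf=eaf,
        beta=beta,
        se=se,
        pval=pval,
        n=float(n),
        n_cases=n_cases,
        trait_type=trait_type,
    )


def make_pair(beta_exp, se_exp, beta_out, se_out, snp_id="rs1", n=50_000, **kw):
    exp = make_record(snp_id=snp_id, beta=beta_exp, se=se_exp, n=n, **kw)
    out = make_record(snp_id=snp_id, beta=beta_out, se=se_out, n=n, **kw)
    return harmonise(exp, out)


@pytest.fixture
def mk():
    return make_record


@pytest.fixture
def mkpair():
    return make_pair


@pytest.fixture
def shared_locus():
    """One shared-causal-variant locus with a strong cis effect."""
    s = Scenario(
        theta=0.3,
        n_exposure=50_000,
        n_outcome=50_000,
        outcome_case_fraction=None,
        seed=11,
    )
    return s, simulate_locus(s)


@pytest.fixture
def locus_data(shared_locus):
    s, loc = shared_locus
    return LocusData(s.gene_id, loc.region, loc.ld, loc.exposure_stats), loc.outcome_stats


@pytest.fixture
def no_outcome_filter_config():
    # a strong true effect makes the instrument genuinely outcome-associated;
    # recovery checks therefore run without the outcome-association exclusion
    return PipelineConfig(p_outcome_threshold=None)
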
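"""Two-sample Mendelian-randomization estimators.

For a gene instrumented by a single cis-SNP the causal effect is the
Wald ratio ``beta_out / beta_exp`` with a first-order delta-method
standard error ``se_out / |beta_exp|``. With multiple approximately
independent instruments the per-SNP ratios are combined by fixed-effect
inverse-variance weighting, which is algebraically the zero-intercept
weighted regression of outcome betas on exposure betas with weights
``1/se_out²``. The MR-Egger intercept — the same regression with a free
intercept, exposure betas oriented non-negative — is a directional
horizontal-pleiotropy diagnostic: a nonzero intercept means instruments
affect the outcome through paths other than the exposure.

Binary outcomes are on the log-odds scale, so ``exp(beta_mr)`` is the
odds ratio per SD of genetically predicted exposure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .sumstats import HarmonisedPair

log = logging.getLogger(__name__)

Z95 = 1.9600  # normal 95% CI multiplier


@dataclass
class MRResult:
    gene_id: str
    method: str  # wald_ratio | ivw
    n_snps: int
    beta_mr: float
    se_mr: float
    pval: float
    or_point: float
    ci_low: float
    ci_high: float
    egger_intercept: float | None = None
    egger_intercept_pval: float | None = None
    p_fdr: float | None = None

    @property
    def significant_fdr(self) -> bool:
        return self.p_fdr is not None and self.p_fdr < 0.05


def _result(gene_id: str, method: str, n_snps: int, beta: float, se: float) -> MRResult:
    pval = 2.0 * stats.norm.sf(abs(beta / se)) if se > 0 else float("nan")
    pval = max(pval, 5e-324)
    return MRResult(
        gene_id=gene_id,
        method=method,
        n_snps=n_snps,
        beta_mr=beta,
        se_mr=se,
        pval=pval,
        or_point=math.exp(beta),
        ci_low=math.exp(beta - Z95 * se),
        ci_high=math.exp(beta + Z95 * se),
    )


def wald_ratio(pair: HarmonisedPair, gene_id: str = "") -> MRResult:
    """Single-instrument causal estimate (first-order delta-method SE)."""
    b_exp, b_out = pair.exposure.beta, pair.outcome.beta
    if b_exp == 0.0:
        raise ValueError("wald_ratio undefined for zero exposure beta")
    beta = b_out / b_exp
    se = pair.outcome.se / abs(b_exp)
    return _result(gene_id, "wald_ratio", 1, beta, se)


def _ratios(pairs: list[HarmonisedPair]) -> tuple[np.ndarray, np.ndarray]:
    b_exp = np.array([p.exposure.beta for p in pairs])
    if np.any(b_exp == 0.0):
        raise ValueError("zero exposure beta among instruments")
    r = np.array([p.outcome.beta for p in pairs]) / b_exp
    se = np.array([p.outcome.se for p in pairs]) / np.abs(b_exp)
    return r, se


def ivw(pairs: list[HarmonisedPair], gene_id: str = "") -> MRResult:
    """Fixed-effect inverse-variance-weighted combination of Wald ratios."""
    if len(pairs) < 2:
        raise ValueError("ivw requires ≥ 2 instruments; use wald_ratio")
    r, se = _ratios(pairs)
    w = 1.0 / se**2
    beta = float(np.sum(w * r) / np.sum(w))
    se_mr = float(1.0 / math.sqrt(np.sum(w)))
    return _result(gene_id, "ivw", len(pairs), beta, se_mr)


def egger_intercept(pairs: list[HarmonisedPair]) -> tuple[float, float, float]:
    """MR-Egger intercept diagnostic for directional pleiotropy.

    Weighted (1/se_out²) regression with intercept of outcome betas on
    exposure betas, exposure betas first oriented non-negative. The
    intercept SE uses the usual regression scale (weighted RSS / (m−2)).
    Returns (intercept, intercept_se, two-sided p).
    """
    m = len(pairs)
    if m < 3:
        raise ValueError("egger_intercept requires ≥ 3 instruments")
    b_exp = np.array([p.exposure.beta for p in pairs])
    b_out = np.array([p.outcome.beta for p in pairs])
    se_out = np.array([p.outcome.se for p in pairs])
    sign = np.where(b_exp < 0, -1.0, 1.0)
    x, y = b_exp * sign, b_out * sign
    w = 1.0 / se_out**2
    X = np.column_stack([np.ones(m), x])
    XtW = X.T * w
    xtwx_inv = np.linalg.inv(XtW @ X)
    coef = xtwx_inv @ (XtW @ y)
    resid = y - X @ coef
    scale = float(np.sum(w * resid**2) / (m - 2))
    se0 = math.sqrt(scale * xtwx_inv[0, 0])
    intercept = float(coef[0])
    p = 2.0 * stats.norm.sf(abs(intercept / se0)) if se0 > 0 else float("nan")
    return intercept, se0, p


def fit_mr(pairs: list[HarmonisedPair], gene_id: str = "") -> MRResult:
    """Wald ratio for a single instrument, IVW otherwise; Egger intercept
    attached as a diagnostic when ≥ 3 instruments are available."""
    if not pairs:
        raise ValueError("no instruments supplied")
    res = wald_ratio(pairs[0], gene_id) if len(pairs) == 1 else ivw(pairs, gene_id)
    if len(pairs) >= 3:
        intercept, _, p_int = egger_intercept(pairs)
        res.egger_intercept = intercept
        res.egger_intercept_pval = p_int
        if p_int < 0.05:
            log.info("%s: MR-Egger intercept p=%.3g flags directional pleiotropy", gene_id, p_int)
    else:
        log.debug("%s: < 3 instruments, Egger intercept diagnostic skipped", gene_id)
    return res


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def attach_fdr(results: list[MRResult]) -> list[MRResult]:
    """Set ``p_fdr`` across a family of MR results (in place; returned for chaining)."""
    if results:
        q = bh_fdr([r.pval for r in results])
        for res, qi in zip(results, q):
            res.p_fdr = float(qi)
    return results
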
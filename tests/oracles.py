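"""Independent analytic oracles used across the test suite.

These are derived directly from the generative model, not from the package's
fitting code, so they can serve as cross-checks on it.
"""

import math

import numpy as np
from scipy import stats

from cfbgwas import SimulationParams


def genotype_variance(params: SimulationParams) -> float:
    return 2.0 * params.maf * (1.0 - params.maf)


def mediator_shift(params: SimulationParams) -> float:
    """Expected shift of the genotype test statistic in a baseline-unadjusted
    CFB analysis, in standard-error units.

    The unadjusted model tests the marginal effect beta_G + beta_G0 * beta_y0
    against a residual scale of sqrt(beta_y0^2 sd_eps0^2 + sd_eps1^2) (the
    conditional CFB noise once treatment and age are regressed out), so the
    standardized noncentrality is |effect| * sqrt(n * var(G)) / sigma_resid.
    """
    effect = params.beta_G + params.beta_G0 * params.beta_y0
    sigma_resid = math.sqrt(
        params.beta_y0**2 * params.sd_eps0**2 + params.sd_eps1**2
    )
    return abs(effect) * math.sqrt(params.n_subjects * genotype_variance(params)) / sigma_resid


def unadjusted_rejection_rate(params: SimulationParams, alpha: float) -> float:
    """Two-sided normal tail P(|Z + delta| > z_{alpha/2}) for the unadjusted
    genotype test under a mediator-effect null (or alternative)."""
    delta = mediator_shift(params)
    z = stats.norm.isf(alpha / 2.0)
    return float(stats.norm.sf(z - delta) + stats.norm.sf(z + delta))


def unadjusted_inflation_ratio(params: SimulationParams, alpha: float) -> float:
    return unadjusted_rejection_rate(params, alpha) / alpha


def baseline_detection_power(
    beta_G0: float, params: SimulationParams, alpha: float
) -> float:
    """Analytic power of the baseline-association model (genotype t-test on
    ln y0) for a variant with baseline effect ``beta_G0``."""
    se = params.sd_eps0 / math.sqrt(params.n_subjects * genotype_variance(params))
    delta = abs(beta_G0) / se
    z = stats.norm.isf(alpha / 2.0)
    return float(stats.norm.sf(z - delta) + stats.norm.sf(z + delta))


def baseline_cfb_correlation(params: SimulationParams) -> float:
    """Closed-form corr(ln y0, ln y1 - ln y0) under the generative model.

    cov(ln y0, CFB) = beta_y0 * var(ln y0); the CFB variance adds the
    treatment and age contributions and the CFB noise. Ignores the (rare)
    floor truncation.
    """
    p = params
    var_lny0 = p.beta_G0**2 * genotype_variance(p) + p.sd_eps0**2
    var_t = p.treatment_prob * (1.0 - p.treatment_prob)
    width = p.age_range[1] - p.age_range[0]
    g_terms = (p.beta_G + p.beta_G0 * p.beta_y0) ** 2 * genotype_variance(p)
    # with beta_G = beta_GT = beta_G0 = 0 this reduces to
    # beta_y0 * sd0 / sqrt(beta_y0^2 sd0^2 + var_T + var_X + sd1^2)
    var_cfb = (
        p.beta_y0**2 * p.sd_eps0**2
        + g_terms
        + p.beta_T**2 * var_t
        + p.beta_X**2 * width**2 / 12.0
        + p.sd_eps1**2
    )
    cov = p.beta_y0 * var_lny0 + p.beta_G0 * (p.beta_G + p.beta_G0 * p.beta_y0) * genotype_variance(p)
    return float(cov / math.sqrt(var_lny0 * var_cfb))


def brute_force_ols(X: np.ndarray, y: np.ndarray):
    """Normal-equations least squares written out independently of the
    package: coefficients, standard errors, two-sided t-test p-values."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = resid @ resid / dof
    cov = np.linalg.inv(XtX) * sigma2
    se = np.sqrt(np.diag(cov))
    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return beta, se, p, cov, dof
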
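"""The twelve analysis models for quantitative change-from-baseline GWAS.

Eleven regression models plus Cochran's Q, spanning the design axes that
matter for the baseline-adjustment question:

==== ===================== ============ ===== ========
id   phenotype             baseline adj test  approach
==== ===================== ============ ===== ========
M1   log-fold CFB          yes (ln y0)  1df   2-step INT residuals
M2   CFB ratio             no           1df   2-step INT residuals
M3   log-fold CFB          no           1df   2-step INT residuals
M4   CFB ratio             yes (raw y0) 1df   2-step INT residuals
M5   log-fold CFB          yes (ln y0)  2df   1-step
M6   log-fold CFB          no           2df   1-step
M7   log baseline          --           1df   1-step (baseline association)
M8   log-fold CFB          yes (ln y0)  1df   1-step
M9   log-fold CFB          no           1df   1-step
M5s  log post-treatment    yes (ln y0)  1df   1-step
M6s  log post-treatment    no           1df   1-step
Q    Cochran's Q on the genotype coefficients of ln y0 and ln y1
==== ===================== ============ ===== ========

Two-step models first regress the phenotype on the non-genetic covariates
(treatment, age, and the baseline term where adjusted), inverse-normal
transform the residuals, then regress the transformed residuals on genotype.
One-step models fit a single ordinary least-squares model containing genotype
(and, for the 2df models, the genotype-by-treatment interaction, tested
jointly with the main effect by a Wald chi-square with 2 degrees of freedom).

All tests are two-sided. Single-coefficient p-values use the t distribution
with the residual degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import DesignError, ValidationError
from .simulate import Cohort, SimulationParams

__all__ = [
    "ModelSpec",
    "AssocResult",
    "MODELS",
    "MODEL_IDS",
    "inverse_normal_transform",
    "fit_model",
    "fit_two_step",
    "fit_one_step",
    "cochran_q",
    "cochran_q_from_estimates",
    "unadjusted_marginal_effect",
    "results_to_table",
]

BLOM_OFFSET = 3.0 / 8.0


@dataclass(frozen=True)
class ModelSpec:
    """Identity and configuration of one analysis model."""

    id: str
    phenotype: str  # log_fold_cfb | cfb_ratio | log_baseline | log_post
    baseline_adjusted: bool
    approach: str  # two_step_int | one_step | cochran_q
    test: str  # wald_1df | joint_2df | baseline_only | cochran_q
    baseline_scale: str = "log"  # raw only for M4


MODELS: dict[str, ModelSpec] = {
    "M1": ModelSpec("M1", "log_fold_cfb", True, "two_step_int", "wald_1df"),
    "M2": ModelSpec("M2", "cfb_ratio", False, "two_step_int", "wald_1df"),
    "M3": ModelSpec("M3", "log_fold_cfb", False, "two_step_int", "wald_1df"),
    "M4": ModelSpec("M4", "cfb_ratio", True, "two_step_int", "wald_1df", baseline_scale="raw"),
    "M5": ModelSpec("M5", "log_fold_cfb", True, "one_step", "joint_2df"),
    "M6": ModelSpec("M6", "log_fold_cfb", False, "one_step", "joint_2df"),
    "M7": ModelSpec("M7", "log_baseline", False, "one_step", "baseline_only"),
    "M8": ModelSpec("M8", "log_fold_cfb", True, "one_step", "wald_1df"),
    "M9": ModelSpec("M9", "log_fold_cfb", False, "one_step", "wald_1df"),
    "M5s": ModelSpec("M5s", "log_post", True, "one_step", "wald_1df"),
    "M6s": ModelSpec("M6s", "log_post", False, "one_step", "wald_1df"),
    "Q": ModelSpec("Q", "log_post", False, "cochran_q", "cochran_q"),
}

MODEL_IDS: tuple[str, ...] = tuple(MODELS)


@dataclass
class AssocResult:
    """Fitted coefficients, standard errors and p-values for one model fit."""

    model_id: str
    n_used: int
    df_resid: int
    beta_G: float = np.nan
    se_G: float = np.nan
    p_G: float = np.nan
    beta_y0: float = np.nan
    se_y0: float = np.nan
    beta_GT: float = np.nan
    se_GT: float = np.nan
    p_GT: float = np.nan
    p_2df: float = np.nan
    q_stat: float = np.nan
    p_Q: float = np.nan
    degenerate: bool = False

    @property
    def primary_p(self) -> float:
        """The p-value used for rejection: joint 2df where available, else
        the genotype main-effect test (Q models use the heterogeneity p)."""
        if not np.isnan(self.p_2df):
            return self.p_2df
        if not np.isnan(self.p_Q):
            return self.p_Q
        return self.p_G


def inverse_normal_transform(values, offset: float = BLOM_OFFSET) -> np.ndarray:
    """Rank-based inverse normal transform Phi^-1((rank - c) / (n + 1 - 2c)).

    Uses the Blom offset c = 3/8 by default; ties receive average ranks, so
    the transform is order preserving.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("cannot inverse-normal transform an empty vector")
    if not np.isfinite(v).all():
        raise ValidationError("inverse normal transform requires finite values")
    ranks = stats.rankdata(v, method="average")
    n = v.size
    return stats.norm.ppf((ranks - offset) / (n + 1.0 - 2.0 * offset))


def unadjusted_marginal_effect(params: SimulationParams) -> float:
    """The genotype effect on CFB that baseline-unadjusted models actually test.

    Substituting the baseline model into the CFB model shows the marginal
    genotype effect is ``beta_G + beta_G0 * beta_y0``: even with no direct
    effect (beta_G = 0), a genotype associated with the baseline (beta_G0 != 0)
    carries a mediator effect on CFB whenever the baseline predicts CFB
    (beta_y0 != 0).
    """
    return params.beta_G + params.beta_G0 * params.beta_y0


def _extra_covariates(covariates) -> dict[str, np.ndarray]:
    if covariates is None:
        return {}
    if isinstance(covariates, pd.DataFrame):
        return {str(c): covariates[c].to_numpy(float) for c in covariates.columns}
    return {str(k): np.asarray(v, float) for k, v in dict(covariates).items()}


def _phenotype(cohort: Cohort, spec: ModelSpec) -> np.ndarray:
    return {
        "log_fold_cfb": cohort.log_fold_cfb,
        "cfb_ratio": cohort.cfb_ratio,
        "log_baseline": cohort.log_y0,
        "log_post": cohort.log_y1,
    }[spec.phenotype]


def _check_design(design: pd.DataFrame) -> None:
    for name in design.columns:
        if name != "intercept" and np.ptp(design[name].to_numpy()) == 0:
            raise DesignError(f"design column {name!r} is constant")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise DesignError(
            f"design matrix is rank deficient (columns: {list(design.columns)})"
        )


def _ols(y: np.ndarray, design: pd.DataFrame):
    return sm.OLS(y, design).fit()


def _is_monomorphic(g: np.ndarray) -> bool:
    return np.ptp(np.asarray(g, float)) == 0


def _degenerate_result(spec: ModelSpec, n: int) -> AssocResult:
    res = AssocResult(model_id=spec.id, n_used=n, df_resid=0, degenerate=True)
    res.p_G = 1.0
    if spec.test == "joint_2df":
        res.p_GT = 1.0
        res.p_2df = 1.0
    if spec.approach == "cochran_q":
        res.p_Q = 1.0
        res.q_stat = 0.0
    return res


def fit_two_step(
    cohort: Cohort,
    spec: ModelSpec,
    covariates=None,
    int_transform: bool = True,
    residualize_genotype: bool = False,
    int_offset: float = BLOM_OFFSET,
) -> AssocResult:
    """Two-step fit: covariate residuals (optionally INTed), then genotype.

    Step 1 regresses the phenotype on intercept + treatment + age (+ extra
    covariates + the baseline term for adjusted specs: ln y0, or raw y0 for
    the CFB-ratio model M4). Step 2 regresses the inverse-normal-transformed
    residuals on intercept + genotype; ``p_G`` is the two-sided t-test on the
    genotype coefficient.

    ``int_transform=False`` skips the INT; ``residualize_genotype=True``
    additionally residualizes the genotype on the same step-1 covariates
    (with ``int_transform=False`` this reproduces the one-step genotype
    coefficient exactly, by Frisch-Waugh-Lovell).
    """
    if spec.approach != "two_step_int":
        raise ValidationError(f"{spec.id} is not a two-step model")
    y = _phenotype(cohort, spec)
    cols = {"intercept": np.ones(len(cohort))}
    if spec.baseline_adjusted:
        cols["y0" if spec.baseline_scale == "raw" else "log_y0"] = (
            cohort.y0 if spec.baseline_scale == "raw" else cohort.log_y0
        )
    cols["treatment"] = cohort.treatment
    cols["age"] = cohort.age
    cols.update(_extra_covariates(covariates))
    design1 = pd.DataFrame(cols)
    _check_design(design1)

    resid = _ols(y, design1).resid.to_numpy()
    z = inverse_normal_transform(resid, offset=int_offset) if int_transform else resid

    g = cohort.genotype.astype(float)
    if _is_monomorphic(g):
        return _degenerate_result(spec, len(cohort))
    if residualize_genotype:
        g = _ols(g, design1).resid.to_numpy()

    design2 = pd.DataFrame({"intercept": np.ones(len(cohort)), "genotype": g})
    fit2 = _ols(z, design2)
    return AssocResult(
        model_id=spec.id,
        n_used=len(cohort),
        df_resid=int(fit2.df_resid),
        beta_G=float(fit2.params["genotype"]),
        se_G=float(fit2.bse["genotype"]),
        p_G=float(fit2.pvalues["genotype"]),
    )


def _one_step_design(cohort: Cohort, spec: ModelSpec, covariates) -> pd.DataFrame:
    cols = {"intercept": np.ones(len(cohort))}
    if spec.baseline_adjusted:
        cols["log_y0"] = cohort.log_y0
    if spec.test != "baseline_only":
        cols["treatment"] = cohort.treatment
    cols["genotype"] = cohort.genotype.astype(float)
    if spec.test == "joint_2df":
        cols["genotype_x_treatment"] = cohort.genotype * cohort.treatment
    cols["age"] = cohort.age
    cols.update(_extra_covariates(covariates))
    return pd.DataFrame(cols)


def fit_one_step(cohort: Cohort, spec: ModelSpec, covariates=None) -> AssocResult:
    """Single least-squares fit of the model formula.

    1df models report the two-sided t-test on the genotype coefficient; 2df
    models additionally report the interaction coefficient and a joint Wald
    chi-square (2 df) on (beta_G, beta_GT) using their estimated covariance.
    """
    if spec.approach != "one_step":
        raise ValidationError(f"{spec.id} is not a one-step model")
    g = cohort.genotype.astype(float)
    if _is_monomorphic(g):
        return _degenerate_result(spec, len(cohort))
    design = _one_step_design(cohort, spec, covariates)
    _check_design(design)
    fit = _ols(_phenotype(cohort, spec), design)

    res = AssocResult(
        model_id=spec.id,
        n_used=len(cohort),
        df_resid=int(fit.df_resid),
        beta_G=float(fit.params["genotype"]),
        se_G=float(fit.bse["genotype"]),
        p_G=float(fit.pvalues["genotype"]),
    )
    if spec.baseline_adjusted:
        res.beta_y0 = float(fit.params["log_y0"])
        res.se_y0 = float(fit.bse["log_y0"])
    if spec.test == "joint_2df":
        res.beta_GT = float(fit.params["genotype_x_treatment"])
        res.se_GT = float(fit.bse["genotype_x_treatment"])
        res.p_GT = float(fit.pvalues["genotype_x_treatment"])
        b = fit.params[["genotype", "genotype_x_treatment"]].to_numpy()
        cov = fit.cov_params().loc[
            ["genotype", "genotype_x_treatment"],
            ["genotype", "genotype_x_treatment"],
        ].to_numpy()
        wald = float(b @ np.linalg.solve(cov, b))
        res.p_2df = float(stats.chi2.sf(wald, df=2))
    return res


def cochran_q_from_estimates(
    beta_G0: float, beta_G1: float, s0_sq: float, s1_sq: float
) -> tuple[float, float]:
    """Cochran's Q from two genotype coefficients and their variances.

    Inverse-variance weighted heterogeneity statistic
    ``Q = sum_i w_i (b_i - b_bar)^2`` with ``w_i = 1/s_i^2`` and p-value from
    a chi-square with 1 degree of freedom.
    """
    w0, w1 = 1.0 / s0_sq, 1.0 / s1_sq
    b_bar = (w0 * beta_G0 + w1 * beta_G1) / (w0 + w1)
    q = w0 * (beta_G0 - b_bar) ** 2 + w1 * (beta_G1 - b_bar) ** 2
    return float(q), float(stats.chi2.sf(q, df=1))


def cochran_q(cohort: Cohort, covariates=None) -> AssocResult:
    """Cochran's Q heterogeneity test of the genotype coefficient between the
    baseline and post-treatment responses.

    Fits ``ln y_i ~ intercept + treatment + genotype + age`` separately for
    i = 0, 1 and compares the two genotype coefficients. The two coefficients
    share the baseline error and are positively correlated, which the
    independence-assuming chi-square reference ignores, so the test is
    conservative.
    """
    g = cohort.genotype.astype(float)
    spec = MODELS["Q"]
    if _is_monomorphic(g):
        return _degenerate_result(spec, len(cohort))
    cols = {
        "intercept": np.ones(len(cohort)),
        "treatment": cohort.treatment,
        "genotype": g,
        "age": cohort.age,
    }
    cols.update(_extra_covariates(covariates))
    design = pd.DataFrame(cols)
    _check_design(design)
    fit0 = _ols(cohort.log_y0, design)
    fit1 = _ols(cohort.log_y1, design)
    q, p = cochran_q_from_estimates(
        float(fit0.params["genotype"]),
        float(fit1.params["genotype"]),
        float(fit0.bse["genotype"]) ** 2,
        float(fit1.bse["genotype"]) ** 2,
    )
    return AssocResult(
        model_id="Q",
        n_used=len(cohort),
        df_resid=int(fit1.df_resid),
        q_stat=q,
        p_Q=p,
    )


def fit_model(cohort: Cohort, model, covariates=None, **kwargs) -> AssocResult:
    """Fit one of the twelve models by id (or ModelSpec) on a cohort."""
    spec = MODELS[model] if isinstance(model, str) else model
    if spec.approach == "two_step_int":
        return fit_two_step(cohort, spec, covariates=covariates, **kwargs)
    if spec.approach == "one_step":
        return fit_one_step(cohort, spec, covariates=covariates, **kwargs)
    if spec.approach == "cochran_q":
        return cochran_q(cohort, covariates=covariates, **kwargs)
    raise ValidationError(f"unknown approach {spec.approach!r}")


_TABLE_COLUMNS = [
    "variant_id",
    "model_id",
    "beta_y0",
    "beta_G",
    "se_G",
    "p_G",
    "beta_GT",
    "se_GT",
    "p_GT",
    "p_2df",
    "q_stat",
    "p_Q",
    "n_used",
    "degenerate",
]


def results_to_table(
    results: Sequence[AssocResult], variant_ids: Sequence[str] | None = None
) -> pd.DataFrame:
    """Serialize fit results to a tidy association table (one row per fit)."""
    if variant_ids is None:
        variant_ids = [""] * len(results)
    rows = []
    for vid, r in zip(variant_ids, results):
        rows.append(
            {
                "variant_id": vid,
                "model_id": r.model_id,
                "beta_y0": r.beta_y0,
                "beta_G": r.beta_G,
                "se_G": r.se_G,
                "p_G": r.p_G,
                "beta_GT": r.beta_GT,
                "se_GT": r.se_GT,
                "p_GT": r.p_GT,
                "p_2df": r.p_2df,
                "q_stat": r.q_stat,
                "p_Q": r.p_Q,
                "n_used": r.n_used,
                "degenerate": r.degenerate,
            }
        )
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)
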
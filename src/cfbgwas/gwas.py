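"""Per-variant model scans and genome-scan diagnostics.

Runs the analysis-model suite across a variant panel (synthetic or loaded)
and computes the scan-level diagnostics: genomic inflation factor lambda,
QQ-plot data with a null confidence band, and the mediator-enriched-subset
comparison — variants are filtered on the baseline-association p-value from
M7 (default threshold 1e-3) and lambda is recomputed per model on that
subset. On such a subset, baseline-unadjusted CFB models show inflation that
baseline-adjusted models do not, because the subset is enriched for variants
whose genotype-CFB association runs through the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import _batch
from .exceptions import AlignmentError, ValidationError
from .models import BLOM_OFFSET, MODELS, fit_model, results_to_table
from .simulate import VariantPanel

__all__ = [
    "GwasSummary",
    "run_gwas",
    "genomic_lambda",
    "mediator_subset",
    "qq_data",
    "GENOME_WIDE_SIGNIFICANCE",
]

#: Conventional genome-wide significance threshold for annotation.
GENOME_WIDE_SIGNIFICANCE = 5e-8

#: Median of the chi-square distribution with 1 df.
_CHI2_1_MEDIAN = stats.chi2.ppf(0.5, df=1)


@dataclass
class GwasSummary:
    """Association table plus scan diagnostics for one panel run."""

    table: pd.DataFrame  # one row per variant per model
    lambda_gc: dict[str, float]
    mediator_threshold: float | None = None
    mediator_subset: np.ndarray | None = None  # variant ids
    lambda_gc_subset: dict[str, float] = field(default_factory=dict)

    def pvalues(self, model_id: str, subset_ids=None) -> np.ndarray:
        sub = self.table[self.table["model_id"] == model_id]
        if subset_ids is not None:
            sub = sub[sub["variant_id"].isin(np.asarray(subset_ids))]
        spec = MODELS[model_id]
        col = "p_2df" if spec.test == "joint_2df" else ("p_Q" if spec.approach == "cochran_q" else "p_G")
        return sub[col].to_numpy()


def genomic_lambda(p_values) -> float:
    """Genomic inflation factor: median observed 1-df chi-square statistic
    over the null median (~0.455).

    p-values are mapped back to chi-square statistics through the quantile
    transform ``chi2_1^-1(1 - p)``; lambda ~ 1 indicates calibrated tests.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValidationError("genomic_lambda requires at least one p-value")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, df=1)
    return float(np.median(chi) / _CHI2_1_MEDIAN)


def mediator_subset(baseline_results, threshold: float = 1e-3) -> np.ndarray:
    """Variant ids whose baseline-association (M7) p-value is below threshold.

    ``baseline_results`` is an association table (as produced by
    :func:`run_gwas`) containing M7 rows, or any frame with ``variant_id``
    and ``p_G`` columns.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValidationError(f"threshold must be in (0, 1], got {threshold}")
    df = baseline_results
    if "model_id" in df.columns and (df["model_id"] == "M7").any():
        df = df[df["model_id"] == "M7"]
    return df.loc[df["p_G"] < threshold, "variant_id"].to_numpy()


def qq_data(p_values) -> pd.DataFrame:
    """Expected vs observed -log10(p) with a pointwise 95% null band.

    The k-th smallest of m uniform p-values follows Beta(k, m + 1 - k); the
    expected value is k / (m + 1) and the band is that Beta's 2.5%/97.5%
    quantiles, all on the -log10 scale.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValidationError("qq_data requires at least one p-value")
    m = p.size
    k = np.arange(1, m + 1)
    obs = -np.log10(np.sort(p))
    expected = -np.log10(k / (m + 1.0))
    lower = -np.log10(stats.beta.ppf(0.975, k, m + 1.0 - k))
    upper = -np.log10(stats.beta.ppf(0.025, k, m + 1.0 - k))
    return pd.DataFrame(
        {"expected": expected, "observed": obs, "lower": lower, "upper": upper}
    )


def _panel_from_tables(genotypes: pd.DataFrame, phenotypes: pd.DataFrame) -> VariantPanel:
    """Build a shared-phenotype panel from aligned genotype/phenotype tables."""
    pheno = phenotypes.set_index("subject_id") if "subject_id" in phenotypes.columns else phenotypes
    geno = genotypes
    if set(geno.index) != set(pheno.index):
        missing = sorted(set(geno.index) ^ set(pheno.index))[:5]
        raise AlignmentError(
            f"genotype and phenotype tables disagree on subject ids (e.g. {missing})"
        )
    geno = geno.loc[pheno.index]
    truth = pd.DataFrame({"variant_id": geno.columns.astype(str)})
    return VariantPanel(
        genotypes=geno.to_numpy(float),
        variant_truth=truth,
        treatment=pheno["treatment"].to_numpy(float),
        age=pheno["age"].to_numpy(float),
        y0=pheno["y0"].to_numpy(float),
        y1=pheno["y1"].to_numpy(float),
        rule="loaded",
        subject_id=pheno.index.to_numpy(),
    )


def _batch_arrays_for(panel: VariantPanel, j0: int, j1: int, covariates) -> dict:
    """Stack variants j0:j1 of a panel as a (V, n) replicate batch."""
    G = panel.genotypes[:, j0:j1].T
    shape = G.shape
    per_variant = panel.y0.ndim == 2
    lny0 = np.log(panel.y0[:, j0:j1].T if per_variant else panel.y0)
    lny1 = np.log(panel.y1[:, j0:j1].T if per_variant else panel.y1)
    arrs = {
        "G": G,
        "T": np.broadcast_to(panel.treatment, shape),
        "X": np.broadcast_to(panel.age, shape),
        "lny0": np.broadcast_to(lny0, shape),
        "lny1": np.broadcast_to(lny1, shape),
    }
    if covariates is not None:
        arrs["extra"] = {
            str(k): np.asarray(v, float) for k, v in dict(covariates).items()
        }
    return arrs


_RESULT_KEYS = ("beta_y0", "beta_G", "se_G", "p_G", "beta_GT", "se_GT", "p_GT",
                "p_2df", "q_stat", "p_Q")


def run_gwas(
    panel: VariantPanel | None = None,
    models: Sequence[str] = ("M1", "M3", "M7"),
    covariates=None,
    genotypes: pd.DataFrame | None = None,
    phenotypes: pd.DataFrame | None = None,
    mediator_threshold: float | None = 1e-3,
    chunk_variants: int = 512,
    int_offset: float = BLOM_OFFSET,
    engine: str = "batch",
) -> GwasSummary:
    """Fit the requested models to every variant of a panel.

    Either a :class:`VariantPanel` or a pair of aligned ``genotypes``
    (subjects x variants, indexed by subject id) and ``phenotypes`` tables is
    accepted. Monomorphic variants are flagged with p = 1 rather than
    aborting the scan. When ``mediator_threshold`` is set and M7 is among the
    models, the summary also reports each model's lambda restricted to the
    M7-filtered (baseline-associated) variant subset.

    The output is deterministic given the inputs and invariant to variant
    ordering and to ``chunk_variants``.
    """
    if panel is None:
        if genotypes is None or phenotypes is None:
            raise ValidationError("provide a panel or genotypes + phenotypes tables")
        panel = _panel_from_tables(genotypes, phenotypes)
    for m in models:
        if m not in MODELS:
            raise ValidationError(f"unknown model id {m!r}")

    vids = panel.variant_ids.astype(str)
    n_var = panel.n_variants
    mono = np.ptp(panel.genotypes, axis=0) == 0

    if engine == "reference":
        rows = []
        for j in range(n_var):
            cohort = panel.cohort_for(j)
            for m in models:
                rows.append((vids[j], fit_model(cohort, m, covariates=covariates)))
        table = results_to_table([r for _, r in rows], [v for v, _ in rows])
    else:
        per_model: dict[str, dict[str, np.ndarray]] = {
            m: {k: np.full(n_var, np.nan) for k in _RESULT_KEYS} for m in models
        }
        for j0 in range(0, n_var, chunk_variants):
            j1 = min(j0 + chunk_variants, n_var)
            keep = ~mono[j0:j1]
            arrs = _batch_arrays_for(panel, j0, j1, covariates)
            if not keep.all():
                arrs = {
                    k: ({kk: vv for kk, vv in v.items()} if k == "extra" else v[keep])
                    for k, v in arrs.items()
                }
            for m in models:
                fit = _batch.batch_fit_model(m, arrs, int_offset=int_offset)
                idx = np.arange(j0, j1)[keep]
                for key, val in fit.items():
                    if key in per_model[m]:
                        per_model[m][key][idx] = val
        rows = []
        for m in models:
            spec = MODELS[m]
            df = pd.DataFrame(per_model[m])
            df.insert(0, "model_id", m)
            df.insert(0, "variant_id", vids)
            df["n_used"] = panel.n_subjects
            df["degenerate"] = mono
            if spec.approach == "cochran_q":
                df.loc[mono, "p_Q"] = 1.0
            elif spec.test == "joint_2df":
                df.loc[mono, ["p_G", "p_GT", "p_2df"]] = 1.0
            else:
                df.loc[mono, "p_G"] = 1.0
            rows.append(df)
        table = pd.concat(rows, ignore_index=True)

    lambdas = {}
    for m in models:
        spec = MODELS[m]
        col = "p_2df" if spec.test == "joint_2df" else ("p_Q" if spec.approach == "cochran_q" else "p_G")
        p = table.loc[table["model_id"] == m, col].to_numpy(float)
        lambdas[m] = genomic_lambda(p[np.isfinite(p)])

    summary = GwasSummary(table=table, lambda_gc=lambdas)
    if mediator_threshold is not None and "M7" in models:
        subset = mediator_subset(table, threshold=mediator_threshold)
        summary.mediator_threshold = mediator_threshold
        summary.mediator_subset = subset
        if subset.size:
            for m in models:
                p = summary.pvalues(m, subset_ids=subset)
                p = p[np.isfinite(p)]
                if p.size:
                    summary.lambda_gc_subset[m] = genomic_lambda(p)
    return summary
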
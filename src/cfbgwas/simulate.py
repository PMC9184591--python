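"""Synthetic cohorts and variant panels for change-from-baseline PGx GWAS.

The generative model has a pre-treatment (baseline) response ``y0`` and a
post-treatment response ``y1``, both positive, simulated on the log scale:

    ln y0       = b0 + beta_G0 * G + eps0
    ln y1 - ln y0 = beta_T * T + beta_X * X + beta_y0 * ln y0
                    + beta_G * G + beta_GT * G * T + eps1

with treatment arm T ~ Bernoulli(treatment_prob), age X ~ Uniform(18, 65),
genotype G ~ Binomial(2, MAF) allele counts, and independent normal errors.
``beta_G0 * beta_y0`` is the mediator effect: genotype influences the change
from baseline (CFB) indirectly through the baseline value. Baseline-unadjusted
analysis models test ``beta_G + beta_G0 * beta_y0`` rather than ``beta_G``,
which is what drives their type I error inflation.

Observed responses may additionally carry multiplicative measurement error
``(1 + r) * y`` with relative error ``r ~ N(mu, sigma^2)``. Responses are
floored at 1 so the log transform is always defined.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "RESPONSE_FLOOR",
    "SimulationParams",
    "MeasurementErrorConfig",
    "Cohort",
    "PanelComposition",
    "VariantPanel",
    "simulate_cohort",
    "apply_measurement_error",
    "simulate_panel",
    "genotypes_from_vcf",
]

#: Lower truncation bound applied to every simulated response on the natural
#: scale, so that ln(y) is defined even in the rare far-left tail.
RESPONSE_FLOOR = 1.0


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SimulationParams:
    """Generative coefficients and cohort dimensions.

    Defaults reproduce the reference simulation setting: n=1000, MAF=0.2,
    log-baseline intercept 4.6, treatment effect -0.25, age effect -0.01,
    standard-normal errors.
    """

    n_subjects: int = 1000
    maf: float = 0.2
    beta_G0: float = 0.0
    beta_y0: float = 0.0
    beta_G: float = 0.0
    beta_GT: float = 0.0
    intercept_baseline: float = 4.6
    beta_T: float = -0.25
    beta_X: float = -0.01
    treatment_prob: float = 0.5
    age_range: tuple[float, float] = (18.0, 65.0)
    sd_eps0: float = 1.0
    sd_eps1: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValidationError(f"maf must be in (0, 0.5], got {self.maf}")
        if self.n_subjects < 2:
            raise ValidationError(f"n_subjects must be >= 2, got {self.n_subjects}")
        if self.sd_eps0 <= 0 or self.sd_eps1 <= 0:
            raise ValidationError("sd_eps0 and sd_eps1 must be positive")
        if not (0.0 < self.treatment_prob < 1.0):
            raise ValidationError(
                f"treatment_prob must be in (0, 1), got {self.treatment_prob}"
            )
        if not self.age_range[0] < self.age_range[1]:
            raise ValidationError(f"age_range must be increasing, got {self.age_range}")

    def mediator_effect(self) -> float:
        """The indirect genotype-on-CFB effect routed through the baseline."""
        return self.beta_G0 * self.beta_y0


@dataclass(frozen=True)
class MeasurementErrorConfig:
    """Multiplicative relative measurement error on observed responses.

    Observed values are ``max(floor, (1 + r_i) * y_i)`` with
    ``r_i ~ N(mu_i, sigma^2)`` drawn independently per subject and time point.
    The three named presets: ``white`` (mu0=mu1=0), ``same`` (mu0=mu1=0.25,
    biased in the same direction) and ``opposite`` (mu0=-0.25, mu1=0.25).
    """

    mu0: float = 0.0
    mu1: float = 0.0
    sigma: float = 0.25
    floor: float = RESPONSE_FLOOR
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValidationError(f"sigma must be >= 0, got {self.sigma}")
        if self.floor <= 0:
            raise ValidationError(f"floor must be > 0, got {self.floor}")

    PRESETS = {
        "none": dict(mu0=0.0, mu1=0.0, sigma=0.0, enabled=False),
        "white": dict(mu0=0.0, mu1=0.0),
        "same": dict(mu0=0.25, mu1=0.25),
        "opposite": dict(mu0=-0.25, mu1=0.25),
    }

    @classmethod
    def preset(cls, name: str) -> "MeasurementErrorConfig":
        try:
            return cls(**cls.PRESETS[name])
        except KeyError:
            raise ValidationError(
                f"unknown measurement-error preset {name!r}; "
                f"choose from {sorted(cls.PRESETS)}"
            ) from None


@dataclass
class Cohort:
    """One simulated (or loaded) subject table.

    Responses are stored on the natural scale and are strictly positive; the
    log-scale views used by the analysis models are provided as properties.
    """

    y0: np.ndarray
    y1: np.ndarray
    treatment: np.ndarray
    age: np.ndarray
    genotype: np.ndarray
    truth: SimulationParams | None = None
    subject_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        arrays = [self.y0, self.y1, self.treatment, self.age, self.genotype]
        n = len(self.y0)
        if any(len(a) != n for a in arrays):
            raise ValidationError("all cohort vectors must have identical length")
        if np.any(self.y0 <= 0) or np.any(self.y1 <= 0):
            raise ValidationError("responses must be positive for log transforms")
        if not np.isin(self.genotype, (0, 1, 2)).all():
            raise ValidationError("genotype must be allele counts in {0, 1, 2}")
        if self.subject_id is None:
            self.subject_id = np.arange(1, n + 1)

    def __len__(self) -> int:
        return len(self.y0)

    @property
    def log_y0(self) -> np.ndarray:
        return np.log(self.y0)

    @property
    def log_y1(self) -> np.ndarray:
        return np.log(self.y1)

    @property
    def log_fold_cfb(self) -> np.ndarray:
        """ln(y1) - ln(y0), the log-fold change from baseline."""
        return self.log_y1 - self.log_y0

    @property
    def cfb_ratio(self) -> np.ndarray:
        """(y1 - y0) / y0, the percent-change phenotype."""
        return (self.y1 - self.y0) / self.y0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "y0": self.y0,
                "y1": self.y1,
                "treatment": self.treatment.astype(int),
                "age": self.age,
                "genotype": self.genotype.astype(int),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, truth: SimulationParams | None = None) -> "Cohort":
        cols = set(df.columns)
        if "genotype" in cols:
            g = df["genotype"].to_numpy()
        else:
            g_cols = [c for c in df.columns if c.startswith("g_")]
            if len(g_cols) != 1:
                raise ValidationError(
                    "expected a 'genotype' column or exactly one 'g_<id>' column"
                )
            g = df[g_cols[0]].to_numpy()
        return cls(
            y0=df["y0"].to_numpy(float),
            y1=df["y1"].to_numpy(float),
            treatment=df["treatment"].to_numpy(float),
            age=df["age"].to_numpy(float),
            genotype=g.astype(float),
            truth=truth,
            subject_id=df["subject_id"].to_numpy() if "subject_id" in cols else None,
        )

    def to_tsv(self, path, write_truth: bool = True) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        if write_truth and self.truth is not None:
            side = path.with_suffix(path.suffix + ".truth.json")
            side.write_text(json.dumps(asdict(self.truth), indent=1))

    @classmethod
    def from_tsv(cls, path) -> "Cohort":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        truth = None
        side = path.with_suffix(path.suffix + ".truth.json")
        if side.exists():
            d = json.loads(side.read_text())
            d["age_range"] = tuple(d["age_range"])
            truth = SimulationParams(**d)
        return cls.from_frame(df, truth=truth)


def _draw_core(
    params: SimulationParams, rng: np.random.Generator, n_reps: int
) -> dict[str, np.ndarray]:
    """Draw (n_reps, n_subjects) arrays of the generative model on the log scale.

    Shared by the single-cohort path and the vectorized replicate engine so the
    two are distributionally identical by construction. Draw order is fixed:
    G, T, X, eps0, eps1.
    """
    p = params
    shape = (n_reps, p.n_subjects)
    G = rng.binomial(2, p.maf, size=shape).astype(float)
    T = (rng.random(size=shape) < p.treatment_prob).astype(float)
    X = rng.uniform(p.age_range[0], p.age_range[1], size=shape)
    eps0 = rng.normal(0.0, p.sd_eps0, size=shape)
    eps1 = rng.normal(0.0, p.sd_eps1, size=shape)

    log_floor = math.log(RESPONSE_FLOOR)
    lny0 = p.intercept_baseline + p.beta_G0 * G + eps0
    np.maximum(lny0, log_floor, out=lny0)
    cfb = (
        p.beta_T * T
        + p.beta_X * X
        + p.beta_y0 * lny0
        + p.beta_G * G
        + p.beta_GT * G * T
        + eps1
    )
    lny1 = np.maximum(lny0 + cfb, log_floor)
    return {"G": G, "T": T, "X": X, "lny0": lny0, "lny1": lny1}


def simulate_cohort(params: SimulationParams, rng=None) -> Cohort:
    """Simulate one cohort from the generative model.

    Deterministic for a fixed ``params.seed`` (or an explicitly passed ``rng``,
    which takes precedence).
    """
    rng = _as_rng(params.seed if rng is None else rng)
    a = _draw_core(params, rng, 1)
    return Cohort(
        y0=np.exp(a["lny0"][0]),
        y1=np.exp(a["lny1"][0]),
        treatment=a["T"][0],
        age=a["X"][0],
        genotype=a["G"][0],
        truth=params,
    )


def _corrupt_logs(
    lny0: np.ndarray,
    lny1: np.ndarray,
    config: MeasurementErrorConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply multiplicative measurement error on the log scale, with flooring.

    Relative-error factors (1 + r) that fall at or below zero would make the
    observed response non-positive; the floor rule maps those to the floor.
    """
    if not config.enabled or (
        config.sigma == 0 and config.mu0 == 0 and config.mu1 == 0
    ):
        return lny0, lny1
    log_floor = math.log(config.floor)
    r0 = rng.normal(config.mu0, config.sigma, size=lny0.shape)
    r1 = rng.normal(config.mu1, config.sigma, size=lny1.shape)
    with np.errstate(divide="ignore"):
        obs0 = lny0 + np.log1p(np.maximum(r0, -1.0))  # -inf where 1+r <= 0
        obs1 = lny1 + np.log1p(np.maximum(r1, -1.0))
    return np.maximum(obs0, log_floor), np.maximum(obs1, log_floor)


def apply_measurement_error(
    cohort: Cohort, config: MeasurementErrorConfig, rng=None
) -> Cohort:
    """Return a new cohort with observed responses ``max(floor, (1+r_i)*y_i)``.

    The input cohort is not modified. ``rng`` may be a seed or Generator; the
    two relative-error vectors are drawn independently per subject.
    """
    if not config.enabled:
        return replace(cohort)
    rng = _as_rng(rng)
    lny0, lny1 = _corrupt_logs(
        cohort.log_y0[None, :], cohort.log_y1[None, :], config, rng
    )
    return Cohort(
        y0=np.exp(lny0[0]),
        y1=np.exp(lny1[0]),
        treatment=cohort.treatment.copy(),
        age=cohort.age.copy(),
        genotype=cohort.genotype.copy(),
        truth=cohort.truth,
        subject_id=cohort.subject_id.copy(),
    )


# ---------------------------------------------------------------------------
# Multi-variant panels


@dataclass(frozen=True)
class PanelComposition:
    """Variant-class mix for a synthetic panel.

    Fractions must sum to 1. ``baseline`` variants affect only the baseline
    (beta_G0 != 0, so with beta_y0 != 0 they carry a pure mediator effect on
    CFB), ``cfb`` variants have a direct main effect, ``interaction`` variants
    a genotype-by-treatment effect, and ``null`` variants none.
    """

    frac_baseline: float = 0.0
    frac_cfb: float = 0.0
    frac_interaction: float = 0.0
    frac_null: float = 1.0
    beta_G0: float = 0.1
    beta_y0: float = -0.2
    beta_G: float = 0.2
    beta_GT: float = 0.2
    rule: Literal["single_causal", "additive"] = "single_causal"

    def __post_init__(self) -> None:
        fracs = (
            self.frac_baseline,
            self.frac_cfb,
            self.frac_interaction,
            self.frac_null,
        )
        if any(f < 0 for f in fracs) or not math.isclose(sum(fracs), 1.0, abs_tol=1e-9):
            raise ValidationError(f"variant-class fractions must sum to 1, got {fracs}")
        if self.rule not in ("single_causal", "additive"):
            raise ValidationError(f"unknown composition rule {self.rule!r}")


@dataclass
class VariantPanel:
    """A subjects x variants genotype matrix with per-variant effect truth.

    Under the ``single_causal`` rule each variant has its own phenotype
    replicate generated from its own truth tuple (``y0``/``y1`` are
    subjects x variants matrices); under ``additive`` a single shared phenotype
    sums all causal effects (``y0``/``y1`` are vectors).
    """

    genotypes: np.ndarray  # (n_subjects, n_variants)
    variant_truth: pd.DataFrame  # columns: variant_id, maf, beta_G0, beta_y0, beta_G, beta_GT, category
    treatment: np.ndarray
    age: np.ndarray
    y0: np.ndarray  # (n,) shared or (n, n_variants) per-variant
    y1: np.ndarray
    rule: str = "single_causal"
    subject_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.subject_id is None:
            self.subject_id = np.arange(1, self.genotypes.shape[0] + 1)

    @property
    def n_subjects(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def variant_ids(self) -> np.ndarray:
        return self.variant_truth["variant_id"].to_numpy()

    def cohort_for(self, j: int) -> Cohort:
        """The single-variant cohort seen by variant index ``j``."""
        per_variant = self.y0.ndim == 2
        return Cohort(
            y0=self.y0[:, j] if per_variant else self.y0,
            y1=self.y1[:, j] if per_variant else self.y1,
            treatment=self.treatment,
            age=self.age,
            genotype=self.genotypes[:, j],
            subject_id=self.subject_id,
        )

    def to_tsv(self, path, write_truth: bool = True) -> None:
        path = Path(path)
        if self.y0.ndim == 2:
            # per-variant phenotypes cannot be flattened into one table; the
            # shared columns store the first variant's phenotype replicate
            y0, y1 = self.y0[:, 0], self.y1[:, 0]
        else:
            y0, y1 = self.y0, self.y1
        df = pd.DataFrame(
            {"subject_id": self.subject_id, "y0": y0, "y1": y1,
             "treatment": self.treatment.astype(int), "age": self.age}
        )
        for j, vid in enumerate(self.variant_ids):
            df[f"g_{vid}"] = self.genotypes[:, j].astype(int)
        df.to_csv(path, sep="\t", index=False)
        if write_truth:
            side = path.with_suffix(path.suffix + ".truth.json")
            side.write_text(self.variant_truth.to_json(orient="records"))


def simulate_panel(
    n_subjects: int,
    n_variants: int,
    composition: PanelComposition,
    seed,
    maf: float = 0.2,
    params_base: SimulationParams | None = None,
) -> VariantPanel:
    """Simulate a multi-variant panel under a variant-class composition rule.

    ``single_causal`` (default): each variant is paired with a phenotype
    replicate generated from that variant's own truth tuple with fresh noise —
    the one-variant-at-a-time design of the type-I-error simulations.
    ``additive``: one shared phenotype sums the contributions of every causal
    variant. Treatment and age are shared across variants in both rules.

    A master seed spawns independent child streams (class assignment, shared
    covariates, per-variant noise) so results are reproducible and invariant
    to execution order.
    """
    if params_base is None:
        params_base = SimulationParams(n_subjects=n_subjects, maf=maf)
    p = params_base
    comp = composition
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    ss_assign, ss_shared, ss_noise = ss.spawn(3)

    counts = np.floor(
        np.array([comp.frac_baseline, comp.frac_cfb, comp.frac_interaction])
        * n_variants
    ).astype(int)
    n_null = n_variants - counts.sum()
    categories = np.concatenate(
        [
            np.repeat("baseline", counts[0]),
            np.repeat("cfb", counts[1]),
            np.repeat("interaction", counts[2]),
            np.repeat("null", n_null),
        ]
    )
    np.random.default_rng(ss_assign).shuffle(categories)

    is_base = categories == "baseline"
    is_cfb = categories == "cfb"
    is_int = categories == "interaction"
    beta_G0 = np.where(is_base, comp.beta_G0, 0.0)
    beta_y0 = np.full(n_variants, comp.beta_y0)
    beta_G = np.where(is_cfb, comp.beta_G, 0.0)
    beta_GT = np.where(is_int, comp.beta_GT, 0.0)

    rng_shared = np.random.default_rng(ss_shared)
    G = rng_shared.binomial(2, maf, size=(n_subjects, n_variants)).astype(float)
    T = (rng_shared.random(n_subjects) < p.treatment_prob).astype(float)
    X = rng_shared.uniform(p.age_range[0], p.age_range[1], size=n_subjects)

    rng_noise = np.random.default_rng(ss_noise)
    log_floor = math.log(RESPONSE_FLOOR)

    if comp.rule == "single_causal":
        eps0 = rng_noise.normal(0.0, p.sd_eps0, size=(n_subjects, n_variants))
        eps1 = rng_noise.normal(0.0, p.sd_eps1, size=(n_subjects, n_variants))
        lny0 = p.intercept_baseline + beta_G0[None, :] * G + eps0
        np.maximum(lny0, log_floor, out=lny0)
        cfb = (
            p.beta_T * T[:, None]
            + p.beta_X * X[:, None]
            + beta_y0[None, :] * lny0
            + beta_G[None, :] * G
            + beta_GT[None, :] * G * T[:, None]
            + eps1
        )
        lny1 = np.maximum(lny0 + cfb, log_floor)
        y0, y1 = np.exp(lny0), np.exp(lny1)
    else:  # additive: one shared phenotype summing all causal contributions
        eps0 = rng_noise.normal(0.0, p.sd_eps0, size=n_subjects)
        eps1 = rng_noise.normal(0.0, p.sd_eps1, size=n_subjects)
        lny0 = p.intercept_baseline + G @ beta_G0 + eps0
        np.maximum(lny0, log_floor, out=lny0)
        cfb = (
            p.beta_T * T
            + p.beta_X * X
            + comp.beta_y0 * lny0
            + G @ beta_G
            + (G * T[:, None]) @ beta_GT
            + eps1
        )
        lny1 = np.maximum(lny0 + cfb, log_floor)
        y0, y1 = np.exp(lny0), np.exp(lny1)

    truth = pd.DataFrame(
        {
            "variant_id": [f"v{j + 1}" for j in range(n_variants)],
            "maf": maf,
            "beta_G0": beta_G0,
            "beta_y0": beta_y0,
            "beta_G": beta_G,
            "beta_GT": beta_GT,
            "category": categories,
        }
    )
    return VariantPanel(
        genotypes=G, variant_truth=truth, treatment=T, age=X, y0=y0, y1=y1,
        rule=comp.rule,
    )


def genotypes_from_vcf(path) -> pd.DataFrame:
    """Read alternate-allele dosages from a VCF into a subjects x variants table.

    Diploid, autosomal, unphased biallelic records; dosage is the count of
    alternate alleles (0/1/2). Requires cyvcf2.
    """
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path), gts012=True)  # gt_types -> 0/1/2 alt-allele counts
    samples = list(vcf.samples)
    ids, cols = [], []
    for rec in vcf:
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        ids.append(vid)
        dosage = np.asarray(rec.gt_types, dtype=float)
        cols.append(dosage)
    geno = pd.DataFrame(np.column_stack(cols) if cols else np.empty((len(samples), 0)),
                        index=samples, columns=ids)
    return geno
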
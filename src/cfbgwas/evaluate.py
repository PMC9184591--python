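"""Monte-Carlo estimation of empirical type I error and power.

For each cell of a parameter grid, replicate cohorts are simulated from the
generative model, the requested analysis models are fitted to every replicate,
and the empirical rejection rate at each nominal level alpha is the proportion
of rejection p-values below alpha. Under a null cell (beta_G = beta_GT = 0)
the rate is the empirical type I error; under an alternative it is power.

The Monte-Carlo standard error of an empirical type I error is
``sqrt(alpha * (1 - alpha) / n_reps)`` (computed from the nominal alpha), and
a cell/model/alpha combination is flagged inflated when the empirical rate
exceeds ``alpha + 3 * mc_se`` — equivalently, when rate/alpha exceeds the
inflation threshold ``1 + 3 * mc_se / alpha``.

Replicate fitting is vectorized through :mod:`cfbgwas._batch`; a slow
reference engine (one statsmodels fit per replicate) consumes the same random
draws and is used to validate the fast path. A master seed spawns one child
stream per fixed-size chunk of replicates, so results are independent of the
number of parallel workers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import _batch
from .exceptions import ValidationError
from .models import BLOM_OFFSET, MODELS, fit_model
from .simulate import (
    Cohort,
    MeasurementErrorConfig,
    SimulationParams,
    _corrupt_logs,
    _draw_core,
)

__all__ = [
    "EvalGrid",
    "simulate_pvalues",
    "estimate_rates",
    "inflation_threshold",
    "compare_power",
]

DEFAULT_ALPHAS = (0.05, 1e-2, 1e-3, 1e-4)


@dataclass(frozen=True)
class EvalGrid:
    """A parameter x alpha evaluation grid.

    ``chunk_size`` fixes the replicate chunking (and hence the random stream
    layout); results are invariant to ``n_jobs`` but not to ``chunk_size``.
    """

    params_list: tuple[SimulationParams, ...]
    alpha_levels: tuple[float, ...] = DEFAULT_ALPHAS
    n_reps: int = 10_000
    error_config: MeasurementErrorConfig | None = None
    models: tuple[str, ...] = ("M1", "M3")
    seed: int = 0
    chunk_size: int = 1000
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if isinstance(self.params_list, SimulationParams):
            object.__setattr__(self, "params_list", (self.params_list,))
        object.__setattr__(self, "params_list", tuple(self.params_list))
        object.__setattr__(self, "alpha_levels", tuple(self.alpha_levels))
        object.__setattr__(self, "models", tuple(self.models))
        if any(not (0.0 < a < 1.0) for a in self.alpha_levels):
            raise ValidationError("alpha levels must lie in (0, 1)")
        if self.n_reps < 1:
            raise ValidationError("n_reps must be >= 1")
        unknown = set(self.models) - set(MODELS)
        if unknown:
            raise ValidationError(f"unknown model ids: {sorted(unknown)}")


def inflation_threshold(alpha: float, n_reps: int) -> float:
    """The rate/alpha ratio above which an empirical type I error is flagged
    inflated: ``1 + 3 * sqrt(alpha * (1 - alpha) / n_reps) / alpha``."""
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    if n_reps < 1:
        raise ValidationError(f"n_reps must be >= 1, got {n_reps}")
    return 1.0 + 3.0 * math.sqrt(alpha * (1.0 - alpha) / n_reps) / alpha


def _chunk_arrays(
    params: SimulationParams,
    n_chunk: int,
    child_ss: np.random.SeedSequence,
    error_config: MeasurementErrorConfig | None,
) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(child_ss)
    arrs = _draw_core(params, rng, n_chunk)
    if error_config is not None and error_config.enabled:
        arrs["lny0"], arrs["lny1"] = _corrupt_logs(
            arrs["lny0"], arrs["lny1"], error_config, rng
        )
    return arrs


def _fit_chunk_batch(models, arrs, int_offset):
    return {m: _batch.batch_fit_model(m, arrs, int_offset=int_offset) for m in models}


def _fit_chunk_reference(models, arrs, int_offset):
    """Reference engine: one statsmodels fit per replicate, same draws."""
    n_chunk = arrs["G"].shape[0]
    out = {m: {} for m in models}
    for i in range(n_chunk):
        cohort = Cohort(
            y0=np.exp(arrs["lny0"][i]),
            y1=np.exp(arrs["lny1"][i]),
            treatment=arrs["T"][i],
            age=arrs["X"][i],
            genotype=arrs["G"][i],
        )
        for m in models:
            kwargs = {"int_offset": int_offset} if MODELS[m].approach == "two_step_int" else {}
            r = fit_model(cohort, m, **kwargs)
            rec = out[m]
            for key in ("beta_G", "se_G", "p_G", "beta_GT", "se_GT", "p_GT",
                        "p_2df", "q_stat", "p_Q"):
                rec.setdefault(key, []).append(getattr(r, key))
    cleaned = {}
    for m, rec in out.items():
        cleaned[m] = {
            k: np.asarray(v) for k, v in rec.items() if not np.isnan(v).all()
        }
    return cleaned


def simulate_pvalues(
    params: SimulationParams,
    models: Sequence[str],
    n_reps: int,
    error_config: MeasurementErrorConfig | None = None,
    seed=0,
    chunk_size: int = 1000,
    n_jobs: int = 1,
    int_offset: float = BLOM_OFFSET,
    engine: str = "batch",
) -> dict[str, dict[str, np.ndarray]]:
    """Simulate ``n_reps`` replicate cohorts and fit each requested model.

    Returns ``{model_id: {"p_G": array, ...}}`` with one entry per replicate.
    All models see the same replicates, so cross-model comparisons are paired.
    """
    if engine not in ("batch", "reference"):
        raise ValidationError(f"unknown engine {engine!r}")
    fitter = _fit_chunk_batch if engine == "batch" else _fit_chunk_reference
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    n_chunks = -(-n_reps // chunk_size)
    children = ss.spawn(n_chunks)
    sizes = [min(chunk_size, n_reps - i * chunk_size) for i in range(n_chunks)]

    def work(child, size):
        arrs = _chunk_arrays(params, size, child, error_config)
        return fitter(tuple(models), arrs, int_offset)

    if n_jobs == 1:
        parts = [work(c, s) for c, s in zip(children, sizes)]
    else:
        parts = Parallel(n_jobs=n_jobs)(
            delayed(work)(c, s) for c, s in zip(children, sizes)
        )
    out: dict[str, dict[str, np.ndarray]] = {}
    for m in models:
        keys = parts[0][m].keys()
        out[m] = {k: np.concatenate([p[m][k] for p in parts]) for k in keys}
    return out


def _rejection_p(fits: dict[str, dict[str, np.ndarray]], model: str) -> np.ndarray:
    return _batch.primary_pvalues(fits[model], model)


_CELL_COLUMNS = ("beta_G0", "beta_y0", "beta_G", "beta_GT")


def estimate_rates(grid: EvalGrid) -> pd.DataFrame:
    """Empirical rejection rates over the grid's cells x models x alphas.

    Returns a tidy frame with one row per (cell, model, alpha): the cell's
    effect sizes, the empirical rate, its nominal-alpha Monte-Carlo standard
    error, the rate/alpha ratio, the inflation flag (rate > alpha + 3 mc_se),
    and the count of replicates whose fit produced no usable p-value.
    """
    rows = []
    ss = np.random.SeedSequence(grid.seed)
    cell_seeds = ss.spawn(len(grid.params_list))
    for params, cell_ss in zip(grid.params_list, cell_seeds):
        fits = simulate_pvalues(
            params,
            grid.models,
            grid.n_reps,
            error_config=grid.error_config,
            seed=cell_ss,
            chunk_size=grid.chunk_size,
            n_jobs=grid.n_jobs,
        )
        for m in grid.models:
            p = _rejection_p(fits, m)
            n_failed = int(np.isnan(p).sum())
            for alpha in grid.alpha_levels:
                rate = float(np.mean(p < alpha))
                mc_se = math.sqrt(alpha * (1.0 - alpha) / grid.n_reps)
                rows.append(
                    {
                        **{c: getattr(params, c) for c in _CELL_COLUMNS},
                        "model": m,
                        "alpha": alpha,
                        "n_reps": grid.n_reps,
                        "rate": rate,
                        "mc_se": mc_se,
                        "ratio": rate / alpha,
                        "inflated": rate > alpha + 3.0 * mc_se,
                        "n_failed": n_failed,
                    }
                )
    return pd.DataFrame(rows)


def compare_power(
    grid: EvalGrid,
    adjusted_model: str = "M1",
    unadjusted_model: str = "M3",
    alpha: float = 1e-6,
) -> pd.DataFrame:
    """Paired power comparison of two models on shared replicates.

    Power is the empirical rejection rate at the fixed nominal ``alpha``
    (not adjusted for any type-I inflation of either model). The paired
    Monte-Carlo standard error comes from the per-replicate difference of
    rejection indicators, which is far smaller than the unpaired binomial se
    when the two models' p-values are highly correlated.
    """
    rows = []
    ss = np.random.SeedSequence(grid.seed)
    cell_seeds = ss.spawn(len(grid.params_list))
    for params, cell_ss in zip(grid.params_list, cell_seeds):
        fits = simulate_pvalues(
            params,
            (adjusted_model, unadjusted_model),
            grid.n_reps,
            error_config=grid.error_config,
            seed=cell_ss,
            chunk_size=grid.chunk_size,
            n_jobs=grid.n_jobs,
        )
        rej_a = _rejection_p(fits, adjusted_model) < alpha
        rej_u = _rejection_p(fits, unadjusted_model) < alpha
        d = rej_a.astype(float) - rej_u.astype(float)
        rows.append(
            {
                **{c: getattr(params, c) for c in _CELL_COLUMNS},
                "alpha": alpha,
                "n_reps": grid.n_reps,
                "power_adjusted": float(rej_a.mean()),
                "power_unadjusted": float(rej_u.mean()),
                "diff": float(d.mean()),
                "paired_se": float(d.std(ddof=1) / math.sqrt(grid.n_reps)),
            }
        )
    return pd.DataFrame(rows)
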
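"""Synthetic assay-data generation and parameter-recovery experiments.

The HED-assay datasets the yeast models were originally fitted to are not
publicly deposited, so this module generates statistically comparable
stand-ins: steady-state NADPH-consumption rate against HED concentration
under the standard yeast background concentrations, with multiplicative
Gaussian noise (constant coefficient of variation — enzyme-assay error
typically scales with signal).  Every generator is a pure function of its
settings and a mandatory seed, making each downstream stage testable and
exactly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .assay import AssayDataset, saturation_curve
from .analytic import v_mut, v_wt
from .fitting import fit_rate_constants
from .model_core import (
    KineticParameters,
    ModelSpec,
    GRX1_BACKGROUND,
    GRX2_BACKGROUND,
    build_hed_assay,
)

__all__ = [
    "NoiseModel",
    "RecoveryReport",
    "DEFAULT_HED_GRID",
    "DEFAULT_GSH_GRID",
    "generate_hed_dataset",
    "generate_gsh_dataset",
    "generate_psgg_family",
    "recovery_experiment",
]

#: default HED grid: 15 log-spaced points, 10-500 uM (brackets the 70 uM
#: reference concentration of the assay background)
DEFAULT_HED_GRID = tuple(np.logspace(1, math.log10(500.0), 15))

#: default GSH saturation grid: log-spaced 0.1-4000 uM
DEFAULT_GSH_GRID = tuple(np.logspace(-1, math.log10(4000.0), 25))

_PROFILES = {"grx1": GRX1_BACKGROUND, "grx2": GRX2_BACKGROUND}


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative Gaussian noise: observed = true * (1 + eps),
    eps ~ N(0, cv^2) truncated at -0.99 so rates stay positive."""

    cv: float = 0.05
    replicates: int = 1
    seed: int = 0
    kind: str = "multiplicative-gaussian"

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.kind != "multiplicative-gaussian":
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("a seed is mandatory (no silent nondeterminism)")


def _apply_noise(
    x: np.ndarray, true_rates: np.ndarray, noise: NoiseModel
) -> tuple[list[tuple], int]:
    """Noisy replicate points; with cv > 0 each point carries its known
    standard deviation cv*true so downstream fits can weight correctly."""
    rng = np.random.default_rng(noise.seed)
    points: list[tuple] = []
    n_truncated = 0
    for _rep in range(noise.replicates):
        if noise.cv > 0:
            eps = rng.normal(0.0, noise.cv, size=true_rates.size)
            n_truncated += int(np.sum(eps < -0.99))
            eps = np.maximum(eps, -0.99)
            observed = true_rates * (1.0 + eps)
            sds = noise.cv * true_rates
            points.extend(zip(x.tolist(), observed.tolist(), sds.tolist()))
        else:
            points.extend(zip(x.tolist(), true_rates.tolist()))
    return points, n_truncated


def _noise_meta(noise: NoiseModel, n_truncated: int, extra: str) -> str:
    return (
        f"{extra}\n"
        f"noise: kind={noise.kind} cv={noise.cv} replicates={noise.replicates} "
        f"seed={noise.seed} truncated={n_truncated}"
    )


def generate_hed_dataset(
    params: KineticParameters,
    background_profile: str = "grx1",
    hed_grid=DEFAULT_HED_GRID,
    noise: NoiseModel = NoiseModel(cv=0.0, seed=0),
) -> AssayDataset:
    """Synthetic HED saturation dataset from the GR-coupled assay model.

    True rates are steady-state NADPH-consumption (GR) fluxes of the
    assay model at each clamped HED concentration under the chosen
    background profile ("grx1", "grx2", or a custom concentration map).
    """
    if isinstance(background_profile, str):
        if background_profile not in _PROFILES:
            raise ValueError(
                f"unknown profile {background_profile!r}; use 'grx1', 'grx2' or a dict"
            )
        background = _PROFILES[background_profile]
        profile_name = background_profile
    else:
        background = background_profile
        profile_name = "custom"
    model = build_hed_assay(params, background)
    grid = np.asarray(hed_grid, dtype=float)
    if np.any(grid < 0):
        raise ValueError("HED grid values must be non-negative")
    true = saturation_curve(model, "HED", grid)
    points, n_truncated = _apply_noise(grid, true.rates, noise)
    return AssayDataset(
        points=points,
        varied_species="HED",
        fixed=dict(true.fixed),
        meta=_noise_meta(
            noise, n_truncated,
            f"synthetic HED assay dataset, profile={profile_name}",
        ),
    )


def generate_gsh_dataset(
    core: str,
    params: KineticParameters,
    pssG_fixed: float,
    gsh_grid=DEFAULT_GSH_GRID,
    noise: NoiseModel = NoiseModel(cv=0.0, seed=0),
) -> AssayDataset:
    """Synthetic GSH saturation dataset from the wild-type or mutant core.

    True rates come from the closed-form steady-state laws (identical to
    the numerical cores by the oracle-equivalence property): sigmoidal in
    GSH for the wild type, hyperbolic for the mutant.
    """
    grid = np.asarray(gsh_grid, dtype=float)
    if np.any(grid < 0):
        raise ValueError("GSH grid values must be non-negative")
    if core == "wildtype":
        true = np.array(
            [v_wt(params.k1, params.k2_wt, params.grx_tot, pssG_fixed, g) for g in grid]
        )
    elif core == "mutant":
        true = np.array(
            [v_mut(params.k1, params.k2p_mut, params.grx_tot, pssG_fixed, g) for g in grid]
        )
    else:
        raise ValueError(f"core must be 'wildtype' or 'mutant', got {core!r}")
    points, n_truncated = _apply_noise(grid, true, noise)
    return AssayDataset(
        points=points,
        varied_species="GSH",
        fixed={"PSSG": pssG_fixed},
        meta=_noise_meta(noise, n_truncated, f"synthetic GSH saturation, core={core}"),
    )


def generate_psgg_family(
    model: ModelSpec,
    pssG_grid,
    gsh_values,
    noise: NoiseModel = NoiseModel(cv=0.0, seed=0),
) -> list[AssayDataset]:
    """One PSSG saturation dataset per GSH level (reciprocal-plot protocol).

    Each dataset in the family gets an independent child seed derived
    from the noise seed, so the family as a whole is reproducible.
    """
    grid = np.asarray(pssG_grid, dtype=float)
    clamped = model.clamped
    if "PSSG" not in clamped or "GSH" not in clamped:
        raise ValueError("model must have clamped PSSG and GSH species")
    child_seeds = np.random.SeedSequence(noise.seed).generate_state(len(list(gsh_values)))
    datasets = []
    for gsh, child in zip(gsh_values, child_seeds):
        variant = model.with_clamped("GSH", float(gsh))
        true = saturation_curve(variant, "PSSG", grid)
        child_noise = NoiseModel(
            cv=noise.cv, replicates=noise.replicates, seed=int(child) % (2 ** 31)
        )
        points, n_truncated = _apply_noise(grid, true.rates, child_noise)
        datasets.append(
            AssayDataset(
                points=points,
                varied_species="PSSG",
                fixed=dict(true.fixed),
                meta=_noise_meta(
                    child_noise, n_truncated,
                    f"synthetic PSSG curve at GSH={gsh} uM, model={model.name}",
                ),
            )
        )
    return datasets


@dataclass(frozen=True)
class RecoveryReport:
    """Monte-Carlo parameter-recovery summary over seeds."""

    truth: dict[str, float]
    n_seeds: int
    n_failed: int
    mean_estimates: dict[str, float]
    relative_bias: dict[str, float]
    rmse: dict[str, float]            # relative RMSE
    ci95_coverage: dict[str, float]   # fraction of seeds covering truth
    estimates: dict[str, list] = field(default_factory=dict)


def recovery_experiment(
    true_params: KineticParameters,
    free_params: list[str] | None = None,
    background_profile: str = "grx1",
    hed_grid=None,
    cv: float = 0.05,
    replicates: int = 1,
    n_seeds: int = 100,
    base_seed: int = 0,
    fit_init: dict[str, float] | None = None,
) -> RecoveryReport:
    """Generate-then-fit loop: bias, RMSE and CI coverage per parameter.

    For each seed, a synthetic HED dataset is generated at the true
    constants and the free parameters are re-fitted from scratch; fit
    failures are counted, not fatal.  Defaults fit the two assay
    constants (GSH oxidation k2_wt and HED reduction k_hed) on a
    20-point log-spaced HED grid.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    free_params = free_params or ["k2_wt", "k_hed"]
    if hed_grid is None:
        hed_grid = np.logspace(1, math.log10(500.0), 20)
    background = _PROFILES[background_profile]
    template = build_hed_assay(true_params, background)
    truth = {p: getattr(true_params, p) for p in free_params}
    seeds = [int(s) % (2 ** 31) for s in np.random.SeedSequence(base_seed).generate_state(n_seeds)]
    collected: dict[str, list] = {p: [] for p in free_params}
    covered: dict[str, int] = {p: 0 for p in free_params}
    ci_counted: dict[str, int] = {p: 0 for p in free_params}
    n_failed = 0
    for seed in seeds:
        dataset = generate_hed_dataset(
            true_params,
            background_profile,
            hed_grid,
            NoiseModel(cv=cv, replicates=replicates, seed=seed),
        )
        fit = fit_rate_constants(
            template, free_params, dataset,
            init=dict(fit_init) if fit_init else dict(truth),
            weighted=True,
        )
        if not fit.converged:
            n_failed += 1
            continue
        for p in free_params:
            collected[p].append(fit.estimates[p])
            if fit.ci95 is not None:
                ci_counted[p] += 1
                lo, hi = fit.ci95[p]
                if lo <= truth[p] <= hi:
                    covered[p] += 1
    mean_estimates, rel_bias, rmse, coverage = {}, {}, {}, {}
    for p in free_params:
        values = np.array(collected[p])
        if values.size == 0:
            mean_estimates[p] = math.nan
            rel_bias[p] = math.nan
            rmse[p] = math.nan
            coverage[p] = math.nan
            continue
        mean_estimates[p] = float(values.mean())
        rel_bias[p] = float((values.mean() - truth[p]) / truth[p])
        rmse[p] = float(np.sqrt(np.mean(((values - truth[p]) / truth[p]) ** 2)))
        coverage[p] = covered[p] / ci_counted[p] if ci_counted[p] else math.nan
    return RecoveryReport(
        truth=truth,
        n_seeds=n_seeds,
        n_failed=n_failed,
        mean_estimates=mean_estimates,
        relative_bias=rel_bias,
        rmse=rmse,
        ci95_coverage=coverage,
        estimates=collected,
    )
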
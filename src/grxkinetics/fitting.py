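"""Nonlinear least-squares estimation of Grx rate constants.

Rate constants are fitted by Levenberg-Marquardt minimisation of the
residual between observed initial rates and the model's steady-state
flux, with the full reaction system (including glutathione reductase)
re-solved to steady state at every trial parameter set — no closed-form
shortcut — so the same procedure applies to any model template.
Parameters are optimised on a log10 scale, which enforces positivity by
construction; asymptotic standard errors come from the Jacobian at the
optimum and are mapped back to natural units by the delta method.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy import stats

from .assay import AssayDataset
from .model_core import ModelSpec
from .simulate import NoSteadyStateError, steady_state_flux

__all__ = ["FitResult", "fit_rate_constants", "r_squared"]

logger = logging.getLogger("grxkinetics")

_PENALTY = 1e6  # residual assigned when a trial steady state fails to converge


@dataclass(frozen=True)
class FitResult:
    """Outcome of a rate-constant fit.

    ``std_errors`` and ``ci95`` are present only when the optimiser
    produced a full-rank covariance estimate; confidence intervals are
    formed on the log scale (hence always positive).
    """

    estimates: dict[str, float]
    std_errors: dict[str, float] | None
    ci95: dict[str, tuple[float, float]] | None
    r2: float
    n_points: int
    converged: bool
    residuals: np.ndarray
    init_used: dict[str, float] = field(default_factory=dict)


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have equal length")
    if observed.size < 2:
        raise ValueError("need at least 2 points")
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("observed rates have zero variance")
    ss_res = float(np.sum((observed - predicted) ** 2))
    return 1.0 - ss_res / ss_tot


def _predict(
    model: ModelSpec,
    varied: str,
    unique_x: np.ndarray,
    trial: dict[str, float],
) -> np.ndarray | None:
    """Steady-state flux at each unique x, or None if any solve fails."""
    candidate = model.with_params(trial)
    out = np.empty_like(unique_x)
    for i, x in enumerate(unique_x):
        try:
            out[i] = steady_state_flux(candidate.with_clamped(varied, float(x)))
        except (NoSteadyStateError, RuntimeError, ValueError):
            return None
    return out


def _grid_search_init(
    model: ModelSpec,
    varied: str,
    unique_x: np.ndarray,
    inverse_index: np.ndarray,
    observed: np.ndarray,
    free_params: list[str],
    centers: dict[str, float],
) -> dict[str, float]:
    """Crude SSR grid search: 5 log-spaced candidates per parameter over
    one decade below to one decade above each center value."""
    grids = {
        name: np.logspace(math.log10(centers[name]) - 1, math.log10(centers[name]) + 1, 5)
        for name in free_params
    }
    best, best_ssr = dict(centers), math.inf
    for combo in itertools.product(*(grids[n] for n in free_params)):
        trial = dict(zip(free_params, combo))
        pred = _predict(model, varied, unique_x, trial)
        if pred is None:
            continue
        ssr = float(np.sum((observed - pred[inverse_index]) ** 2))
        if ssr < best_ssr:
            best_ssr, best = ssr, trial
    return best


def fit_rate_constants(
    model_template: ModelSpec,
    free_params: list[str],
    dataset: AssayDataset,
    init: dict[str, float] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    weighted: bool = False,
) -> FitResult:
    """Fit the named rate constants of a model to an assay dataset.

    ``free_params`` name KineticParameters fields referenced by the
    template's reactions (e.g. ``["k2_wt", "k_hed"]``).  If ``init`` is
    omitted, starting values come from a 5-per-parameter log-spaced grid
    search around the template's current constants.  With ``weighted``
    and per-point sds, residuals are scaled by 1/sd.
    """
    if not dataset.points:
        raise ValueError("dataset is empty")
    referenced = {ref for rxn in model_template.reactions for ref in rxn.param_refs.values()}
    missing = [p for p in free_params if p not in referenced]
    if missing:
        raise ValueError(
            f"parameter(s) {missing} are not referenced by model "
            f"{model_template.name}"
        )
    varied = dataset.varied_species
    x_all = dataset.x
    observed = dataset.rates
    unique_x, inverse_index = np.unique(x_all, return_inverse=True)
    sds = dataset.sds if weighted else None

    current = {
        ref: rxn.constants[slot]
        for rxn in model_template.reactions
        for slot, ref in rxn.param_refs.items()
    }
    if init is None:
        init = _grid_search_init(
            model_template, varied, unique_x, inverse_index, observed,
            free_params, {p: current[p] for p in free_params},
        )
    for name, value in init.items():
        if not (value > 0):
            raise ValueError(f"initial value for {name} must be positive")

    params = lmfit.Parameters()
    for name in free_params:
        lo, hi = (bounds or {}).get(name, (None, None))
        params.add(
            f"log10_{name}",
            value=math.log10(init[name]),
            min=math.log10(lo) if lo else -math.inf,
            max=math.log10(hi) if hi else math.inf,
        )

    n_penalized = 0

    def residual(p: lmfit.Parameters) -> np.ndarray:
        nonlocal n_penalized
        trial = {name: 10.0 ** p[f"log10_{name}"].value for name in free_params}
        pred = _predict(model_template, varied, unique_x, trial)
        if pred is None:
            n_penalized += 1
            return np.full(observed.shape, _PENALTY)
        res = observed - pred[inverse_index]
        if sds is not None:
            res = res / sds
        return res

    minim = lmfit.Minimizer(residual, params)
    try:
        result = minim.minimize(method="leastsq")
        success = bool(result.success)
    except Exception as exc:  # optimizer failure -> honest non-convergence
        logger.warning("rate-constant fit failed: %s", exc)
        return FitResult(
            estimates=dict(init),
            std_errors=None,
            ci95=None,
            r2=0.0,
            n_points=len(observed),
            converged=False,
            residuals=np.array([]),
            init_used=dict(init),
        )
    if n_penalized:
        logger.info("%d trial points rejected for solver non-convergence", n_penalized)

    estimates = {
        name: 10.0 ** result.params[f"log10_{name}"].value for name in free_params
    }
    std_errors = None
    ci95 = None
    if result.errorbars:
        ln10 = math.log(10.0)
        # covariance is scaled by the estimated noise level, so the proper
        # 95% interval uses the t quantile with n - p degrees of freedom
        dof = max(len(observed) - len(free_params), 1)
        t_crit = float(stats.t.ppf(0.975, dof))
        std_errors, ci95 = {}, {}
        for name in free_params:
            se_log = result.params[f"log10_{name}"].stderr
            if se_log is None:
                std_errors = ci95 = None
                break
            std_errors[name] = estimates[name] * ln10 * se_log
            log_val = result.params[f"log10_{name}"].value
            ci95[name] = (
                10.0 ** (log_val - t_crit * se_log),
                10.0 ** (log_val + t_crit * se_log),
            )

    pred = _predict(model_template, varied, unique_x, estimates)
    if pred is None:
        converged = False
        residuals = np.array([])
        r2 = 0.0
    else:
        residuals = observed - pred[inverse_index]
        r2 = r_squared(observed, pred[inverse_index])
        converged = success
    return FitResult(
        estimates=estimates,
        std_errors=std_errors,
        ci95=ci95,
        r2=r2,
        n_points=len(observed),
        converged=converged,
        residuals=residuals,
        init_used=dict(init),
    )
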
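"""Time-course integration and steady-state solving for ModelSpec networks.

The assay models mix fast glutathione-reductase turnover (kcat 900 s^-1)
with very slow Grx reduction constants (~1e-6 uM^-2 s^-1), so trajectories
are integrated with a stiff-capable method (LSODA).  Steady states are
found by conservation-aware root finding: one species per registered
moiety is eliminated through its conserved total before solving, which
removes the rank deficiency that moiety-closed mass-action networks
otherwise hand the Jacobian.  If root finding from the initial state does
not converge, the system is first relaxed by integration and the root
polished from there; the `converged` flag is honest — a residual above
tolerance or a negative concentration is reported, never silently
accepted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root as _scipy_root

from .model_core import ModelSpec, reaction_rate

__all__ = [
    "Trajectory",
    "SteadyState",
    "IntegrationError",
    "NoSteadyStateError",
    "time_course",
    "steady_state",
    "steady_state_flux",
]

logger = logging.getLogger("grxkinetics")

#: default steady-state tolerance on max |d[x]/dt|, uM s^-1
DEFAULT_SS_ATOL = 1e-10


class IntegrationError(RuntimeError):
    """The ODE integrator failed; carries the last valid state."""

    def __init__(self, message: str, last_state: dict[str, float] | None = None):
        super().__init__(message)
        self.last_state = last_state


class NoSteadyStateError(RuntimeError):
    """No steady state could be located for the model."""


@dataclass(frozen=True)
class Trajectory:
    """Integrated time course: times (s), species (uM), reaction fluxes."""

    times: np.ndarray
    states: pd.DataFrame   # one column per species, index aligned with times
    fluxes: pd.DataFrame   # one column per reaction


@dataclass(frozen=True)
class SteadyState:
    state: dict[str, float]    # uM
    fluxes: dict[str, float]   # uM s^-1
    residual: float            # max |d[x]/dt| over dynamic species
    converged: bool


class _CompiledModel:
    """Vectorised RHS of a ModelSpec over its dynamic species."""

    def __init__(self, model: ModelSpec):
        self.model = model
        self.dynamic = list(model.dynamic_species)
        self.clamped = dict(model.clamped)
        self.index = {name: i for i, name in enumerate(self.dynamic)}
        # stoichiometric matrix restricted to dynamic species
        self.stoich = np.zeros((len(self.dynamic), len(model.reactions)))
        for j, rxn in enumerate(model.reactions):
            for sp, coeff in rxn.stoichiometry.items():
                if sp in self.index:
                    self.stoich[self.index[sp], j] = coeff

    def conc(self, y: np.ndarray) -> dict[str, float]:
        c = dict(self.clamped)
        for name, i in self.index.items():
            c[name] = y[i]
        return c

    def rates(self, y: np.ndarray) -> np.ndarray:
        # clip integrator trial excursions below zero; final states are
        # validated separately
        c = self.conc(np.maximum(y, 0.0))
        return np.array([reaction_rate(r, c) for r in self.model.reactions])

    def rhs(self, _t: float, y: np.ndarray) -> np.ndarray:
        return self.stoich @ self.rates(y)

    def y0(self) -> np.ndarray:
        init = self.model.initial_state()
        return np.array([init[name] for name in self.dynamic])


def time_course(
    model: ModelSpec,
    t_end: float,
    n_points: int = 200,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> Trajectory:
    """Integrate the model from its initial state over [0, t_end] seconds.

    Clamped species are constant columns; the trajectory reports every
    species plus every reaction flux at ``n_points`` evenly spaced times.
    """
    if t_end <= 0:
        raise ValueError(f"t_end must be positive, got {t_end}")
    compiled = _CompiledModel(model)
    times = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(
        compiled.rhs,
        (0.0, t_end),
        compiled.y0(),
        method="LSODA",
        t_eval=times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        last = compiled.conc(sol.y[:, -1]) if sol.y.size else None
        raise IntegrationError(
            f"integration of {model.name} failed: {sol.message}", last_state=last
        )
    states = pd.DataFrame(index=times)
    for name in model.species_names:
        if name in compiled.index:
            states[name] = sol.y[compiled.index[name]]
        else:
            states[name] = compiled.clamped[name]
    flux_rows = np.array([compiled.rates(sol.y[:, k]) for k in range(sol.y.shape[1])])
    fluxes = pd.DataFrame(
        flux_rows, index=times, columns=[r.id for r in model.reactions]
    )
    return Trajectory(times=times, states=states, fluxes=fluxes)


def _reduced_system(model: ModelSpec, compiled: _CompiledModel):
    """Split dynamic species into free unknowns and moiety-eliminated ones.

    For each registered moiety, its first dynamic member is expressed
    through the conserved total and dropped from the unknown vector
    (together with its redundant ODE).
    """
    eliminated: dict[str, tuple] = {}
    used: set[str] = set()
    for moiety in model.conservation:
        member = next(
            (sp for sp in compiled.dynamic if sp in moiety.members and sp not in used),
            None,
        )
        if member is None:
            continue
        used.add(member)
        others = [
            (sp, mult)
            for sp, mult in moiety.members.items()
            if sp != member and sp in compiled.index
        ]
        eliminated[member] = (moiety, others)
    free = [sp for sp in compiled.dynamic if sp not in eliminated]
    return free, eliminated


def _full_state_from_free(
    free_values: np.ndarray,
    free: list[str],
    eliminated: dict,
    compiled: _CompiledModel,
) -> np.ndarray:
    y = np.zeros(len(compiled.dynamic))
    free_map = dict(zip(free, free_values))
    for sp, v in free_map.items():
        y[compiled.index[sp]] = v
    for sp, (moiety, others) in eliminated.items():
        mult = moiety.members[sp]
        rest = sum(m * free_map.get(o, y[compiled.index[o]]) for o, m in others)
        y[compiled.index[sp]] = (moiety.total - rest) / mult
    return y


def steady_state(
    model: ModelSpec,
    atol: float = DEFAULT_SS_ATOL,
    max_relax_time: float = 1e9,
) -> SteadyState:
    """Solve d[x]/dt = 0 subject to the model's conservation relations.

    Strategy: hybrid (Powell) root finding on the conservation-reduced
    system, initialised from the model's initial state; if that fails,
    the system is relaxed by stiff integration over geometrically growing
    horizons up to ``max_relax_time`` seconds and the root re-polished.
    Raises NoSteadyStateError when no root with non-negative
    concentrations and residual below ``atol`` exists (e.g. the
    reversible variant with an unclamped accumulating product).
    """
    compiled = _CompiledModel(model)
    if not compiled.dynamic:
        raise NoSteadyStateError(f"model {model.name} has no dynamic species")
    free, eliminated = _reduced_system(model, compiled)

    def residual_full(y: np.ndarray) -> float:
        return float(np.max(np.abs(compiled.rhs(0.0, y)))) if y.size else 0.0

    def make_result(y: np.ndarray, converged: bool) -> SteadyState:
        y = np.where(np.abs(y) < 1e-300, 0.0, y)
        state = compiled.conc(y)
        rates = compiled.rates(y)
        ok = converged and residual_full(y) < atol and bool(np.all(y >= 0.0))
        return SteadyState(
            state=state,
            fluxes={r.id: float(v) for r, v in zip(model.reactions, rates)},
            residual=residual_full(np.maximum(y, 0.0)),
            converged=ok,
        )

    def solve_from(y_start: np.ndarray) -> np.ndarray | None:
        if not free:
            return y_start
        x0 = np.array([y_start[compiled.index[sp]] for sp in free])

        def fun(x: np.ndarray) -> np.ndarray:
            y = _full_state_from_free(x, free, eliminated, compiled)
            dydt = compiled.rhs(0.0, y)
            return np.array([dydt[compiled.index[sp]] for sp in free])

        sol = _scipy_root(fun, x0, method="hybr", tol=1e-14)
        y = _full_state_from_free(sol.x, free, eliminated, compiled)
        if residual_full(np.maximum(y, 0.0)) < atol and np.all(y >= -1e-12):
            return np.maximum(y, 0.0)
        return None

    y0 = compiled.y0()
    y = solve_from(y0)
    if y is None:
        # relaxation fallback: integrate towards the attractor, retrying
        # the root polish from progressively longer horizons
        y_relax = y0
        t = 1.0
        while t <= max_relax_time:
            sol = solve_ivp(
                compiled.rhs,
                (0.0, t),
                y_relax,
                method="LSODA",
                rtol=1e-10,
                atol=1e-14,
            )
            if not sol.success:
                break
            y_relax = np.maximum(sol.y[:, -1], 0.0)
            y = solve_from(y_relax)
            if y is not None:
                break
            if residual_full(y_relax) < atol:
                y = y_relax
                break
            t *= 100.0
        if y is None and residual_full(np.maximum(y_relax, 0.0)) < atol:
            y = np.maximum(y_relax, 0.0)
    if y is None:
        logger.warning("no steady state found for model %s", model.name)
        raise NoSteadyStateError(
            f"no steady state found for model {model.name} "
            f"(residual tolerance {atol} uM/s)"
        )
    result = make_result(y, converged=True)
    logger.debug(
        "steady state of %s: residual %.3e, converged=%s",
        model.name,
        result.residual,
        result.converged,
    )
    return result


def steady_state_flux(model: ModelSpec, reaction_id: str | None = None) -> float:
    """Steady-state flux through one reaction (default: the measured one)."""
    if reaction_id is None:
        reaction_id = model.measured_reaction
    model.reaction(reaction_id)  # raises KeyError for unknown ids
    ss = steady_state(model)
    return ss.fluxes[reaction_id]
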
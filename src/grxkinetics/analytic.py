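"""Closed-form steady-state rate laws of the Grx cores.

At steady state of the two-reaction wild-type cycle the deglutathionylation
and GSH-oxidation fluxes balance, giving the harmonic-sum rate law

    v_wt = Grx_tot / (1/(k2*GSH^2) + 1/(k1*PSSG))

and its first-order-in-GSH mutant analogue.  Rearranged, the wild-type
law is exactly a Hill curve in GSH with exponent 2 — the squared GSH
dependence of GrxSS reduction, not binding cooperativity — with maximal
rate V = Grx_tot*k1*PSSG and half-saturation GSH_0.5 = sqrt(k1*PSSG/k2);
the mutant form is the hyperbolic n = 1 case with GSH_0.5 = k1*PSSG/k2'.
In double-reciprocal coordinates the wild-type law is a line in 1/PSSG
whose slope 1/(Grx_tot*k1) is independent of GSH: the ping-pong
(parallel-line) signature.

These functions double as the independent oracle for the numerical
steady-state solver; rate functions return the continuous limit 0 at
zero substrate so saturation grids may include 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "HillForm",
    "ReciprocalCoefficients",
    "v_wt",
    "grxss_fraction",
    "v_mut",
    "rate_ratio",
    "rate_ratio_limit",
    "reciprocal_coefficients",
    "hill_form_wt",
    "hill_form_mut",
]


def _require_positive(**values: float) -> None:
    for name, v in values.items():
        if not (v > 0):
            raise ValueError(f"{name} must be strictly positive, got {v}")


def _require_nonnegative(**values: float) -> None:
    for name, v in values.items():
        if not (v >= 0):
            raise ValueError(f"{name} must be non-negative, got {v}")


@dataclass(frozen=True)
class HillForm:
    """Hill parameterisation v = V * sigma^n / (1 + sigma^n), sigma = GSH/K_half."""

    V: float        # maximal rate, uM s^-1
    K_half: float   # half-saturation GSH concentration, uM
    n: int          # Hill exponent: 2 (wild type) or 1 (mutant)

    def __post_init__(self) -> None:
        _require_positive(V=self.V, K_half=self.K_half)
        if self.n not in (1, 2):
            raise ValueError(f"analytic Hill exponent must be 1 or 2, got {self.n}")

    def rate(self, gsh: float) -> float:
        _require_nonnegative(gsh=gsh)
        sigma_n = (gsh / self.K_half) ** self.n
        return self.V * sigma_n / (1.0 + sigma_n)


@dataclass(frozen=True)
class ReciprocalCoefficients:
    """Coefficients of 1/v = slope*(1/PSSG) + intercept for the wild type.

    slope = 1/(Grx_tot*k1) is independent of GSH (parallel reciprocal
    lines); intercept = 1/(Grx_tot*k2*GSH^2) falls with the square of GSH.
    """

    slope_vs_invPSSG: float  # s (uM of PSSG per uM/s of rate)
    intercept: float         # s uM^-1

    def __post_init__(self) -> None:
        _require_positive(
            slope_vs_invPSSG=self.slope_vs_invPSSG, intercept=self.intercept
        )


def v_wt(k1: float, k2: float, grx_tot: float, pssG: float, gsh: float) -> float:
    """Wild-type steady-state deglutathionylation rate (uM s^-1)."""
    _require_positive(k1=k1, k2=k2, grx_tot=grx_tot)
    _require_nonnegative(pssG=pssG, gsh=gsh)
    if pssG == 0.0 or gsh == 0.0:
        return 0.0
    return grx_tot / (1.0 / (k2 * gsh * gsh) + 1.0 / (k1 * pssG))


def grxss_fraction(k1: float, k2: float, pssG: float, gsh: float) -> float:
    """Steady-state oxidised fraction GrxSS/Grx_tot of the wild-type core."""
    _require_positive(k1=k1, k2=k2)
    _require_nonnegative(pssG=pssG, gsh=gsh)
    denominator = k1 * pssG + k2 * gsh * gsh
    if denominator == 0.0:
        raise ValueError("k1*PSSG + k2*GSH^2 must be positive")
    return k1 * pssG / denominator


def v_mut(k1: float, k2p: float, grx_tot: float, pssG: float, gsh: float) -> float:
    """Mutant steady-state rate (uM s^-1): first order in GSH."""
    _require_positive(k1=k1, k2p=k2p, grx_tot=grx_tot)
    _require_nonnegative(pssG=pssG, gsh=gsh)
    if pssG == 0.0 or gsh == 0.0:
        return 0.0
    return grx_tot / (1.0 / (k2p * gsh) + 1.0 / (k1 * pssG))


def rate_ratio(k1: float, k2: float, k2p: float, pssG: float, gsh: float) -> float:
    """Ratio v_wt/v_mut of the two cores (Grx_tot cancels)."""
    _require_positive(k1=k1, k2=k2, k2p=k2p, pssG=pssG, gsh=gsh)
    numerator = v_wt(k1, k2, 1.0, pssG, gsh)
    denominator = v_mut(k1, k2p, 1.0, pssG, gsh)
    if denominator == 0.0:
        raise ValueError("mutant rate is zero; ratio undefined")
    return numerator / denominator


def rate_ratio_limit(k2: float, k2p: float, gsh: float) -> float:
    """High-substrate limit of v_wt/v_mut: k2*GSH/k2'.

    Valid when deglutathionylation is fast relative to GSH oxidation in
    both cores (k1*PSSG >> k2*GSH^2 and >> k2'*GSH), i.e. GSH oxidation
    is rate limiting.
    """
    _require_positive(k2=k2, k2p=k2p, gsh=gsh)
    return k2 * gsh / k2p


def reciprocal_coefficients(
    k1: float, k2: float, grx_tot: float, gsh: float
) -> ReciprocalCoefficients:
    """Slope and intercept of the wild-type double-reciprocal line."""
    _require_positive(k1=k1, k2=k2, grx_tot=grx_tot, gsh=gsh)
    return ReciprocalCoefficients(
        slope_vs_invPSSG=1.0 / (grx_tot * k1),
        intercept=1.0 / (grx_tot * k2 * gsh * gsh),
    )


def hill_form_wt(k1: float, k2: float, grx_tot: float, pssG: float) -> HillForm:
    """Exact Hill-curve parameterisation of v_wt as a function of GSH (n = 2)."""
    _require_positive(k1=k1, k2=k2, grx_tot=grx_tot, pssG=pssG)
    return HillForm(
        V=grx_tot * k1 * pssG,
        K_half=math.sqrt(k1 * pssG / k2),
        n=2,
    )


def hill_form_mut(k1: float, k2p: float, grx_tot: float, pssG: float) -> HillForm:
    """Exact Hill-curve parameterisation of v_mut as a function of GSH (n = 1)."""
    _require_positive(k1=k1, k2p=k2p, grx_tot=grx_tot, pssG=pssG)
    return HillForm(
        V=grx_tot * k1 * pssG,
        K_half=k1 * pssG / k2p,
        n=1,
    )
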
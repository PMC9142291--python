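"""Equilibria, reproductive number, local stability, Lyapunov diagnostics.

The smoking-free state E0 = (1, 0, 0, 0, 0) always exists.  Its local
stability is decided by the spectrum of the Jacobian at E0, which factors
into three closed-form eigenvalues

    lambda1 = -a,
    lambda2,3 = (1/2) * (-2a - d - f -/+ sqrt(d^2 + 2df - 4def + f^2)),

plus a double eigenvalue -a.  The threshold quantity

    R0 = d * f * (1 - e) / ((a + d) * (a + f))

is the model's reproductive number.  Note that this expression is < 1 for
every strictly positive parameter set (d*f*(1-e) < (a+d)*(a+f) identically),
so under this formula the smoking-free state is always sub-threshold; the
numeric endemic-root scan below is the operational existence check for an
endemic state.

Endemic equilibria are parametrized by the heavy-smoker level S*:

    P* = a / (a + b S*),
    L* = a b S* / ((a + b S*)(a + c S*)),
    Q* = d (1 - e) S* / (a + f),
    R* = e d S* / a,

with S* any positive root of the scalar residual

    g(S*) = -(a + d) + c L*(S*) + f d (1 - e) / (a + f).

Global-stability diagnostics use the Volterra-type Lyapunov function
M = sum_x (x - x* - x* log(x/x*)) and its derivative along the flow,
dM/dt = sum_x ((x - x*)/x) * xdot, evaluated by the chain rule.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .model import CompartmentState, ModelVariant, SmokingParameters, jacobian, rhs

__all__ = [
    "StabilityReport",
    "LyapunovDiagnostic",
    "disease_free_equilibrium",
    "reproductive_number",
    "endemic_equilibrium",
    "dfe_eigenvalues",
    "lyapunov_value",
    "lyapunov_derivative",
    "stability_report",
]

#: residual tolerance certifying an equilibrium (well-conditioned 5x5, unit scale)
EQUILIBRIUM_RESIDUAL_TOL = 1e-10
#: tolerance matching closed-form eigenvalues against the numeric spectrum
EIGENVALUE_MATCH_TOL = 1e-8


def disease_free_equilibrium(params: SmokingParameters) -> CompartmentState:
    """The smoking-free steady state E0 = (1, 0, 0, 0, 0).

    Parameter-free: the whole population sits in the potential-smoker
    compartment.  The vector field vanishes there exactly.
    """
    return CompartmentState(1.0, 0.0, 0.0, 0.0, 0.0)


def reproductive_number(params: SmokingParameters) -> float:
    """R0 = d f (1 - e) / ((a + d)(a + f)), dimensionless."""
    denom_ad = params.a + params.d
    denom_af = params.a + params.f
    if denom_ad == 0.0:
        raise ZeroDivisionError("reproductive number undefined: a + d = 0")
    if denom_af == 0.0:
        raise ZeroDivisionError("reproductive number undefined: a + f = 0")
    return params.d * params.f * (1.0 - params.e) / (denom_ad * denom_af)


def _endemic_residual(s: float, params: SmokingParameters) -> float:
    a, b, c, d, e, f = (
        params.a, params.b, params.c, params.d, params.e, params.f,
    )
    l_star = a * b * s / ((a + b * s) * (a + c * s))
    return -(a + d) + c * l_star + f * d * (1.0 - e) / (a + f)


def _compose_endemic(s: float, params: SmokingParameters) -> CompartmentState:
    a, b, c, d, e, f = (
        params.a, params.b, params.c, params.d, params.e, params.f,
    )
    p = a / (a + b * s)
    l = a * b * s / ((a + b * s) * (a + c * s))
    q = d * (1.0 - e) * s / (a + f)
    r = e * d * s / a
    return CompartmentState(p, l, s, q, r)


def endemic_equilibrium(
    params: SmokingParameters,
    s_max: float = 1.0,
    n_scan: int = 10_000,
) -> list[CompartmentState]:
    """All endemic steady states with heavy-smoker level S* in (0, s_max].

    Roots of the scalar residual are bracketed by a uniform sign scan over
    ``n_scan`` intervals and refined by bisection to 1e-12.  Every returned
    state zeroes the full vector field to within ``EQUILIBRIUM_RESIDUAL_TOL``.
    An empty list means no endemic state exists on the scanned range.
    """
    if params.a == 0.0:
        raise ZeroDivisionError("endemic equilibrium undefined for a = 0 (R* = e d S*/a)")
    if s_max <= 0:
        raise ValueError(f"s_max must be > 0, got {s_max}")
    grid = np.linspace(0.0, s_max, n_scan + 1)[1:]  # exclude S = 0 (that's E0)
    vals = np.array([_endemic_residual(s, params) for s in grid])
    roots: list[CompartmentState] = []
    for i in np.nonzero(np.diff(np.sign(vals)) != 0)[0]:
        s_root = brentq(
            _endemic_residual, grid[i], grid[i + 1], args=(params,),
            xtol=1e-12, rtol=8.9e-16,
        )
        state = _compose_endemic(s_root, params)
        residual = float(np.max(np.abs(rhs(state, params, ModelVariant.PS))))
        if residual < EQUILIBRIUM_RESIDUAL_TOL:
            roots.append(state)
    # exact zeros sitting on grid points (no sign change) are vanishingly
    # unlikely for float inputs and deliberately not special-cased
    return roots


def dfe_eigenvalues(
    params: SmokingParameters,
) -> tuple[list[complex], np.ndarray, str]:
    """Closed-form and numeric spectra at E0, plus the stability verdict.

    Returns ``(closed_form, numeric, verdict)``: the three closed-form
    eigenvalues, the full five-value spectrum of the Jacobian at E0, and
    ``"locally_stable"`` iff every numeric eigenvalue has negative real part
    (else ``"not_stable"``).  A negative discriminant yields a complex pair,
    not an error.
    """
    a, d, e, f = params.a, params.d, params.e, params.f
    disc = d * d + 2.0 * d * f - 4.0 * d * e * f + f * f
    root = math.sqrt(disc) if disc >= 0 else complex(0.0, math.sqrt(-disc))
    lam1 = -a
    lam2 = 0.5 * (-2.0 * a - d - f - root)
    lam3 = 0.5 * (-2.0 * a - d - f + root)
    closed = [lam1, lam2, lam3]
    closed = [complex(v) if isinstance(v, complex) else float(v) for v in closed]
    numeric = np.linalg.eigvals(jacobian(disease_free_equilibrium(params), params))
    verdict = "locally_stable" if np.all(numeric.real < 0) else "not_stable"
    return closed, numeric, verdict


def _volterra_summand(x: float, x_star: float) -> float:
    # x* = 0 degenerates to x (x* log(x*/x) -> 0); standard Volterra convention
    if x_star == 0.0:
        return x
    return x - x_star - x_star * math.log(x / x_star)


def lyapunov_value(state: CompartmentState, eq: CompartmentState) -> float:
    """Volterra Lyapunov value M = sum (x - x* - x* log(x/x*)), >= 0.

    ``state`` must be strictly positive (logarithm); components of ``eq``
    may be zero, in which case the corresponding summand degenerates to x.
    M = 0 exactly when state = eq.
    """
    y = state.as_array()
    y_star = eq.as_array()
    if np.any(y <= 0):
        bad = ("P", "L", "S", "Q", "R")[int(np.argmax(y <= 0))]
        raise ValueError(f"lyapunov_value requires a strictly positive state; {bad} <= 0")
    if np.any(y_star < 0):
        raise ValueError("lyapunov_value requires a nonnegative reference equilibrium")
    return float(sum(_volterra_summand(x, xs) for x, xs in zip(y, y_star)))


def lyapunov_derivative(
    state: CompartmentState,
    eq: CompartmentState,
    params: SmokingParameters,
) -> float:
    """dM/dt along the PS-variant flow, by the chain rule: sum ((x-x*)/x) xdot."""
    y = state.as_array()
    y_star = eq.as_array()
    if np.any(y <= 0):
        bad = ("P", "L", "S", "Q", "R")[int(np.argmax(y <= 0))]
        raise ValueError(f"lyapunov_derivative requires a strictly positive state; {bad} <= 0")
    ydot = rhs(state, params, ModelVariant.PS)
    return float(np.sum((y - y_star) / y * ydot))


@dataclass
class LyapunovDiagnostic:
    """Lyapunov value and its time derivative at one state."""

    M: float
    dMdt: float


@dataclass
class StabilityReport:
    """Equilibria, R0, spectra and the local-stability verdict for one parameter set."""

    dfe: CompartmentState
    endemic_roots: list[CompartmentState]
    R0: float
    eigenvalues_closed_form: list[complex]
    eigenvalues_numeric: np.ndarray
    verdict: str
    params: SmokingParameters = field(repr=False, default=None)

    def to_dict(self) -> dict:
        def _num(v):
            v = complex(v)
            return v.real if v.imag == 0 else {"re": v.real, "im": v.imag}

        return {
            "dfe": list(self.dfe.as_array()),
            "endemic": [list(s.as_array()) for s in self.endemic_roots],
            "R0": self.R0,
            "eigenvalues_closed_form": [_num(v) for v in self.eigenvalues_closed_form],
            "eigenvalues_numeric": [_num(v) for v in self.eigenvalues_numeric],
            "verdict": self.verdict,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)


def stability_report(
    params: SmokingParameters, s_max: float = 1.0
) -> StabilityReport:
    """Run the full equilibrium/stability analysis for one parameter set."""
    closed, numeric, verdict = dfe_eigenvalues(params)
    return StabilityReport(
        dfe=disease_free_equilibrium(params),
        endemic_roots=endemic_equilibrium(params, s_max=s_max),
        R0=reproductive_number(params),
        eigenvalues_closed_form=closed,
        eigenvalues_numeric=numeric,
        verdict=verdict,
        params=params,
    )
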
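"""Integer-order PLSQR smoking dynamics: parameters, state, vector field, Jacobian.

The population is split into five compartments, each a fraction of a unit
total: potential smokers P, occasional (light) smokers L, heavy smokers S,
temporary quitters Q, and permanent quitters R.  Six nonnegative rates govern
the flow between them:

    a  natural death / renewal rate (inflow of fresh potential smokers),
    b  contact rate moving potential smokers into occasional smoking,
    c  contact rate escalating occasional smokers to heavy smoking,
    d  quitting rate of heavy smokers,
    e  fraction of quitters who quit permanently (dimensionless, in [0, 1]),
    f  relapse rate of temporary quitters back to heavy smoking.

Two variants of the occasional-smoker inflow are supported: the default
``PS`` incidence b*P*S (consistent with the model's equilibrium system,
Jacobian, and conservation of total population) and the alternative ``PL``
incidence b*P*L, kept as an explicit flag because it appears in one printed
form of the system.  Under PS the componentwise sum of the vector field is
a*(1 - T) with T = P+L+S+Q+R, so a unit total population is invariant; under
PL the sum picks up an extra b*P*(L - S) term and the total drifts.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "ModelVariant",
    "SmokingParameters",
    "CompartmentState",
    "rhs",
    "rhs_array",
    "jacobian",
]

_COMPARTMENTS = ("P", "L", "S", "Q", "R")


class ModelVariant(str, Enum):
    """Which bilinear term feeds the occasional-smoker compartment."""

    PS = "PS"  # inflow b*P*S (default; conserves total population)
    PL = "PL"  # inflow b*P*L (printed alternative; total population drifts)


@dataclass(frozen=True)
class SmokingParameters:
    """The six rates of the PLSQR model.

    All rates are plain per-unit-time quantities with no implicit time unit;
    the time unit is whatever the user's rates imply.
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d", "e", "f"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"parameter {name} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"parameter {name} must be >= 0, got {v}")
        if self.e > 1:
            raise ValueError(f"parameter e must lie in [0, 1], got {self.e}")

    def as_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in ("a", "b", "c", "d", "e", "f")}


@dataclass(frozen=True)
class CompartmentState:
    """One point (P, L, S, Q, R) of the population.

    Components must be finite.  Nonnegativity is an entry-point validation
    rule (see :mod:`plsqr.scenario`), not enforced here: solver iterates may
    transiently leave the positive orthant and masking that would corrupt
    convergence diagnostics.
    """

    P: float
    L: float
    S: float
    Q: float
    R: float

    def __post_init__(self) -> None:
        for name in _COMPARTMENTS:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"compartment {name} must be finite, got {v!r}")

    @property
    def total(self) -> float:
        return float(self.P + self.L + self.S + self.Q + self.R)

    def as_array(self) -> np.ndarray:
        return np.array([self.P, self.L, self.S, self.Q, self.R], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "CompartmentState":
        y = np.asarray(y, dtype=float)
        if y.shape != (5,):
            raise ValueError(f"expected a 5-component state, got shape {y.shape}")
        return cls(*map(float, y))


def _check_finite_state(y: np.ndarray) -> None:
    bad = ~np.isfinite(y)
    if bad.any():
        name = _COMPARTMENTS[int(np.argmax(bad))]
        raise ValueError(f"compartment {name} is not finite: {y[bad][0]!r}")


def rhs_array(
    y: np.ndarray,
    params: SmokingParameters,
    variant: ModelVariant = ModelVariant.PS,
) -> np.ndarray:
    """Vector field on a raw 5-array; the fast path used by the solvers."""
    y = np.asarray(y, dtype=float)
    _check_finite_state(y)
    P, L, S, Q, R = y
    a, b, c, d, e, f = (
        params.a, params.b, params.c, params.d, params.e, params.f,
    )
    incidence = b * P * S if variant is ModelVariant.PS else b * P * L
    return np.array(
        [
            a * (1.0 - P) - b * P * S,
            -a * L + incidence - c * L * S,
            -(a + d) * S + c * L * S + f * Q,
            -(a + f) * Q + d * (1.0 - e) * S,
            -a * R + e * d * S,
        ]
    )


def rhs(
    state: CompartmentState,
    params: SmokingParameters,
    variant: ModelVariant = ModelVariant.PS,
) -> np.ndarray:
    """Time derivative (dP, dL, dS, dQ, dR) of the PLSQR system.

    With the PS incidence the five components sum to a*(1 - T), so a unit
    total population is exactly invariant along the flow.
    """
    return rhs_array(state.as_array(), params, variant)


def jacobian(state: CompartmentState, params: SmokingParameters) -> np.ndarray:
    """5x5 Jacobian of the PS-variant vector field at ``state``.

    The PS incidence is used unconditionally: only that variant matches the
    model's linearization used in the local-stability analysis.
    """
    y = state.as_array()
    _check_finite_state(y)
    P, L, S, Q, R = y
    a, b, c, d, e, f = (
        params.a, params.b, params.c, params.d, params.e, params.f,
    )
    return np.array(
        [
            [-a - b * S, 0.0, -b * P, 0.0, 0.0],
            [b * S, -a - c * S, b * P - c * L, 0.0, 0.0],
            [0.0, c * S, -(a + d) + c * L, f, 0.0],
            [0.0, 0.0, d * (1.0 - e), -(a + f), 0.0],
            [0.0, 0.0, e * d, 0.0, -a],
        ]
    )
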
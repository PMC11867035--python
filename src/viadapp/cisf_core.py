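"""Compartment model of a coupled infrastructure system (CIS).

The model couples one ecological resource compartment ``R`` — described by the
vector of ecosystem-service (ES) potentials it can deliver — with three social
role compartments: exploitation ``E``, conservation ``C`` and policy-making
``P``.  Interactions between compartments are parameterised by a fixed set of
dimensionless annual action-rate weights (``u0a`` … ``u7h``).  Self-loops
(``u0a``–``u0d``) describe natural growth or decay of each compartment,
numbered link sets describe exploitation, monitoring, regulation, support and
sanction actions, and the ``u7*`` weights connect the system to its external
social-economic and climatic settings.

Structural contracts:

* every weight lies in a declared admissible interval;
* the incoming weights of each social compartment sum to one, so that the
  total capacity of action directed at a role is a convex combination of the
  linking actions.

The right-hand side of the dynamics is assembled from labelled bilinear
terms; :func:`derivative_terms` exposes the individual terms and
:func:`eval_derivative` their sum, so the decomposition can be checked
term-by-term.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Mapping

import numpy as np

__all__ = [
    "ActionWeights",
    "RoleState",
    "ESVector",
    "WEIGHT_RANGES",
    "E_SUM_FIELDS",
    "P_SUM_FIELDS",
    "C_SUM_FIELDS",
    "FREE_WEIGHT_FIELDS",
    "NormalizationReport",
    "GrowthCondition",
    "derivative_terms",
    "eval_derivative",
    "check_normalization",
    "resource_growth_condition",
    "integrate",
]

#: Admissible interval per weight.  Management, monitoring and regulation
#: rates are non-negative; the external climatic stress on R (``u7b``) is a
#: loss; every other weight may support or sanction and spans [-1, 1].
_UNIT = (0.0, 1.0)
_SYM = (-1.0, 1.0)
WEIGHT_RANGES: dict[str, tuple[float, float]] = {
    "u0a": _SYM, "u0b": _SYM, "u0c": _SYM, "u0d": _SYM,
    "u1a": _UNIT, "u1b": _SYM,
    "u2a": _UNIT, "u2b": _SYM,
    "u3a": _SYM, "u3b": _SYM,
    "u4a": _UNIT, "u4b": _SYM,
    "u5a": _UNIT, "u5b": _UNIT, "u5a_prime": _UNIT, "u5b_prime": _UNIT,
    "u6a": _SYM, "u6b": _SYM, "u6b_prime": _SYM,
    "u7a": _SYM, "u7b": (-1.0, 0.0), "u7c": _SYM, "u7d": _SYM,
    "u7e": _SYM, "u7f": _SYM, "u7g": _SYM, "u7h": _SYM,
}

#: Incoming-weight groups whose sums must equal one.
E_SUM_FIELDS = ("u0b", "u1b", "u2b", "u6b", "u7d")
P_SUM_FIELDS = ("u0c", "u2a", "u3b", "u7f")
C_SUM_FIELDS = ("u0d", "u3a", "u4a", "u6a", "u7h")

#: Weights not bound by any sum-to-1 constraint.  These are the operational
#: knobs an OCA may legitimately re-tune without breaking the contracts.
FREE_WEIGHT_FIELDS = tuple(
    name for name in WEIGHT_RANGES
    if name not in E_SUM_FIELDS + P_SUM_FIELDS + C_SUM_FIELDS
)

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class ActionWeights:
    """The full set of CIS action-rate weights (dimensionless, per year)."""

    u0a: float = 0.0
    u0b: float = 0.0
    u0c: float = 0.0
    u0d: float = 0.0
    u1a: float = 0.0
    u1b: float = 0.0
    u2a: float = 0.0
    u2b: float = 0.0
    u3a: float = 0.0
    u3b: float = 0.0
    u4a: float = 0.0
    u4b: float = 0.0
    u5a: float = 0.0
    u5b: float = 0.0
    u5a_prime: float = 0.0
    u5b_prime: float = 0.0
    u6a: float = 0.0
    u6b: float = 0.0
    u6b_prime: float = 0.0
    u7a: float = 0.0
    u7b: float = 0.0
    u7c: float = 0.0
    u7d: float = 0.0
    u7e: float = 0.0
    u7f: float = 0.0
    u7g: float = 0.0
    u7h: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def range_violations(self) -> list[str]:
        """Names of weights outside their admissible interval."""
        out = []
        for name, (lo, hi) in WEIGHT_RANGES.items():
            v = getattr(self, name)
            if not (lo - 1e-12 <= v <= hi + 1e-12):
                out.append(name)
        return out

    def validate(self) -> None:
        bad = self.range_violations()
        if bad:
            raise ValueError(f"action weights out of admissible range: {bad}")

    def replace(self, **changes: float) -> "ActionWeights":
        return replace(self, **changes)

    @classmethod
    def from_dict(cls, data: Mapping[str, float]) -> "ActionWeights":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown action-weight keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in data.items()})


@dataclass
class RoleState:
    """Relative capacities of action of the three social roles, each in [0,1]."""

    e_capacity: float = 0.0
    c_capacity: float = 0.0
    p_capacity: float = 0.0

    def clamped(self) -> "RoleState":
        return RoleState(
            e_capacity=min(1.0, max(0.0, self.e_capacity)),
            c_capacity=min(1.0, max(0.0, self.c_capacity)),
            p_capacity=min(1.0, max(0.0, self.p_capacity)),
        )

    def validate(self) -> None:
        for name in ("e_capacity", "c_capacity", "p_capacity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class ESVector:
    """Named ecosystem-service levels, each in [0,1], tagged by sign.

    ``signs`` entries are ``"service"`` (ES+, kept above a minimum) or
    ``"disservice"`` (ES-, kept below a maximum).
    """

    names: tuple[str, ...]
    signs: tuple[str, ...]
    levels: np.ndarray

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)

    def validate_structure(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("ES names must be unique")
        if len(self.names) != len(self.signs) or len(self.names) != self.levels.shape[-1]:
            raise ValueError("names, signs and levels have inconsistent lengths")
        for s in self.signs:
            if s not in ("service", "disservice"):
                raise ValueError(f"unknown ES sign {s!r}")

    def validate(self) -> None:
        self.validate_structure()
        if np.any(self.levels < -1e-12) or np.any(self.levels > 1 + 1e-12):
            raise ValueError("ES levels must lie in [0, 1]")

    def clamped(self) -> "ESVector":
        return ESVector(self.names, self.signs, np.clip(self.levels, 0.0, 1.0))

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.levels)))


def _mean_level(levels: np.ndarray) -> float:
    # Scalar reduction of the vector resource state used wherever the role
    # dynamics couple to R; the mean ES level keeps the coupling in [0, 1].
    return float(np.mean(levels)) if levels.size else 0.0


def derivative_terms(
    resource_levels: ESVector,
    roles: RoleState,
    weights: ActionWeights,
) -> dict[str, np.ndarray | float]:
    """Labelled terms of the compartment dynamics.

    The resource equation applies componentwise to the ES vector; the role
    equations are scalar and couple to the mean ES level.  Externality terms
    are first-order outflows.  Keys are grouped by compartment prefix
    (``r_``, ``e_``, ``c_``, ``p_``).
    """
    # Out-of-range weights are a hard error; state ranges are the caller's
    # precondition (the clamping-off integration path may legitimately probe
    # iterates outside [0, 1]).
    weights.validate()
    resource_levels.validate_structure()

    u = weights
    R = resource_levels.levels
    rbar = _mean_level(R)
    E, C, P = roles.e_capacity, roles.c_capacity, roles.p_capacity

    return {
        # resource compartment (vector over ES components)
        "r_natural_growth": u.u0a * R,
        "r_settings_impact": u.u7b * R,
        "r_externalities": -u.u7a * R,
        "r_supported_by_c": u.u4a * R * C,
        "r_es_access_flow_regulated": -(u.u1b * R * E) * (u.u5b * C),
        "r_access_management_regulated": (u.u1a * E * R) * (u.u5a * C),
        # exploitation role
        "e_natural_growth_decay": u.u0b * E,
        "e_settings_impact": u.u7d * E,
        "e_externalities": -u.u7c * E,
        "e_es_flow_regulated": (u.u1b * rbar * E) * (u.u5b * C),
        "e_c_support_regulation": u.u6b_prime * E * C,
        "e_p_support_sanctions": u.u2b * E * P,
        # conservation role
        "c_natural_growth_decay": u.u0d * C,
        "c_settings_impact": u.u7h * C,
        "c_externalities": -u.u7g * C,
        "c_es_flow_monitoring": (u.u1b * rbar * E) * (u.u5b_prime * C),
        "c_access_management_monitoring": (u.u1a * rbar * E) * (u.u5a_prime * C),
        "c_e_joining_leaving": (u.u6a - u.u6b) * E * C,
        "c_p_support_sanctions": u.u3a * P * C,
        # policy-making role; the settings/externality inflows scale with the
        # conservation capacity, which is how the model couples external
        # support for policy to the strength of the conservation arena
        "p_natural_growth_decay": u.u0c * P,
        "p_settings_impact": u.u7f * C,
        "p_externalities": -u.u7e * C,
        "p_e_joint_support_sanction": u.u2a * E * P,
        "p_c_joint_support_sanction": u.u3b * C * P,
    }


def eval_derivative(
    resource_levels: ESVector,
    roles: RoleState,
    weights: ActionWeights,
) -> tuple[np.ndarray, float, float, float]:
    """Time derivatives ``(dR/dt per ES component, dE/dt, dC/dt, dP/dt)``."""
    t = derivative_terms(resource_levels, roles, weights)
    dR = sum(v for k, v in t.items() if k.startswith("r_"))
    dE = sum(v for k, v in t.items() if k.startswith("e_"))
    dC = sum(v for k, v in t.items() if k.startswith("c_"))
    dP = sum(v for k, v in t.items() if k.startswith("p_"))
    return np.asarray(dR, dtype=float), float(dE), float(dC), float(dP)


@dataclass(frozen=True)
class NormalizationReport:
    """Per-compartment incoming-weight sums and the overall pass flag."""

    e_sum: float
    p_sum: float
    c_sum: float
    range_violations: tuple[str, ...]
    tolerance: float = _SUM_TOL

    @property
    def e_ok(self) -> bool:
        return abs(self.e_sum - 1.0) <= self.tolerance

    @property
    def p_ok(self) -> bool:
        return abs(self.p_sum - 1.0) <= self.tolerance

    @property
    def c_ok(self) -> bool:
        return abs(self.c_sum - 1.0) <= self.tolerance

    @property
    def passed(self) -> bool:
        return self.e_ok and self.p_ok and self.c_ok and not self.range_violations


def check_normalization(weights: ActionWeights, tolerance: float = _SUM_TOL) -> NormalizationReport:
    """Check the sum-to-1 contracts for the E, P and C compartments.

    Failure is reported, not raised.
    """
    w = weights.as_dict()
    return NormalizationReport(
        e_sum=sum(w[f] for f in E_SUM_FIELDS),
        p_sum=sum(w[f] for f in P_SUM_FIELDS),
        c_sum=sum(w[f] for f in C_SUM_FIELDS),
        range_violations=tuple(weights.range_violations()),
        tolerance=tolerance,
    )


@dataclass(frozen=True)
class GrowthCondition:
    """Two readings of the resource-growth (non-decline) condition.

    ``printed`` evaluates the closed-form inequality
    ``u0a + (u1a*u5a' + u4b)*C >= |u7b| + u1b*u5a`` in which the climatic
    stress rate enters by magnitude on the loss side.  ``derived`` evaluates
    the sign of the per-unit resource derivative assembled from the full
    dynamics at the given role capacities.  The two differ because the
    closed form mixes the regulation and monitoring rates and omits the
    exploitation capacity; both are exposed rather than silently choosing.
    """

    printed: bool
    derived: bool
    printed_margin: float
    derived_margin: float


def resource_growth_condition(
    weights: ActionWeights,
    c_capacity: float,
    e_capacity: float = 1.0,
) -> GrowthCondition:
    """Evaluate both variants of the resource-growth condition ``dR/dt >= 0``."""
    weights.validate()
    if not 0.0 <= c_capacity <= 1.0:
        raise ValueError("c_capacity must lie in [0, 1]")
    if not 0.0 <= e_capacity <= 1.0:
        raise ValueError("e_capacity must lie in [0, 1]")
    u, C, E = weights, c_capacity, e_capacity

    printed_margin = (u.u0a + (u.u1a * u.u5a_prime + u.u4b) * C) - (
        abs(u.u7b) + u.u1b * u.u5a
    )
    # per-unit rate of the resource equation (divide the componentwise dR/dt
    # by R > 0): growth + stress - externalities + support - regulated
    # exploitation + regulated management
    derived_margin = (
        u.u0a + u.u7b - u.u7a + u.u4a * C
        - u.u1b * E * u.u5b * C + u.u1a * E * u.u5a * C
    )
    return GrowthCondition(
        printed=printed_margin >= 0.0,
        derived=derived_margin >= 0.0,
        printed_margin=printed_margin,
        derived_margin=derived_margin,
    )


def integrate(
    resource_levels: ESVector,
    roles: RoleState,
    weights: ActionWeights,
    years: float,
    dt: float = 1.0,
    clamp: bool = True,
) -> tuple[ESVector, RoleState]:
    """Fixed-step explicit Euler integration of the compartment dynamics.

    The default annual step matches the annual framing of land-cover
    transitions in the application fixture.  After each step the ES levels
    and role capacities are clamped back to [0, 1] (dynamics first, clamp
    second); set ``clamp=False`` to observe the raw Euler iterates.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_steps = int(round(years / dt))
    es = ESVector(resource_levels.names, resource_levels.signs,
                  resource_levels.levels.copy())
    st = RoleState(roles.e_capacity, roles.c_capacity, roles.p_capacity)
    for _ in range(n_steps):
        dR, dE, dC, dP = eval_derivative(es, st, weights)
        es = ESVector(es.names, es.signs, es.levels + dt * dR)
        st = RoleState(st.e_capacity + dt * dE,
                       st.c_capacity + dt * dC,
                       st.p_capacity + dt * dP)
        if clamp:
            es = es.clamped()
            st = st.clamped()
    return es, st
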
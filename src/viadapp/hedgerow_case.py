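"""Synthetic hedgerow-network case: dynamics, services, constraints, arrangements.

This module generates a complete, self-contained model instance emulating a
temperate agricultural landscape whose hedgerow network delivers a bundle of
ecosystem services.  The landscape composition is a 5-class simplex — tall
species-rich (TR), tall species-poor (TP), short species-rich (SR), short
species-poor (SP) hedgerows and hedgerow-free land (NONE) — evolving under
an annual Markov transition operator composed of three layers:

* baseline ecological transitions (growth, impoverishment, slow natural
  enrichment, dieback, attrition, colonization);
* management modifiers set by the active governance arrangement (planting,
  enrichment, trimming, removal, and a maintenance factor damping natural
  decay);
* climate-stress multipliers (levels 0/1/2) inflating the degradation of
  tall and species-rich classes and feeding the external stress rate of the
  CIS resource compartment.

Seven ES are produced from the composition — five services (pollinator
resources, fruit production, wood biomass, sunlight protection, landscape
aesthetics) and two disservices (maintenance costs, environmental hazards).
All but aesthetics are convex-linear in the class proportions with
coefficients in [0, 1], hence bounded in [0, 1] over the whole simplex;
aesthetics is the Shannon diversity of the four hedgerow classes normalized
by ln 4.

Two social-ecological archetypes are shipped: a rural context with strictly
tighter satisfaction thresholds than the peri-urban one.  Nine nested
governance arrangements (CCA|KCA combinations) span a gradient from
traditional private exploitation (CCA1|KCA1) to a fully polycentric
arrangement with exploitation, conservation and policy-making roles all
active (CCA4|KCA8, CCA4|KCA9).

All numeric constants here are documented design constants of the synthetic
case, not estimates: they are chosen so that the stated qualitative
properties hold (the 2020 initial state satisfies both constraint sets,
holding CCA1|KCA1 for 30 years is non-viable everywhere, rural constraints
are strictly tighter, climate strictly accelerates TR/SR decay).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cisf_core import (
    ActionWeights,
    C_SUM_FIELDS,
    E_SUM_FIELDS,
    ESVector,
    FREE_WEIGHT_FIELDS,
    P_SUM_FIELDS,
    WEIGHT_RANGES,
)
from .governance import Arrangement, arrangement_weights, validate_nesting
from .viability import ESBound, SatisfactoryDomain
from .dapp import DecisionSchedule

__all__ = [
    "CLASSES",
    "ES_NAMES",
    "ES_SIGNS",
    "HedgerowState",
    "ManagementProfile",
    "HedgerowModel",
    "HedgerowFixture",
    "shannon_aesthetics",
    "default_fixture",
    "hedgerow_step",
    "compute_es",
]

CLASSES = ("TR", "TP", "SR", "SP", "NONE")
_TR, _TP, _SR, _SP, _NONE = range(5)
HEDGE_IDX = (_TR, _TP, _SR, _SP)

ES_NAMES = (
    "pollinator_resources",
    "fruit_production",
    "wood_biomass",
    "sunlight_protection",
    "landscape_aesthetics",
    "maintenance_costs",
    "environmental_hazards",
)
ES_SIGNS = ("service", "service", "service", "service", "service",
            "disservice", "disservice")
_AESTHETICS = ES_NAMES.index("landscape_aesthetics")

#: Convex ES coefficients per class (TR, TP, SR, SP, NONE); aesthetics is
#: computed from the Shannon index instead.  Services weight species-rich
#: and/or tall classes higher; disservices weight tall (costly to maintain)
#: and species-poor tall (hazard-prone) classes higher.
ES_COEFS: dict[str, tuple[float, float, float, float, float]] = {
    "pollinator_resources": (1.00, 0.20, 0.80, 0.15, 0.00),
    "fruit_production":     (0.90, 0.30, 0.70, 0.20, 0.00),
    "wood_biomass":         (1.00, 0.80, 0.25, 0.15, 0.00),
    "sunlight_protection":  (0.90, 0.85, 0.20, 0.15, 0.00),
    "maintenance_costs":    (0.70, 0.60, 0.35, 0.30, 0.05),
    "environmental_hazards": (0.45, 0.80, 0.15, 0.35, 0.10),
}

#: Baseline annual transition rates (from-class, to-class) -> rate / year.
BASELINE_RATES: dict[tuple[int, int], float] = {
    (_SR, _TR): 0.060,   # vertical growth
    (_SP, _TP): 0.050,
    (_TR, _TP): 0.035,   # species impoverishment
    (_SR, _SP): 0.040,
    (_TP, _TR): 0.005,   # slow natural enrichment
    (_SP, _SR): 0.008,
    (_TR, _SR): 0.020,   # dieback / breakage
    (_TP, _SP): 0.025,
    (_TR, _NONE): 0.008,  # attrition
    (_TP, _NONE): 0.012,
    (_SR, _NONE): 0.010,
    (_SP, _NONE): 0.015,
    (_NONE, _SR): 0.003,  # spontaneous colonization
    (_NONE, _SP): 0.005,
}

#: Transitions counted as natural decay: damped by maintenance effort and
#: (for TR/SR sources) inflated by climate stress.
DECAY_CELLS = frozenset({
    (_TR, _TP), (_SR, _SP), (_TR, _SR), (_TP, _SP),
    (_TR, _NONE), (_TP, _NONE), (_SR, _NONE), (_SP, _NONE),
})
#: Decay transitions out of the climate-sensitive (tall and/or rich) classes.
CLIMATE_CELLS = frozenset({
    (_TR, _TP), (_TR, _SR), (_TR, _NONE),
    (_SR, _SP), (_SR, _NONE),
    (_TP, _SP), (_TP, _NONE),
})

#: Climate stress per level: multiplier on CLIMATE_CELLS rates and the
#: external stress rate u7b of the CIS resource compartment.
CLIMATE_FACTORS = {0: 1.0, 1: 1.6, 2: 2.2}
CLIMATE_U7B = {0: 0.0, 1: -0.15, 2: -0.30}


@dataclass(frozen=True)
class HedgerowState:
    """Landscape fractions of the five composition classes (a simplex point)."""

    p_tr: float
    p_tp: float
    p_sr: float
    p_sp: float
    p_none: float

    def __post_init__(self) -> None:
        v = self.as_array()
        if np.any(v < -1e-9) or np.any(v > 1 + 1e-9):
            raise ValueError("class proportions must lie in [0, 1]")
        if abs(float(v.sum()) - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1, got {v.sum()!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_tr, self.p_tp, self.p_sr, self.p_sp,
                         self.p_none])

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "HedgerowState":
        return cls(*[float(x) for x in np.asarray(arr, dtype=float)])


@dataclass(frozen=True)
class ManagementProfile:
    """Per-arrangement management rates (per year) and effort factors.

    ``maintenance`` in [0, 1) scales natural decay by ``1 - maintenance``;
    ``rich_share`` splits planting between species-rich and species-poor
    stock; ``class_effort`` is the per-class protection effort multiplier on
    decay outflows (1 = neutral).  The shipped defaults keep ``class_effort``
    uniform: baseline management does not discriminate by species richness,
    which is exactly what the retrospective sensitivity perturbations probe.
    """

    planting: float = 0.0
    enrichment: float = 0.0
    trimming: float = 0.0
    removal: float = 0.0
    maintenance: float = 0.0
    rich_share: float = 0.5
    class_effort: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)


def transition_matrix(profile: ManagementProfile, climate_level: int) -> np.ndarray:
    """Effective annual transition operator (row-stochastic, 5x5).

    Composition: baseline decay is damped by maintenance and inflated by
    climate stress on the climate-sensitive cells, then management flows
    (planting, enrichment, trimming, removal) are added, and the diagonal
    absorbs the remainder of each row.
    """
    if climate_level not in CLIMATE_FACTORS:
        raise ValueError(f"unknown climate level {climate_level!r}")
    cf = CLIMATE_FACTORS[climate_level]
    t = np.zeros((5, 5))
    for (i, j), rate in BASELINE_RATES.items():
        r = rate
        if (i, j) in DECAY_CELLS:
            r *= (1.0 - profile.maintenance) * profile.class_effort[i]
            if (i, j) in CLIMATE_CELLS:
                r *= cf
        t[i, j] += r
    # management flows
    t[_NONE, _SR] += profile.planting * profile.rich_share
    t[_NONE, _SP] += profile.planting * (1.0 - profile.rich_share)
    t[_TP, _TR] += profile.enrichment
    t[_SP, _SR] += profile.enrichment
    t[_TR, _SR] += profile.trimming
    t[_TP, _SP] += profile.trimming
    for i in HEDGE_IDX:
        t[i, _NONE] += profile.removal
    np.fill_diagonal(t, 0.0)
    row_out = t.sum(axis=1)
    if np.any(row_out > 1.0):
        # keep rows stochastic under extreme stacked rates
        scale = np.minimum(1.0, 0.99 / np.maximum(row_out, 1e-12))
        t *= scale[:, None]
        row_out = t.sum(axis=1)
    np.fill_diagonal(t, 1.0 - row_out)
    return t


def shannon_aesthetics(proportions: np.ndarray) -> np.ndarray:
    """Normalized Shannon diversity of the four hedgerow classes.

    Proportions are renormalized over the present hedgerows (the hedge-free
    fraction is excluded); the index is ``-sum q ln q / ln 4``, i.e. 1 for
    four equal classes and 0 for a single class or no hedgerows at all.
    Accepts a single 4-vector or an ``(N, 4)`` batch.
    """
    p = np.asarray(proportions, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    if p.shape[1] != 4:
        raise ValueError("expected the four hedgerow-class proportions")
    if np.any(p < -1e-12):
        raise ValueError("proportions must be non-negative")
    total = p.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(total > 0, p / np.maximum(total, 1e-300), 0.0)
        h = -np.where(q > 0, q * np.log(q), 0.0).sum(axis=1) / np.log(4.0)
    h = np.where(total[:, 0] > 0, h, 0.0)
    h = np.clip(h, 0.0, 1.0)
    return h[0] if single else h


@dataclass
class HedgerowModel:
    """Controlled hedgerow-composition dynamics with ES production.

    Implements the duck-typed protocol expected by the viability and DAPP
    modules: the model state is the full 5-simplex vector, the grid state
    the first four (hedgerow-class) coordinates.
    """

    transition_ops: np.ndarray            # (n_controls, 5, 5)
    es_coef_matrix: np.ndarray            # (5, n_es) with aesthetics column 0
    climate_level: int
    es_names: tuple[str, ...] = ES_NAMES
    es_signs: tuple[str, ...] = ES_SIGNS
    #: per-class protection effort already baked into the operators; kept so
    #: sensitivity perturbations can rescale or permute it consistently
    class_effort: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)

    @property
    def n_controls(self) -> int:
        return len(self.transition_ops)

    def step_many(self, states: np.ndarray, control: int) -> np.ndarray:
        return np.asarray(states) @ self.transition_ops[int(control)]

    def step(self, state: HedgerowState, control: int) -> HedgerowState:
        return HedgerowState.from_array(
            self.step_many(state.as_array()[None, :], control)[0])

    def es_many(self, states: np.ndarray) -> np.ndarray:
        states = np.atleast_2d(np.asarray(states, dtype=float))
        levels = states @ self.es_coef_matrix
        levels[:, _AESTHETICS] = shannon_aesthetics(states[:, :4])
        return np.clip(levels, 0.0, 1.0)

    # grid-space adapters: the kernel grid lives on the 4 hedgerow classes
    def embed(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        p_none = 1.0 - points.sum(axis=1, keepdims=True)
        return np.hstack([points, np.clip(p_none, 0.0, 1.0)])

    def project(self, states: np.ndarray) -> np.ndarray:
        return np.atleast_2d(states)[:, :4]

    def valid_mask(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        return (points.sum(axis=1) <= 1.0 + 1e-9) & np.all(points >= -1e-12,
                                                           axis=1)

    def validate(self) -> None:
        for t in self.transition_ops:
            if np.any(t < -1e-12):
                raise ValueError("transition operator has negative entries")
            if np.any(np.abs(t.sum(axis=1) - 1.0) > 1e-9):
                raise ValueError("transition operator rows must sum to 1")


def _es_coef_matrix() -> np.ndarray:
    m = np.zeros((5, len(ES_NAMES)))
    for j, name in enumerate(ES_NAMES):
        if j == _AESTHETICS:
            continue
        m[:, j] = ES_COEFS[name]
    return m


#: Management profiles of the nine nested arrangements, ordered as
#: MANAGEMENT_LABELS.  The gradient runs from traditional exploitation
#: (trimming and removal, little planting) to polycentric arrangements with
#: strong planting, enrichment and maintenance; CCA4|KCA9 is the
#: cost-minimizing variant (little intervention, high protection).
MANAGEMENT_LABELS = (
    "CCA1|KCA1", "CCA2|KCA2", "CCA2|KCA3", "CCA2|KCA4", "CCA3|KCA5",
    "CCA3|KCA6", "CCA3|KCA7", "CCA4|KCA8", "CCA4|KCA9",
)
MANAGEMENT_PROFILES: dict[str, ManagementProfile] = {
    "CCA1|KCA1": ManagementProfile(planting=0.005, enrichment=0.000,
                                   trimming=0.050, removal=0.020,
                                   maintenance=0.05),
    "CCA2|KCA2": ManagementProfile(planting=0.020, enrichment=0.020,
                                   trimming=0.030, removal=0.005,
                                   maintenance=0.25),
    "CCA2|KCA3": ManagementProfile(planting=0.025, enrichment=0.060,
                                   trimming=0.025, removal=0.004,
                                   maintenance=0.30),
    "CCA2|KCA4": ManagementProfile(planting=0.045, enrichment=0.030,
                                   trimming=0.030, removal=0.004,
                                   maintenance=0.30),
    "CCA3|KCA5": ManagementProfile(planting=0.020, enrichment=0.050,
                                   trimming=0.020, removal=0.003,
                                   maintenance=0.40),
    "CCA3|KCA6": ManagementProfile(planting=0.030, enrichment=0.040,
                                   trimming=0.015, removal=0.003,
                                   maintenance=0.45),
    "CCA3|KCA7": ManagementProfile(planting=0.035, enrichment=0.070,
                                   trimming=0.010, removal=0.002,
                                   maintenance=0.50),
    "CCA4|KCA8": ManagementProfile(planting=0.050, enrichment=0.080,
                                   trimming=0.015, removal=0.002,
                                   maintenance=0.55),
    "CCA4|KCA9": ManagementProfile(planting=0.015, enrichment=0.020,
                                   trimming=0.005, removal=0.001,
                                   maintenance=0.60),
}

#: Role eligibility per CCA: E always present; P joins under contracting
#: (CCA2); a conservation role is created under CCA3; CCA4 is fully
#: polycentric.
_CCA_ROLES = {
    1: {"E": True, "C": False, "P": False},
    2: {"E": True, "C": False, "P": True},
    3: {"E": True, "C": True, "P": False},
    4: {"E": True, "C": True, "P": True},
}

#: Link sets switched off per KCA (on top of role-implied deactivation).
_KCA_LINKS_OFF: dict[int, tuple[str, ...]] = {
    1: (),
    2: (),
    3: (),
    4: ("0a",),       # intensive planting relies on managed stock only
    5: ("6",),        # no direct E-C coordination yet
    6: (),
    7: ("2",),        # conservation-led, no state monitoring of E
    8: (),
    9: ("3",),        # lean polycentric variant without P-C arbitration
}

_KCA_TO_CCA = {1: 1, 2: 2, 3: 2, 4: 2, 5: 3, 6: 3, 7: 3, 8: 4, 9: 4}

#: Base CIS action weights before masking; the three incoming groups sum to 1.
_BASE_WEIGHTS = {
    "u0a": 0.05, "u0b": 0.20, "u0c": 0.30, "u0d": 0.20,
    "u1a": 0.40, "u1b": 0.25,
    "u2a": 0.30, "u2b": 0.20,
    "u3a": 0.20, "u3b": 0.25,
    "u4a": 0.25, "u4b": 0.15,
    "u5a": 0.50, "u5b": 0.40, "u5a_prime": 0.30, "u5b_prime": 0.35,
    "u6a": 0.20, "u6b": 0.15, "u6b_prime": 0.10,
    "u7a": 0.02, "u7b": 0.0, "u7c": 0.05, "u7d": 0.20,
    "u7e": 0.05, "u7f": 0.15, "u7g": 0.05, "u7h": 0.15,
}

#: Satisfaction thresholds; the rural context is strictly tighter on every
#: bound (higher service floors, lower disservice caps).
_DOMAINS = {
    "peri_urban": {
        "pollinator_resources": ("service", 0.15),
        "fruit_production": ("service", 0.10),
        "wood_biomass": ("service", 0.10),
        "sunlight_protection": ("service", 0.12),
        "landscape_aesthetics": ("service", 0.25),
        "maintenance_costs": ("disservice", 0.65),
        "environmental_hazards": ("disservice", 0.55),
    },
    "rural": {
        "pollinator_resources": ("service", 0.20),
        "fruit_production": ("service", 0.18),
        "wood_biomass": ("service", 0.15),
        "sunlight_protection": ("service", 0.15),
        "landscape_aesthetics": ("service", 0.30),
        "maintenance_costs": ("disservice", 0.55),
        "environmental_hazards": ("disservice", 0.45),
    },
}

#: 2020 composition: dominated by species-poor and short hedgerows.
_INITIAL_2020 = (0.05, 0.15, 0.10, 0.40, 0.30)


def _jitter_weights(rng: np.random.Generator, climate_level: int) -> ActionWeights:
    """Seeded base weights: free rates jittered within range, incoming
    groups jittered then renormalized so the sum-to-1 contracts hold by
    construction."""
    values = dict(_BASE_WEIGHTS)
    values["u7b"] = CLIMATE_U7B[climate_level]
    for name in FREE_WEIGHT_FIELDS:
        if name == "u7b":
            continue
        lo, hi = WEIGHT_RANGES[name]
        v = values[name] * (1.0 + 0.10 * rng.uniform(-1.0, 1.0))
        values[name] = float(np.clip(v, lo, hi))
    for group in (E_SUM_FIELDS, P_SUM_FIELDS, C_SUM_FIELDS):
        jittered = {
            name: values[name] * (1.0 + 0.10 * rng.uniform(-1.0, 1.0))
            for name in group
        }
        total = sum(jittered.values())
        for name in group:
            values[name] = jittered[name] / total
    return ActionWeights.from_dict(values)


def _build_arrangements() -> list[Arrangement]:
    out = []
    for label in MANAGEMENT_LABELS:
        cca = int(label[3])
        kca = int(label[-1])
        roles = dict(_CCA_ROLES[cca])
        links = {name: True for name in
                 ("0a", "0b", "0c", "0d", "1", "2", "3", "4", "5", "6",
                  "7R", "7E", "7P", "7C")}
        for off in _KCA_LINKS_OFF[kca]:
            links[off] = False
        out.append(Arrangement(
            identifier=label,
            cca_index=cca,
            kca_index=kca,
            role_mask=roles,
            link_mask=links,
        ))
    validate_nesting(out)
    return out


@dataclass
class HedgerowFixture:
    """Everything needed to run the pipeline on the synthetic case."""

    ses_type: str
    climate_level: int
    seed: int
    model: HedgerowModel
    arrangements: list[Arrangement]
    arrangement_weights: list[ActionWeights]
    base_weights: ActionWeights
    domain: SatisfactoryDomain
    initial_state: HedgerowState
    schedule: DecisionSchedule
    labels: tuple[str, ...] = MANAGEMENT_LABELS

    @property
    def initial_array(self) -> np.ndarray:
        return self.initial_state.as_array()


def default_fixture(ses_type: str = "peri_urban", climate_level: int = 0,
                    seed: int = 0) -> HedgerowFixture:
    """Generate the full synthetic case deterministically from the seed.

    The seed drives only the jitter of the CIS action weights; landscape
    dynamics, ES coefficients and constraint sets are fixed design constants
    so the qualitative calibration of the case does not drift with the seed.
    """
    if ses_type not in _DOMAINS:
        raise ValueError(f"unknown ses_type {ses_type!r}; expected one of "
                         f"{sorted(_DOMAINS)}")
    if climate_level not in CLIMATE_FACTORS:
        raise ValueError(f"unknown climate level {climate_level!r}")
    rng = np.random.default_rng(seed)
    base = _jitter_weights(rng, climate_level)
    arrangements = _build_arrangements()
    weights = [arrangement_weights(a, base) for a in arrangements]
    ops = np.stack([
        transition_matrix(MANAGEMENT_PROFILES[label], climate_level)
        for label in MANAGEMENT_LABELS
    ])
    model = HedgerowModel(
        transition_ops=ops,
        es_coef_matrix=_es_coef_matrix(),
        climate_level=climate_level,
    )
    model.validate()
    domain = SatisfactoryDomain({
        name: ESBound(sign, thr)
        for name, (sign, thr) in _DOMAINS[ses_type].items()
    })
    return HedgerowFixture(
        ses_type=ses_type,
        climate_level=climate_level,
        seed=seed,
        model=model,
        arrangements=arrangements,
        arrangement_weights=weights,
        base_weights=base,
        domain=domain,
        initial_state=HedgerowState(*_INITIAL_2020),
        schedule=DecisionSchedule(),
    )


def hedgerow_step(state: HedgerowState, arrangement: str | int,
                  climate_level: int, dt: int = 1) -> HedgerowState:
    """Advance one state by ``dt`` annual applications of the effective
    operator of the named (or indexed) arrangement."""
    if isinstance(arrangement, str):
        profile = MANAGEMENT_PROFILES[arrangement]
    else:
        profile = MANAGEMENT_PROFILES[MANAGEMENT_LABELS[arrangement]]
    t = transition_matrix(profile, climate_level)
    v = state.as_array()
    for _ in range(int(dt)):
        v = v @ t
    return HedgerowState.from_array(v)


def compute_es(state: HedgerowState, model: HedgerowModel) -> ESVector:
    """ES vector of one composition state."""
    levels = model.es_many(state.as_array()[None, :])[0]
    return ESVector(model.es_names, model.es_signs, levels)
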
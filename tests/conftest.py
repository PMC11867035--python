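"""Shared fixtures: small controlled toy models and random-weight helpers."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from viadapp.cisf_core import (
    ActionWeights,
    C_SUM_FIELDS,
    E_SUM_FIELDS,
    FREE_WEIGHT_FIELDS,
    P_SUM_FIELDS,
    WEIGHT_RANGES,
)
from viadapp.viability import ESBound, SatisfactoryDomain

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


class AffineToyModel:
    """2-state controlled affine dynamics, ES = state.

    Each control contracts toward its own attractor:
    ``x' = 0.7 x + 0.3 target_u``.  With both coordinates read directly as
    service levels this gives a tiny, fully enumerable system for oracle
    tests of the kernel and pathway machinery.
    """

    es_names = ("es_x", "es_y")
    es_signs = ("service", "service")

    def __init__(self, targets=((0.9, 0.3), (0.3, 0.9), (0.65, 0.65)),
                 contraction=0.7):
        self.targets = np.asarray(targets, dtype=float)
        self.contraction = float(contraction)

    @property
    def n_controls(self) -> int:
        return len(self.targets)

    def step_many(self, states: np.ndarray, control: int) -> np.ndarray:
        states = np.atleast_2d(np.asarray(states, dtype=float))
        a = self.contraction
        return a * states + (1.0 - a) * self.targets[int(control)]

    def es_many(self, states: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(states, dtype=float))


@pytest.fixture
def toy_model() -> AffineToyModel:
    return AffineToyModel()


@pytest.fixture
def toy_domain() -> SatisfactoryDomain:
    return SatisfactoryDomain({
        "es_x": ESBound("service", 0.25),
        "es_y": ESBound("service", 0.25),
    })


@pytest.fixture
def vacuous_domain() -> SatisfactoryDomain:
    return SatisfactoryDomain({
        "es_x": ESBound("service", 0.0),
        "es_y": ESBound("service", 0.0),
    })


def random_valid_weights(rng: np.random.Generator) -> ActionWeights:
    """Uniformly sampled weights honouring ranges and sum-to-1 contracts."""
    values = {}
    for name in FREE_WEIGHT_FIELDS:
        lo, hi = WEIGHT_RANGES[name]
        values[name] = float(rng.uniform(lo, hi))
    for group in (E_SUM_FIELDS, P_SUM_FIELDS, C_SUM_FIELDS):
        parts = rng.dirichlet(np.ones(len(group)))
        for name, part in zip(group, parts):
            values[name] = float(part)
    return ActionWeights.from_dict(values)
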
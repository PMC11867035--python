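"""Retrospective sensitivity of pathway security to management targeting.

For every pathway the analysis re-simulates the trajectory under two
perturbed models that shift management effort between hedgerow classes —
species-rich vs species-poor (RH vs PH) or tall vs short (TH vs SH) — and
reports, per ecosystem service, the difference in security margin
(time-mean normalized distance to the satisfactory-domain boundary):

    dES = margin(favoring the first class group) - margin(favoring the second)

``dES > 0`` for a contrast like RH_vs_PH means acting more on species-rich
hedgerows buys more security for that ES than acting more on species-poor
ones.  Distributions are summarized over all supplied pathways and over the
viable subset (viability judged under the unperturbed model).

Two perturbation modes exist:

``shift`` (default)
    protection effort is shifted by the perturbation size toward the first
    group and away from the second (decay outflows scaled ``1 -/+ delta``),
    mirrored for the second model — the mode used for the security-gain
    distributions;
``swap``
    the per-class protection efforts of the two groups are exchanged.  The
    shipped management profiles are richness-blind (equal effort within each
    height pair), so an RH/PH effort swap is structurally a no-op and every
    dES — in particular landscape aesthetics, whose Shannon definition is
    symmetric under any relabeling of hedgerow classes — is identically 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .dapp import DecisionSchedule, simulate_pathway
from .hedgerow_case import (
    CLASSES,
    HEDGE_IDX,
    DECAY_CELLS,
    HedgerowModel,
)
from .viability import SatisfactoryDomain

logger = logging.getLogger(__name__)

__all__ = [
    "CONTRASTS",
    "DeltaESDistribution",
    "DistributionSummary",
    "perturbed_model",
    "delta_security",
    "summarize_distribution",
]

#: class-index groups per contrast: (favored-first group, second group)
CONTRASTS: dict[str, tuple[tuple[int, ...], tuple[int, ...]]] = {
    "RH_vs_PH": ((0, 2), (1, 3)),   # TR, SR  vs  TP, SP
    "PH_vs_RH": ((1, 3), (0, 2)),
    "TH_vs_SH": ((0, 1), (2, 3)),   # TR, TP  vs  SR, SP
    "SH_vs_TH": ((2, 3), (0, 1)),
}


@dataclass
class DeltaESDistribution:
    """Sample of per-pathway dES values for one ES and one population."""

    es_name: str
    population: str                  # "all" | "viable_only"
    sample: np.ndarray
    median: float
    q1: float
    q3: float

    @classmethod
    def from_sample(cls, es_name: str, population: str,
                    sample: np.ndarray) -> "DeltaESDistribution":
        sample = np.asarray(sample, dtype=float)
        if sample.size:
            q1, med, q3 = np.quantile(sample, [0.25, 0.5, 0.75])
        else:
            q1 = med = q3 = float("nan")
        return cls(es_name, population, sample, float(med), float(q1),
                   float(q3))


def _scale_class_outflows(ops: np.ndarray, factors: np.ndarray) -> np.ndarray:
    """Scale decay outflows of each hedgerow class and re-absorb the diagonal.

    Rates are clipped at zero (a perturbation cannot reverse a flow); when
    scaled outflows would exceed row mass they are renormalized, and both
    events are logged.
    """
    out = ops.copy()
    clipped = 0
    for t in out:
        for (i, j) in DECAY_CELLS:
            scaled = t[i, j] * factors[i]
            if scaled < 0.0:
                clipped += 1
                scaled = 0.0
            t[i, j] = scaled
        np.fill_diagonal(t, 0.0)
        row_out = t.sum(axis=1)
        if np.any(row_out > 1.0):
            clipped += int(np.count_nonzero(row_out > 1.0))
            scale = np.minimum(1.0, 0.99 / np.maximum(row_out, 1e-12))
            t *= scale[:, None]
            row_out = t.sum(axis=1)
        np.fill_diagonal(t, 1.0 - row_out)
    if clipped:
        logger.warning("perturbation pushed %d transition rates out of "
                       "range; they were clipped", clipped)
    return out


def perturbed_model(model: HedgerowModel, contrast: str,
                    perturbation_size: float,
                    direction: str = "first",
                    mode: str = "shift") -> HedgerowModel:
    """Model with management effort shifted toward one side of a contrast.

    ``direction="first"`` favors the first class group of the contrast
    (e.g. RH in RH_vs_PH); ``"second"`` mirrors it.  In ``swap`` mode the
    protection efforts of the paired classes are exchanged instead and
    ``direction``/``perturbation_size`` are ignored beyond validation.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}")
    if perturbation_size < 0:
        raise ValueError("perturbation_size must be non-negative")
    first, second = CONTRASTS[contrast]
    effort = np.array(model.class_effort, dtype=float)
    new_effort = effort.copy()
    factors = np.ones(5)
    if mode == "shift":
        delta = perturbation_size if direction == "first" else -perturbation_size
        for i in first:
            factors[i] = 1.0 - delta   # more effort => less decay
        for i in second:
            factors[i] = 1.0 + delta
        new_effort *= 1.0 / np.maximum(factors[:4], 1e-12)
    elif mode == "swap":
        # exchange the per-class protection efforts of the paired classes;
        # the decay outflows are rescaled by the relative effort change, so
        # with uniform (class-blind) effort the swap is the identity
        for a, b in zip(first, second):
            new_effort[[a, b]] = new_effort[[b, a]]
        with np.errstate(divide="ignore", invalid="ignore"):
            factors[:4] = np.where(effort > 0, new_effort / effort, 1.0)
    else:
        raise ValueError(f"unknown perturbation mode {mode!r}")
    ops = model.transition_ops
    if not np.allclose(factors, 1.0):
        ops = _scale_class_outflows(ops, factors)
    return HedgerowModel(
        transition_ops=ops,
        es_coef_matrix=model.es_coef_matrix,
        climate_level=model.climate_level,
        es_names=model.es_names,
        es_signs=model.es_signs,
        class_effort=tuple(new_effort),
    )


def _per_es_security(model, x0, controls, schedule, domain) -> np.ndarray:
    result = simulate_pathway(model, x0, controls, schedule, domain)
    return domain.normalized_margins(result.es_levels,
                                     model.es_names).mean(axis=0)


def delta_security(
    model: HedgerowModel,
    domain: SatisfactoryDomain,
    initial_state: np.ndarray,
    pathways: Sequence[Sequence[int]],
    contrast: str = "RH_vs_PH",
    perturbation_size: float = 0.10,
    schedule: Optional[DecisionSchedule] = None,
    mode: str = "shift",
) -> dict[str, dict[str, DeltaESDistribution]]:
    """Per-ES dES distributions over a pathway collection.

    Returns ``{es_name: {"all": dist, "viable_only": dist}}``.  Viability of
    each pathway is judged under the unperturbed model.
    """
    if schedule is None:
        schedule = DecisionSchedule()
    model_a = perturbed_model(model, contrast, perturbation_size,
                              direction="first", mode=mode)
    model_b = perturbed_model(model, contrast, perturbation_size,
                              direction="second", mode=mode)
    if mode == "swap":
        # the mirrored model of a swap is the unperturbed one
        model_b = model

    names = model.es_names
    deltas = np.zeros((len(pathways), len(names)))
    viable = np.zeros(len(pathways), dtype=bool)
    for idx, controls in enumerate(pathways):
        base = simulate_pathway(model, initial_state, controls, schedule,
                                domain)
        viable[idx] = base.viable
        sec_a = _per_es_security(model_a, initial_state, controls, schedule,
                                 domain)
        sec_b = _per_es_security(model_b, initial_state, controls, schedule,
                                 domain)
        deltas[idx] = sec_a - sec_b

    out: dict[str, dict[str, DeltaESDistribution]] = {}
    for j, name in enumerate(names):
        out[name] = {
            "all": DeltaESDistribution.from_sample(name, "all", deltas[:, j]),
            "viable_only": DeltaESDistribution.from_sample(
                name, "viable_only", deltas[viable, j]),
        }
    return out


@dataclass
class DistributionSummary:
    """Sample summary with fixed-width histogram bins for density export."""

    n: int
    median: float
    q1: float
    q3: float
    bin_edges: np.ndarray
    counts: np.ndarray
    empty: bool = False


def summarize_distribution(sample: Sequence[float],
                           bins: int = 20) -> DistributionSummary:
    """Median, quartiles (linear-interpolation quantiles) and histogram.

    An empty sample yields an explicit empty marker rather than NaN noise.
    """
    arr = np.asarray(list(sample), dtype=float)
    if arr.size == 0:
        return DistributionSummary(0, float("nan"), float("nan"),
                                   float("nan"), np.zeros(0), np.zeros(0,
                                   dtype=int), empty=True)
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
    counts, edges = np.histogram(arr, bins=bins)
    return DistributionSummary(int(arr.size), float(med), float(q1),
                               float(q3), edges, counts)
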
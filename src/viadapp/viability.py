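"""Satisfactory domain, finite-horizon viability kernel and regulation map.

The satisfactory domain ``K_R`` is a box of ecosystem-service levels: every
service must stay above its minimum and every disservice below its maximum.
The viability kernel over a decision horizon is the set of states from which
at least one sequence of governance arrangements keeps the trajectory inside
``K_R`` at every (annual) time step.  It is computed with a backward
induction on a regular grid of the state space: a grid node is viable at
decision epoch ``k`` iff its ES image lies in ``K_R`` and some arrangement
steers it — simulated at annual resolution over one decision interval — to a
grid cell viable at epoch ``k+1``.  States at interval boundaries are
snapped to the nearest grid node (the discrete-grid approximation of the
backward algorithm); trajectories leaving the grid bounds are treated as
non-viable and logged.

The per-node sets of arrangements that remain viable form the regulation
map, which downstream modules turn into pathway graphs.

Models plugged into this module follow a small duck-typed protocol:

``n_controls``
    number of selectable arrangements;
``es_names`` / ``es_signs``
    orderings of the ES vector returned by ``es_many``;
``step_many(states, control)``
    one annual step applied to an ``(N, d)`` batch of model states;
``es_many(states)``
    the ``(N, n_es)`` ES levels of a batch of model states.

Optionally a model may expose ``embed(points)`` / ``project(states)`` to map
between grid coordinates and the (possibly higher-dimensional) model state,
and ``valid_mask(points)`` to exclude grid nodes outside the admissible
region (e.g. off the composition simplex).
"""

from __future__ import annotations

import base64
import gzip
import json
import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ESBound",
    "SatisfactoryDomain",
    "MarginReport",
    "GridSpec",
    "ViabilityKernel",
    "compute_kernel",
    "regulation_map",
    "kernel_slice",
    "export_kernel",
    "load_kernel",
    "export_slice_tsv",
]

_EPS = 1e-12


@dataclass(frozen=True)
class ESBound:
    """Threshold for one ES: a floor for services, a cap for disservices."""

    sign: str  # "service" | "disservice"
    threshold: float

    def __post_init__(self) -> None:
        if self.sign not in ("service", "disservice"):
            raise ValueError(f"unknown ES sign {self.sign!r}")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError(f"threshold {self.threshold} outside [0, 1]")


@dataclass(frozen=True)
class SatisfactoryDomain:
    """Per-ES bounds defining the satisfactory domain ``K_R``."""

    bounds: Mapping[str, ESBound]

    def bound_arrays(self, names: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """(is_service, threshold) arrays aligned with ``names``."""
        missing = [n for n in names if n not in self.bounds]
        if missing:
            raise KeyError(f"no bound declared for ES {missing}")
        is_service = np.array([self.bounds[n].sign == "service" for n in names])
        thr = np.array([self.bounds[n].threshold for n in names])
        return is_service, thr

    def margins(self, levels: np.ndarray, names: Sequence[str]) -> np.ndarray:
        """Signed raw margins: ``level - min`` (services), ``max - level``."""
        is_service, thr = self.bound_arrays(names)
        levels = np.asarray(levels, dtype=float)
        return np.where(is_service, levels - thr, thr - levels)

    def normalized_margins(self, levels: np.ndarray, names: Sequence[str]) -> np.ndarray:
        """Margins divided by the feasible width of each bound.

        A service at level 1 or a disservice at level 0 scores 1; a level
        exactly at its threshold scores 0.  A vacuous bound (service floor
        at 0, disservice cap at 1) cannot be violated inside the ES range
        and contributes full security, 1.
        """
        is_service, thr = self.bound_arrays(names)
        width = np.where(is_service, 1.0 - thr, thr)
        norm = self.margins(levels, names) / np.maximum(width, _EPS)
        vacuous = np.where(is_service, thr <= 0.0, thr >= 1.0)
        return np.where(vacuous, 1.0, norm)

    def contains(self, levels: np.ndarray, names: Sequence[str],
                 tol: float = 0.0) -> np.ndarray:
        """Membership of ``K_R`` (all margins non-negative); broadcasts."""
        return np.all(self.margins(levels, names) >= -tol, axis=-1)

    def relaxed(self, amount: float) -> "SatisfactoryDomain":
        """Every bound loosened by ``amount`` (floors down, caps up)."""
        out = {}
        for name, b in self.bounds.items():
            if b.sign == "service":
                thr = max(0.0, b.threshold - amount)
            else:
                thr = min(1.0, b.threshold + amount)
            out[name] = ESBound(b.sign, thr)
        return SatisfactoryDomain(out)


@dataclass(frozen=True)
class MarginReport:
    """Per-ES margins of one ES vector against a satisfactory domain."""

    names: tuple[str, ...]
    raw: np.ndarray
    normalized: np.ndarray
    member: bool
    normalized_sum: float


def margin(domain: SatisfactoryDomain, es_names: Sequence[str],
           levels: np.ndarray) -> MarginReport:
    """Signed margins, membership and the normalized margin sum.

    The "normalized sum" is the mean of the per-ES normalized margins, so a
    state maximally inside every bound scores 1.
    """
    raw = domain.margins(levels, es_names)
    norm = domain.normalized_margins(levels, es_names)
    return MarginReport(
        names=tuple(es_names),
        raw=raw,
        normalized=norm,
        member=bool(np.all(raw >= 0.0)),
        normalized_sum=float(np.mean(norm)),
    )


@dataclass(frozen=True)
class GridSpec:
    """Regular rectangular grid over the model's state box."""

    lower: tuple[float, ...]
    upper: tuple[float, ...]
    n_points: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.lower) == len(self.upper) == len(self.n_points)):
            raise ValueError("lower/upper/n_points must have equal lengths")
        if any(n < 2 for n in self.n_points):
            raise ValueError("need at least 2 grid points per dimension")
        if any(u <= l for l, u in zip(self.lower, self.upper)):
            raise ValueError("upper bounds must exceed lower bounds")

    @property
    def ndim(self) -> int:
        return len(self.n_points)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(self.n_points)

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.n_points))

    @property
    def steps(self) -> np.ndarray:
        lo, hi, n = map(np.asarray, (self.lower, self.upper, self.n_points))
        return (hi - lo) / (n - 1)

    def axes(self) -> list[np.ndarray]:
        return [np.linspace(l, u, n) for l, u, n in
                zip(self.lower, self.upper, self.n_points)]

    def node_points(self) -> np.ndarray:
        """All grid nodes as an ``(n_nodes, ndim)`` array (C order)."""
        mesh = np.meshgrid(*self.axes(), indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=-1)

    def snap(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Nearest-node flat indices and an in-bounds mask.

        A point is out of bounds when any coordinate lies more than half a
        cell outside the grid box.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        lo = np.asarray(self.lower)
        h = self.steps
        idx_f = (pts - lo) / h
        idx = np.rint(idx_f).astype(np.int64)
        n = np.asarray(self.n_points)
        inbounds = np.all((idx_f >= -0.5) & (idx_f <= (n - 1) + 0.5), axis=1)
        idx = np.clip(idx, 0, n - 1)
        flat = np.ravel_multi_index(tuple(idx.T), self.shape)
        return flat, inbounds


def _model_embed(model, points: np.ndarray) -> np.ndarray:
    return model.embed(points) if hasattr(model, "embed") else points


def _model_project(model, states: np.ndarray) -> np.ndarray:
    return model.project(states) if hasattr(model, "project") else states


def _model_valid(model, points: np.ndarray) -> np.ndarray:
    if hasattr(model, "valid_mask"):
        return np.asarray(model.valid_mask(points), dtype=bool)
    return np.ones(len(points), dtype=bool)


@dataclass
class ViabilityKernel:
    """Grid-indexed finite-horizon viable set with its regulation map.

    ``membership[k]`` flags the nodes viable at decision epoch ``k``
    (``k = n_epochs - 1`` is the horizon, where viability reduces to ``K_R``
    membership).  ``viable_controls[k, node, u]`` is True when arrangement
    ``u`` keeps node ``node`` viable from epoch ``k`` to ``k+1``.
    """

    grid: GridSpec
    n_epochs: int
    n_controls: int
    membership: np.ndarray          # (n_epochs, n_nodes) bool
    viable_controls: np.ndarray     # (n_epochs - 1, n_nodes, n_controls) bool
    out_of_bounds_count: int = 0

    def membership_grid(self, epoch: int) -> np.ndarray:
        return self.membership[epoch].reshape(self.grid.shape)


def compute_kernel(
    model,
    domain: SatisfactoryDomain,
    schedule,
    grid: GridSpec,
    check_internal: bool = True,
) -> ViabilityKernel:
    """Backward-grid computation of the finite-horizon viability kernel.

    Parameters
    ----------
    model:
        Controlled dynamics following the module's duck-typed protocol.
    domain:
        The satisfactory domain ``K_R``.
    schedule:
        A decision schedule exposing ``epochs`` (>= 1) and ``step`` (years
        per decision interval); see :class:`viadapp.dapp.DecisionSchedule`.
    grid:
        Grid over the model's (projected) state space.
    check_internal:
        When True (default) ``K_R`` is enforced at every annual sub-step of
        each decision interval; when False only at decision nodes, which is
        faster but weaker.
    """
    if schedule.epochs < 1:
        raise ValueError("schedule must have at least one epoch")
    names = model.es_names
    points = grid.node_points()
    states0 = _model_embed(model, points)
    valid = _model_valid(model, points)
    in_k = domain.contains(model.es_many(states0), names) & valid

    n_epochs = schedule.epochs
    n_nodes = grid.n_nodes
    n_controls = model.n_controls
    membership = np.zeros((n_epochs, n_nodes), dtype=bool)
    controls = np.zeros((max(n_epochs - 1, 0), n_nodes, n_controls), dtype=bool)
    membership[-1] = in_k
    out_of_bounds = 0

    # one decision interval under each arrangement is identical at every
    # epoch (autonomous dynamics), so simulate once and reuse backwards
    end_index = np.zeros((n_controls, n_nodes), dtype=np.int64)
    interval_ok = np.zeros((n_controls, n_nodes), dtype=bool)
    for u in range(n_controls):
        x = states0.copy()
        ok = in_k.copy()
        for _ in range(int(schedule.step)):
            x = model.step_many(x, u)
            if check_internal:
                ok &= domain.contains(model.es_many(x), names)
        flat, inb = grid.snap(_model_project(model, x))
        out_of_bounds += int(np.count_nonzero(ok & ~inb))
        ok &= inb
        if not check_internal:
            ok &= domain.contains(model.es_many(x), names)
        end_index[u] = flat
        interval_ok[u] = ok

    for k in range(n_epochs - 2, -1, -1):
        nxt = membership[k + 1]
        for u in range(n_controls):
            controls[k, :, u] = interval_ok[u] & nxt[end_index[u]]
        membership[k] = controls[k].any(axis=1)

    if out_of_bounds:
        logger.warning(
            "%d interval end-states left the grid bounds and were treated "
            "as non-viable", out_of_bounds,
        )
    return ViabilityKernel(
        grid=grid,
        n_epochs=n_epochs,
        n_controls=n_controls,
        membership=membership,
        viable_controls=controls,
        out_of_bounds_count=out_of_bounds,
    )


def regulation_map(kernel: ViabilityKernel, state: np.ndarray,
                   epoch: int) -> frozenset[int]:
    """Arrangements that keep the grid cell containing ``state`` viable.

    ``state`` is given in grid coordinates (the projected state space).
    Empty exactly where the cell is outside the kernel at that epoch.
    """
    if not 0 <= epoch < kernel.n_epochs - 1:
        raise ValueError(
            f"epoch {epoch} has no outgoing decision interval "
            f"(valid range 0..{kernel.n_epochs - 2})"
        )
    flat, inb = kernel.grid.snap(np.atleast_2d(state))
    if not bool(inb[0]):
        raise ValueError("state lies outside the grid bounds")
    return frozenset(np.nonzero(kernel.viable_controls[epoch, flat[0]])[0].tolist())


def kernel_slice(
    kernel: ViabilityKernel,
    dims: tuple[int, int],
    fixed_values: Mapping[int, float],
    epoch: int = 0,
) -> np.ndarray:
    """2-D boolean cut of the kernel at one epoch.

    ``dims`` selects the two free axes; every remaining dimension is fixed
    at the grid index nearest to its entry in ``fixed_values``.
    """
    d0, d1 = dims
    ndim = kernel.grid.ndim
    if d0 == d1 or not (0 <= d0 < ndim and 0 <= d1 < ndim):
        raise ValueError(f"invalid slice dims {dims} for a {ndim}-d grid")
    rest = [d for d in range(ndim) if d not in (d0, d1)]
    missing = [d for d in rest if d not in fixed_values]
    if missing:
        raise ValueError(f"missing fixed values for dimensions {missing}")
    member = kernel.membership_grid(epoch)
    indexer: list = [slice(None)] * ndim
    axes = kernel.grid.axes()
    for d in rest:
        indexer[d] = int(np.argmin(np.abs(axes[d] - fixed_values[d])))
    sliced = member[tuple(indexer)]
    if d0 > d1:
        sliced = sliced.T
    return sliced


def _pack_bool(arr: np.ndarray) -> str:
    return base64.b64encode(np.packbits(arr.astype(np.uint8))).decode("ascii")


def _unpack_bool(data: str, size: int) -> np.ndarray:
    bits = np.unpackbits(np.frombuffer(base64.b64decode(data), dtype=np.uint8))
    return bits[:size].astype(bool)


def export_kernel(kernel: ViabilityKernel, path) -> None:
    """Write a kernel to gzipped JSON (grid spec + per-epoch bitsets)."""
    payload = {
        "grid": {
            "lower": list(kernel.grid.lower),
            "upper": list(kernel.grid.upper),
            "n_points": list(kernel.grid.n_points),
        },
        "n_epochs": kernel.n_epochs,
        "n_controls": kernel.n_controls,
        "out_of_bounds_count": kernel.out_of_bounds_count,
        "membership": [_pack_bool(kernel.membership[k])
                       for k in range(kernel.n_epochs)],
        "viable_controls": [_pack_bool(kernel.viable_controls[k].ravel())
                            for k in range(kernel.n_epochs - 1)],
    }
    with gzip.open(path, "wt", encoding="utf-8") as fh:
        json.dump(payload, fh, sort_keys=True)


def load_kernel(path) -> ViabilityKernel:
    with gzip.open(path, "rt", encoding="utf-8") as fh:
        payload = json.load(fh)
    g = payload["grid"]
    grid = GridSpec(tuple(g["lower"]), tuple(g["upper"]), tuple(g["n_points"]))
    n_epochs = payload["n_epochs"]
    n_controls = payload["n_controls"]
    n_nodes = grid.n_nodes
    membership = np.stack([
        _unpack_bool(s, n_nodes) for s in payload["membership"]
    ])
    controls = np.stack([
        _unpack_bool(s, n_nodes * n_controls).reshape(n_nodes, n_controls)
        for s in payload["viable_controls"]
    ]) if payload["viable_controls"] else np.zeros((0, n_nodes, n_controls), bool)
    return ViabilityKernel(grid, n_epochs, n_controls, membership, controls,
                           payload.get("out_of_bounds_count", 0))


def export_slice_tsv(slice2d: np.ndarray, path) -> None:
    """Write a 2-D boolean kernel cut as a 0/1 TSV matrix."""
    np.savetxt(path, slice2d.astype(int), fmt="%d", delimiter="\t")
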
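"""Dynamic adaptive policy pathway (DAPP) maps over governance arrangements.

A pathway assigns one governance arrangement to each decision epoch of a
schedule (by default every 5 years over a 30-year horizon, i.e. 7 epochs;
the final epoch's arrangement labels the end state but governs no interval,
which is what makes the pathway count ``n_arrangements ** epochs``).  The
DAPP map is a layered directed graph whose nodes are (epoch, arrangement)
pairs and whose edges between consecutive epochs carry the number of viable
full-horizon pathways traversing them; normalizing the counts by the map's
maximum gives the grayscale shading of a probability map.

Enumeration is exact: the forward sweep over the decision tree is memoized
on the (deterministic) model state reached at each epoch, so the number of
simulated decision intervals grows with the number of *distinct* reachable
states rather than with the raw pathway count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .viability import SatisfactoryDomain, margin

__all__ = [
    "DecisionSchedule",
    "PathwayResult",
    "DAPPGraph",
    "count_pathways",
    "simulate_pathway",
    "enumerate_viable",
    "iter_viable_pathways",
    "build_graph_from_pathways",
    "top_secured",
    "optimal_for_es",
    "es_trajectories",
]


@dataclass(frozen=True)
class DecisionSchedule:
    """Decision epochs of a DAPP horizon.

    ``epochs = horizon / step + 1``: one arrangement per decision node,
    including the terminal node that labels (but does not govern) the end
    state.
    """

    start_year: int = 2020
    horizon: int = 30
    step: int = 5

    def __post_init__(self) -> None:
        if self.step <= 0 or self.horizon <= 0:
            raise ValueError("horizon and step must be positive")
        if self.horizon % self.step != 0:
            raise ValueError(
                f"decision step {self.step} does not divide horizon {self.horizon}"
            )

    @property
    def epochs(self) -> int:
        return self.horizon // self.step + 1

    @property
    def n_intervals(self) -> int:
        return self.epochs - 1

    @property
    def years(self) -> np.ndarray:
        return self.start_year + np.arange(self.horizon + 1)

    @property
    def decision_years(self) -> np.ndarray:
        return self.start_year + self.step * np.arange(self.epochs)


def count_pathways(n_arrangements: int, schedule: DecisionSchedule) -> int:
    """Total number of governance pathways, ``n_arrangements ** epochs``."""
    if n_arrangements < 1:
        raise ValueError("need at least one arrangement")
    return n_arrangements ** schedule.epochs


@dataclass
class PathwayResult:
    """One simulated pathway: trajectory, viability and security score."""

    controls: tuple[int, ...]
    years: np.ndarray
    states: np.ndarray           # (horizon + 1, state_dim)
    es_levels: np.ndarray        # (horizon + 1, n_es)
    es_names: tuple[str, ...]
    viable: bool
    security: float
    first_violation_year: Optional[int] = None

    def es_mean(self, es_name: str) -> float:
        return float(self.es_levels[:, self.es_names.index(es_name)].mean())


def _security_aggregate(values: np.ndarray, how: str) -> float:
    if how == "mean":
        return float(np.mean(values))
    if how == "min":
        return float(np.min(values))
    raise ValueError(f"unknown security aggregation {how!r}")


def simulate_pathway(
    model,
    initial_state: np.ndarray,
    controls: Sequence[int],
    schedule: DecisionSchedule,
    domain: SatisfactoryDomain,
    security: str = "mean",
) -> PathwayResult:
    """Deterministic annual-resolution simulation of one pathway.

    Viability requires every annual state (including the initial one) to lie
    in ``K_R``.  The security score aggregates the normalized margin sum over
    the annual steps — the time mean by default, the worst year with
    ``security="min"``.
    """
    controls = tuple(int(c) for c in controls)
    if len(controls) != schedule.epochs:
        raise ValueError(
            f"pathway length {len(controls)} != epochs {schedule.epochs}"
        )
    names = model.es_names
    x = np.atleast_2d(np.asarray(initial_state, dtype=float))
    states = [x[0].copy()]
    for u in controls[:-1]:
        for _ in range(schedule.step):
            x = model.step_many(x, u)
            states.append(x[0].copy())
    states_arr = np.asarray(states)
    es = model.es_many(states_arr)
    member = domain.contains(es, names)
    viable = bool(member.all())
    margins = domain.normalized_margins(es, names).mean(axis=1)
    first_violation = None
    if not viable:
        first_violation = int(schedule.start_year + np.argmin(member))
    return PathwayResult(
        controls=controls,
        years=schedule.years.copy(),
        states=states_arr,
        es_levels=es,
        es_names=tuple(names),
        viable=viable,
        security=_security_aggregate(margins, security),
        first_violation_year=first_violation,
    )


@dataclass
class DAPPGraph:
    """Epoch-layered directed graph of arrangements with traversal counts.

    ``edge_counts[k, u, v]`` is the number of viable full-horizon pathways
    whose epoch-``k`` arrangement is ``u`` and epoch-``k+1`` arrangement is
    ``v``.  For each layer the counts sum to ``total_viable``.
    """

    schedule: DecisionSchedule
    n_arrangements: int
    labels: tuple[str, ...]
    edge_counts: np.ndarray      # (epochs - 1, U, U) int64
    total_viable: int
    total_pathways: int

    @property
    def shades(self) -> np.ndarray:
        """Edge counts normalized by the map-wide maximum (0-1 grayscale)."""
        peak = self.edge_counts.max()
        if peak == 0:
            return np.zeros_like(self.edge_counts, dtype=float)
        return self.edge_counts / float(peak)

    def layer_sums(self) -> np.ndarray:
        return self.edge_counts.sum(axis=(1, 2))

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        years = self.schedule.decision_years
        shades = self.shades
        for k in range(self.schedule.epochs):
            for u in range(self.n_arrangements):
                g.add_node(f"{years[k]}:{self.labels[u]}",
                           epoch=int(k), year=int(years[k]),
                           arrangement=self.labels[u])
        for k in range(self.schedule.epochs - 1):
            for u in range(self.n_arrangements):
                for v in range(self.n_arrangements):
                    c = int(self.edge_counts[k, u, v])
                    if c > 0:
                        g.add_edge(
                            f"{years[k]}:{self.labels[u]}",
                            f"{years[k + 1]}:{self.labels[v]}",
                            traversals=c, shade=float(shades[k, u, v]),
                        )
        return g

    def write_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)

    def write_dot(self, path) -> None:
        g = self.to_networkx()
        lines = ["digraph dapp {", "  rankdir=LR;"]
        for node in g.nodes:
            lines.append(f'  "{node}";')
        for a, b, data in g.edges(data=True):
            lines.append(
                f'  "{a}" -> "{b}" [traversals={data["traversals"]}, '
                f'shade={data["shade"]:.6f}];'
            )
        lines.append("}")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n")


class _ForwardLayers:
    """Layered forward exploration with per-state memoization.

    For each epoch layer it stores the distinct reachable (viable-so-far)
    states, the number of viable prefixes leading to each, and for every
    arrangement the interval outcome (constraint satisfaction, accumulated
    normalized margin, successor state index).
    """

    def __init__(self, model, initial_state, schedule, domain,
                 security: str = "mean"):
        self.model = model
        self.schedule = schedule
        self.domain = domain
        self.names = model.es_names
        self.n_controls = model.n_controls
        self.security = security

        x0 = np.atleast_2d(np.asarray(initial_state, dtype=float))
        es0 = model.es_many(x0)
        self.root_ok = bool(domain.contains(es0, self.names)[0])
        self.root_margin = float(
            domain.normalized_margins(es0, self.names).mean())

        self.states: list[np.ndarray] = []        # per layer (N, d)
        self.prefix: list[np.ndarray] = []        # per layer (N,) int64
        self.ok: list[np.ndarray] = []            # per layer (U, N) bool
        self.margin_sum: list[np.ndarray] = []    # per layer (U, N) float
        self.margin_min: list[np.ndarray] = []    # per layer (U, N) float
        self.succ: list[np.ndarray] = []          # per layer (U, N) int64
        self._run(x0)

    def _run(self, x0: np.ndarray) -> None:
        model, domain, names = self.model, self.domain, self.names
        n_int = self.schedule.n_intervals
        states = x0
        prefix = np.array([1 if self.root_ok else 0], dtype=np.int64)
        for k in range(n_int):
            self.states.append(states)
            self.prefix.append(prefix)
            n = len(states)
            ok_k = np.zeros((self.n_controls, n), dtype=bool)
            msum_k = np.zeros((self.n_controls, n))
            mmin_k = np.full((self.n_controls, n), np.inf)
            succ_k = np.full((self.n_controls, n), -1, dtype=np.int64)
            key_index: dict[bytes, int] = {}
            next_states: list[np.ndarray] = []
            next_prefix: list[int] = []
            for u in range(self.n_controls):
                x = states.copy()
                ok = np.ones(n, dtype=bool)
                msum = np.zeros(n)
                mmin = np.full(n, np.inf)
                for _ in range(self.schedule.step):
                    x = model.step_many(x, u)
                    es = model.es_many(x)
                    ok &= domain.contains(es, names)
                    m = domain.normalized_margins(es, names).mean(axis=1)
                    msum += m
                    mmin = np.minimum(mmin, m)
                ok_k[u] = ok
                msum_k[u] = msum
                mmin_k[u] = mmin
                for i in np.nonzero(ok)[0]:
                    key = x[i].tobytes()
                    j = key_index.get(key)
                    if j is None:
                        j = len(next_states)
                        key_index[key] = j
                        next_states.append(x[i])
                        next_prefix.append(0)
                    succ_k[u, i] = j
                    next_prefix[j] += int(prefix[i])
            self.ok.append(ok_k)
            self.margin_sum.append(msum_k)
            self.margin_min.append(mmin_k)
            self.succ.append(succ_k)
            if next_states:
                states = np.asarray(next_states)
                prefix = np.asarray(next_prefix, dtype=np.int64)
            else:
                states = np.zeros((0, states.shape[1]))
                prefix = np.zeros(0, dtype=np.int64)
        self.states.append(states)
        self.prefix.append(prefix)

    def suffix_counts(self) -> list[np.ndarray]:
        """``S[k][i]``: viable assignments of the remaining arrangements."""
        n_int = self.schedule.n_intervals
        S: list[np.ndarray] = [np.zeros(0)] * (n_int + 1)
        # the terminal arrangement labels the end state and is always viable
        S[n_int] = np.full(len(self.states[n_int]), self.n_controls,
                           dtype=np.int64)
        for k in range(n_int - 1, -1, -1):
            n = len(self.states[k])
            s = np.zeros(n, dtype=np.int64)
            for u in range(self.n_controls):
                ok = self.ok[k][u]
                idx = self.succ[k][u]
                contrib = np.zeros(n, dtype=np.int64)
                contrib[ok] = S[k + 1][idx[ok]]
                s += contrib
            S[k] = s
        return S


def enumerate_viable(
    model,
    initial_state: np.ndarray,
    schedule: DecisionSchedule,
    domain: SatisfactoryDomain,
    labels: Optional[Sequence[str]] = None,
) -> DAPPGraph:
    """Exact DAPP graph of viable pathways from one initial state.

    Per-edge traversal counts are assembled as (viable prefixes reaching the
    edge's tail in the tail state) x (viable suffixes from the interval's
    end state that start with the edge's head arrangement), memoized on the
    distinct states reachable at each epoch.
    """
    fw = _ForwardLayers(model, initial_state, schedule, domain)
    n_int = schedule.n_intervals
    U = fw.n_controls
    S = fw.suffix_counts()
    edge = np.zeros((n_int, U, U), dtype=np.int64)
    if fw.root_ok:
        for k in range(n_int):
            prefix = fw.prefix[k]
            for u in range(U):
                ok_u = fw.ok[k][u]
                idx_u = fw.succ[k][u]
                if not ok_u.any():
                    continue
                sel = np.nonzero(ok_u)[0]
                tails = prefix[sel]
                ends = idx_u[sel]
                for v in range(U):
                    if k + 1 < n_int:
                        ok_v = fw.ok[k + 1][v][ends]
                        suf = np.zeros(len(sel), dtype=np.int64)
                        suf[ok_v] = S[k + 2][fw.succ[k + 1][v][ends][ok_v]]
                    else:
                        suf = np.ones(len(sel), dtype=np.int64)
                    edge[k, u, v] = int(np.sum(tails * suf))
    total_viable = int(S[0][0]) if fw.root_ok and len(S[0]) else 0
    if labels is None:
        labels = tuple(str(u) for u in range(U))
    return DAPPGraph(
        schedule=schedule,
        n_arrangements=U,
        labels=tuple(labels),
        edge_counts=edge,
        total_viable=total_viable,
        total_pathways=count_pathways(U, schedule),
    )


def iter_viable_pathways(
    model,
    initial_state: np.ndarray,
    schedule: DecisionSchedule,
    domain: SatisfactoryDomain,
    security: str = "mean",
    max_pathways: Optional[int] = None,
) -> Iterator[tuple[tuple[int, ...], float]]:
    """Yield every viable pathway with its security score.

    Pathways are produced in lexicographic arrangement order.  The walk is
    pruned with memoized suffix counts, so dead branches cost nothing; for
    maps with very many viable pathways ``max_pathways`` caps the yield (a
    ``RuntimeError`` is raised when the cap is hit, so a silent truncation
    can never masquerade as an exhaustive enumeration).
    """
    fw = _ForwardLayers(model, initial_state, schedule, domain,
                        security=security)
    if not fw.root_ok:
        return
    S = fw.suffix_counts()
    n_int = schedule.n_intervals
    U = fw.n_controls
    horizon_steps = schedule.horizon
    yielded = 0

    # iterative DFS: (layer, state index, margin sum so far, margin min,
    # prefix controls)
    stack: list[tuple[int, int, float, float, tuple[int, ...]]] = [
        (0, 0, fw.root_margin, fw.root_margin, ())
    ]
    while stack:
        k, i, msum, mmin, prefix = stack.pop()
        if k == n_int:
            if security == "mean":
                score = msum / (horizon_steps + 1)
            else:
                score = mmin
            for v in range(U):
                if max_pathways is not None and yielded >= max_pathways:
                    raise RuntimeError(
                        f"viable pathway cap {max_pathways} exceeded"
                    )
                yielded += 1
                yield prefix + (v,), score
            continue
        # push in reverse so pathways emerge lexicographically
        for u in range(U - 1, -1, -1):
            if not fw.ok[k][u][i]:
                continue
            j = int(fw.succ[k][u][i])
            if S[k + 1][j] == 0:
                continue
            stack.append((
                k + 1, j,
                msum + float(fw.margin_sum[k][u][i]),
                min(mmin, float(fw.margin_min[k][u][i])),
                prefix + (u,),
            ))


def build_graph_from_pathways(
    pathways: Iterable[Sequence[int]],
    n_arrangements: int,
    schedule: DecisionSchedule,
    labels: Optional[Sequence[str]] = None,
) -> DAPPGraph:
    """DAPP graph whose edge counts tally an explicit pathway collection."""
    edge = np.zeros((schedule.n_intervals, n_arrangements, n_arrangements),
                    dtype=np.int64)
    total = 0
    for controls in pathways:
        total += 1
        for k in range(schedule.n_intervals):
            edge[k, controls[k], controls[k + 1]] += 1
    if labels is None:
        labels = tuple(str(u) for u in range(n_arrangements))
    return DAPPGraph(
        schedule=schedule,
        n_arrangements=n_arrangements,
        labels=tuple(labels),
        edge_counts=edge,
        total_viable=total,
        total_pathways=count_pathways(n_arrangements, schedule),
    )


def top_secured(
    pathways: Sequence[tuple[tuple[int, ...], float]],
    fraction: float,
    n_arrangements: int,
    schedule: DecisionSchedule,
    labels: Optional[Sequence[str]] = None,
) -> tuple[list[tuple[tuple[int, ...], float]], DAPPGraph]:
    """The ``ceil(fraction * n)`` most secured pathways and their map.

    Ties are broken by lexicographic arrangement sequence (ascending), so
    the selection is deterministic.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    ranked = sorted(pathways, key=lambda p: (-p[1], p[0]))
    n_keep = math.ceil(fraction * len(ranked))
    kept = ranked[:n_keep]
    graph = build_graph_from_pathways(
        [c for c, _ in kept], n_arrangements, schedule, labels)
    return kept, graph


def optimal_for_es(
    results: Sequence[PathwayResult],
    es_name: str,
    sense: str,
    aggregate: str = "mean",
    tol: float = 1e-12,
) -> list[PathwayResult]:
    """Viable pathways achieving the best aggregated level of one ES.

    ``aggregate`` is the time mean by default or ``"terminal"`` for the end
    value; all co-optimal pathways (within ``tol``) are returned.
    """
    if sense not in ("maximize", "minimize"):
        raise ValueError(f"sense must be maximize or minimize, got {sense!r}")
    viable = [r for r in results if r.viable]
    if not viable:
        return []
    if es_name not in viable[0].es_names:
        raise KeyError(f"unknown ES {es_name!r}")
    col = viable[0].es_names.index(es_name)

    def value(r: PathwayResult) -> float:
        if aggregate == "mean":
            return float(r.es_levels[:, col].mean())
        if aggregate == "terminal":
            return float(r.es_levels[-1, col])
        raise ValueError(f"unknown aggregate {aggregate!r}")

    values = np.array([value(r) for r in viable])
    best = values.max() if sense == "maximize" else values.min()
    return [r for r, v in zip(viable, values) if abs(v - best) <= tol]


def es_trajectories(
    model,
    initial_state: np.ndarray,
    controls: Sequence[int],
    schedule: DecisionSchedule,
) -> pd.DataFrame:
    """Annual ES levels along a pathway, one row per year."""
    x = np.atleast_2d(np.asarray(initial_state, dtype=float))
    rows = [model.es_many(x)[0]]
    for u in controls[:-1]:
        for _ in range(schedule.step):
            x = model.step_many(x, int(u))
            rows.append(model.es_many(x)[0])
    return pd.DataFrame(np.asarray(rows), index=pd.Index(schedule.years, name="year"),
                        columns=list(model.es_names))
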
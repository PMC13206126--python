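"""Elimination orders: moral graphs, minfill, widths, lifted orders.

The width of an order is computed by simulating factor scopes (clusters),
so evidence indicators and any extra factors are counted exactly as
variable elimination will see them.  Lifted orders follow the copy-and-
append construction that turns an order for a base SCM into one for its
objective model, preserving the treewidth bounds proved for it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .model import Model

__all__ = [
    "Order",
    "WidthReport",
    "moral_graph",
    "minfill_order",
    "order_width",
    "scope_width",
    "lift_order",
    "is_external",
    "exhaustive_treewidth",
    "ConstraintError",
]


class ConstraintError(ValueError):
    """An elimination order does not satisfy its target-suffix constraint."""


@dataclass(frozen=True)
class Order:
    """A total elimination order, optionally constrained to end with ``constraint``."""

    names: tuple[str, ...]
    constraint: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("elimination order repeats a variable")
        if self.constraint:
            suffix = set(self.names[-len(self.constraint):])
            if suffix != set(self.constraint):
                raise ConstraintError(
                    f"constrained variables {sorted(self.constraint)} must occupy "
                    "the suffix of the order"
                )

    def split(self, targets: Iterable[str]) -> tuple[tuple[str, ...], tuple[str, ...]]:
        """Split into (non-target prefix, target suffix); targets must be last."""
        t = set(targets)
        k = len(t)
        if k and set(self.names[-k:]) != t:
            raise ConstraintError(
                f"order is not constrained to place {sorted(t)} last"
            )
        return (self.names[: len(self.names) - k], self.names[len(self.names) - k:])

    def __iter__(self):
        return iter(self.names)

    def __len__(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class WidthReport:
    """Clusters induced by eliminating along an order, and the width."""

    order: tuple[str, ...]
    clusters: tuple[frozenset, ...]

    @property
    def width(self) -> int:
        return self.max_cluster_size - 1

    @property
    def max_cluster_size(self) -> int:
        return max((len(c) for c in self.clusters), default=1)


def moral_graph(model: Model) -> nx.Graph:
    """Undirected graph marrying each variable to its parents and co-parents."""
    g = nx.Graph()
    g.add_nodes_from(model.variables)
    for name, ps in model.parents.items():
        g.add_edges_from((p, name) for p in ps)
        g.add_edges_from(itertools.combinations(ps, 2))
    return g


def minfill_order(model: Model, constraint: Iterable[str] | None = None) -> Order:
    """Greedy minfill elimination order, ties broken by declaration order.

    Variables in ``constraint`` become eligible only once every other
    variable has been eliminated, producing a constrained order.
    """
    targets = tuple(constraint or ())
    for t in targets:
        if t not in model.variables:
            raise ValueError(f"constraint names unknown variable {t!r}")
    graph = moral_graph(model)
    adj: dict[str, set[str]] = {n: set(graph[n]) for n in graph}
    decl = {n: i for i, n in enumerate(model.variables)}
    remaining = set(model.variables)
    target_set = set(targets)
    order: list[str] = []

    def fill(v: str) -> int:
        nbrs = list(adj[v])
        return sum(
            1
            for a, b in itertools.combinations(nbrs, 2)
            if b not in adj[a]
        )

    while remaining:
        eligible = remaining - target_set if remaining - target_set else remaining
        best = min(eligible, key=lambda v: (fill(v), decl[v]))
        nbrs = list(adj[best])
        for a, b in itertools.combinations(nbrs, 2):
            adj[a].add(b)
            adj[b].add(a)
        for n in nbrs:
            adj[n].discard(best)
        del adj[best]
        remaining.discard(best)
        order.append(best)
    return Order(tuple(order), targets)


def scope_width(
    scopes: Sequence[Iterable[str]], order: Sequence[str]
) -> WidthReport:
    """Width of an order by factor-scope simulation over arbitrary scopes."""
    live = [frozenset(s) for s in scopes]
    clusters: list[frozenset] = []
    for name in order:
        touching = [s for s in live if name in s]
        cluster = frozenset().union(*touching) if touching else frozenset({name})
        clusters.append(cluster)
        live = [s for s in live if name not in s]
        live.append(cluster - {name})
    return WidthReport(tuple(order), tuple(clusters))


def order_width(
    model: Model, order: Order | Sequence[str], evidence: Iterable[str] = ()
) -> WidthReport:
    """Width of an elimination order on a model, with evidence indicators.

    Simulates the factor scopes of variable elimination: each CPT
    contributes its scope, and each evidence variable contributes a
    singleton indicator scope.
    """
    names = tuple(order.names if isinstance(order, Order) else order)
    if set(names) != set(model.variables) or len(names) != len(model.variables):
        raise ValueError("order is not a permutation of the model's variables")
    scopes: list[set[str]] = [
        set(model.parents[n]) | {n} for n in model.variables
    ]
    for e in evidence:
        if e not in model.variables:
            raise ValueError(f"evidence names unknown variable {e!r}")
        scopes.append({e})
    return scope_width(scopes, names)


# ----------------------------------------------------------------------
# lifted orders for objective models


def _bracket(name: str, world: int) -> str:
    return "[" * world + name + "]" * world


def lift_order(
    order: Order | Sequence[str],
    units: Iterable[str],
    n: int,
    *,
    exogenous: Iterable[str],
    constrained: bool = False,
    worlds: Sequence[int] = (0, 1, 2),
    clamps: Sequence[str] = (),
    h_name: str = "H",
) -> Order:
    """Lift a base-model order to an order for an n-component objective model.

    Every non-unit endogenous variable X expands to its per-component world
    copies (X1..Xn, then [X1]..[Xn], then [[X1]]..[[Xn]] for the default
    three worlds; two worlds under the twin optimization), every non-unit
    exogenous variable to its per-component copies A1..An, while unit
    variables stay put.  Equality-clamp nodes are appended just before the
    mixture variable H, which goes last (unconstrained) or just before the
    unit block (constrained).
    """
    names = tuple(order.names if isinstance(order, Order) else order)
    unit_set = set(units)
    exo = set(exogenous)
    lifted: list[str] = []
    for name in names:
        if name in unit_set:
            lifted.append(name)
        elif name in exo:
            lifted.extend(f"{name}{i}" for i in range(1, n + 1))
        else:
            for w in worlds:
                lifted.extend(_bracket(f"{name}{i}", w) for i in range(1, n + 1))
    if constrained:
        k = sum(1 for name in names if name in unit_set)
        if k and set(names[-k:]) != unit_set:
            raise ConstraintError("base order is not unit-constrained")
        cut = len(lifted) - k
        lifted = lifted[:cut] + list(clamps) + [h_name] + lifted[cut:]
        return Order(tuple(lifted), tuple(names[-k:]) if k else ())
    lifted = lifted + list(clamps) + [h_name]
    return Order(tuple(lifted))


def is_external(model: Model, units: Iterable[str]) -> bool:
    """True when removing the (root) unit variables leaves the DAG connected.

    External units force every unit-constrained order to have width at
    least the number of units.
    """
    unit_set = set(units)
    roots = set(model.roots)
    bad = unit_set - roots
    if bad:
        raise ValueError(f"units must be roots; {sorted(bad)} are not")
    skeleton = model.graph().to_undirected()
    if len(skeleton) and not nx.is_connected(skeleton):
        raise ValueError("model graph must be connected")
    skeleton.remove_nodes_from(unit_set)
    if len(skeleton) == 0:
        return False
    return nx.is_connected(skeleton)


def exhaustive_treewidth(
    model: Model, constraint: Iterable[str] | None = None, evidence: Iterable[str] = ()
) -> int:
    """Exact (constrained) treewidth by brute-force search over orders.

    Only feasible for small models; serves as an oracle for minfill.
    """
    targets = tuple(constraint or ())
    others = [n for n in model.variables if n not in set(targets)]
    best = len(model.variables)
    for prefix in itertools.permutations(others):
        for suffix in itertools.permutations(targets):
            w = order_width(model, prefix + suffix, evidence).width
            best = min(best, w)
    return best
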
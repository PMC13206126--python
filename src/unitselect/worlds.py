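"""Parallel-worlds models: twins, triplets and mutilation.

A counterfactual probability such as Pr(y_x, w_v | e) on an SCM reduces to
an observational probability on a multi-world model: several copies of the
SCM joined so they share their exogenous variables, with the intervened
copies mutilated (incoming edges removed and a point prior installed).
World 0 is the real world carrying the evidence; worlds 1 and 2 carry the
two counterfactual arms and their copies are written [X] and [[X]].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .factors import Factor, Instantiation, Variable
from .model import Model, ModelValidationError

__all__ = [
    "WorldModel",
    "world_name",
    "build_worlds",
    "mutilate",
    "counterfactual_query",
    "ZeroEvidenceError",
]


class ZeroEvidenceError(ValueError):
    """Conditioning on a zero-probability event was requested."""


def world_name(name: str, world: int, suffix: str = "") -> str:
    """Name of the copy of ``name`` in a given world.

    World 0 keeps the base name, world 1 wraps it in single brackets and
    world 2 in double brackets; ``suffix`` tags per-component copies.
    """
    return "[" * world + f"{name}{suffix}" + "]" * world


@dataclass(frozen=True)
class WorldModel:
    """A joined multi-world SCM plus the bookkeeping to navigate it."""

    model: Model
    base: Model
    worlds: tuple[int, ...]
    shared: tuple[str, ...]
    name_maps: Mapping[int, Mapping[str, str]]  # world -> base name -> copy name
    shared_map: Mapping[str, str]  # base root name -> shared node name
    interventions: Mapping[int, Mapping[str, str]]

    def name_of(self, base_name: str, world: int = 0) -> str:
        world_map = self.name_maps.get(world, {})
        if base_name in world_map:
            return world_map[base_name]
        return self.shared_map[base_name]

    def to_json(self) -> dict:
        data = self.model.to_json()
        data["worlds"] = {
            "worlds": list(self.worlds),
            "shared": list(self.shared),
            "interventions": {str(w): dict(i) for w, i in self.interventions.items()},
        }
        return data


def _assemble(
    model: Model,
    worlds: Sequence[int],
    shared: Sequence[str],
    suffix: str = "",
    plain: Sequence[str] = (),
    interventions: Mapping[int, Instantiation] | None = None,
) -> WorldModel:
    """Join copies of ``model`` (one per world id) sharing the roots ``shared``.

    ``plain`` lists shared roots kept under their base name even when a
    suffix is in force; world-specific interventions mutilate the named
    copies.  Names must not collide with each other.
    """
    interventions = {w: dict(i) for w, i in (interventions or {}).items()}
    plain_set = set(plain)
    root_set = set(model.roots)
    bad = set(shared) - root_set
    if bad:
        raise ValueError(f"shared variables must be roots; {sorted(bad)} are not")
    for inter in interventions.values():
        model.check_instantiation(inter)

    shared_map = {
        r: (r if (r in plain_set or not suffix) else f"{r}{suffix}") for r in shared
    }
    # an intervened shared root gets a world-local clamped copy; the other
    # worlds keep the shared node
    name_maps: dict[int, dict[str, str]] = {
        w: {
            x: world_name(x, w, suffix)
            for x in model.variables
            if x not in shared_map or x in interventions.get(w, {})
        }
        for w in worlds
    }

    variables: list[Variable] = []
    parents: dict[str, tuple[str, ...]] = {}
    tables: dict[str, np.ndarray] = {}
    seen: set[str] = set()

    def add(var: Variable, ps: tuple[str, ...], table: np.ndarray) -> None:
        if var.name in seen:
            raise ModelValidationError(f"world naming collision on {var.name!r}")
        seen.add(var.name)
        variables.append(var)
        parents[var.name] = ps
        tables[var.name] = table

    for r in shared:
        base = model.variables[r]
        add(Variable(shared_map[r], base.states), (), model.cpts[r].values.copy())

    for w in worlds:
        rename = name_maps[w]
        inter = interventions.get(w, {})
        for x, var in model.variables.items():
            if x in shared_map and x not in inter:
                continue
            copy = Variable(rename[x], var.states)
            if x in inter:
                point = np.zeros(var.cardinality)
                point[var.index(inter[x])] = 1.0
                add(copy, (), point)
            else:
                ps = tuple(
                    rename.get(p, shared_map.get(p, p)) for p in model.parents[x]
                )
                add(copy, ps, model.cpts[x].values.copy())

    joined = Model(variables, parents, tables, model.kind, validate=False)
    joined.validate()
    return WorldModel(
        joined,
        model,
        tuple(worlds),
        tuple(shared),
        name_maps,
        shared_map,
        {w: dict(i) for w, i in interventions.items()},
    )


def build_worlds(
    model: Model,
    k: int = 2,
    shared: Sequence[str] | None = None,
    *,
    worlds: Sequence[int] | None = None,
    interventions: Mapping[int, Instantiation] | None = None,
) -> WorldModel:
    """Build a k-world model of an SCM sharing the given roots.

    By default all roots are shared (the usual counterfactual semantics);
    sharing a strict subset copies the remaining roots per world, giving
    the general n-world construction.
    """
    if model.kind != "scm":
        raise ModelValidationError("world models are built over SCMs")
    if k < 1:
        raise ValueError("world count must be at least 1")
    if shared is None:
        shared = model.roots
    return _assemble(
        model,
        tuple(worlds) if worlds is not None else tuple(range(k)),
        tuple(shared),
        interventions=interventions,
    )


def mutilate(model: Model, intervention: Instantiation) -> Model:
    """Sever the intervened variables from their parents and clamp them.

    Each intervened node loses all parents and its table becomes a point
    prior on the intervened state; every other table is unchanged.
    """
    model.check_instantiation(intervention)
    out = model.copy()
    for name, state in intervention.items():
        var = out.variables[name]
        point = np.zeros(var.cardinality)
        point[var.index(state)] = 1.0
        out.parents[name] = ()
        out.cpts[name] = Factor((var,), point, check=False)
    out.validate()
    return out


def counterfactual_query(
    model: Model,
    do1: Instantiation | None = None,
    out1: Instantiation | None = None,
    do2: Instantiation | None = None,
    out2: Instantiation | None = None,
    evidence: Instantiation | None = None,
    *,
    force_triplet: bool = False,
) -> float:
    """Pr(out1 under do(do1), out2 under do(do2) | evidence) on an SCM.

    Builds the smallest sufficient parallel-worlds model (twin when the
    evidence or one arm is empty, triplet otherwise, always triplet when
    forced), mutilates the counterfactual worlds, and evaluates the
    corresponding observational conditional by variable elimination.
    Conditioning on a zero-probability event raises
    :class:`ZeroEvidenceError` rather than silently returning 0.
    """
    from .inference import marginal  # local import to avoid a cycle

    do1, out1 = dict(do1 or {}), dict(out1 or {})
    do2, out2 = dict(do2 or {}), dict(out2 or {})
    evidence = dict(evidence or {})
    for inst in (do1, out1, do2, out2, evidence):
        model.check_instantiation(inst)
    for do, out in ((do1, out1), (do2, out2)):
        clash = set(do) & set(out)
        if clash:
            raise ValueError(
                f"treatments and outcomes overlap within an arm: {sorted(clash)}"
            )

    root_set = set(model.roots)
    needs_real = force_triplet or any(v not in root_set for v in evidence)
    worlds: list[int] = []
    if needs_real:
        worlds.append(0)
    if force_triplet or do1 or out1:
        worlds.append(1)
    if force_triplet or do2 or out2:
        worlds.append(2)
    if not worlds:
        raise ValueError("query names no outcomes, interventions or evidence worlds")

    wm = _assemble(
        model,
        worlds,
        model.roots,
        interventions={w: i for w, i in ((1, do1), (2, do2)) if i and w in worlds},
    )

    cond: dict[str, str] = {}
    for name, state in evidence.items():
        cond[wm.name_of(name, 0)] = state
    for name, state in do1.items():
        cond[wm.name_of(name, 1)] = state
    for name, state in do2.items():
        cond[wm.name_of(name, 2)] = state
    outcome: dict[str, str] = {}
    for name, state in out1.items():
        outcome[wm.name_of(name, 1)] = state
    for name, state in out2.items():
        outcome[wm.name_of(name, 2)] = state
    overlap = set(outcome) & set(cond)
    for name in overlap:
        if outcome[name] != cond[name]:
            return 0.0
        del outcome[name]

    denominator = marginal(wm.model, cond)
    if denominator <= 0.0:
        raise ZeroEvidenceError(
            "conditioning event has probability zero; the counterfactual "
            "conditional is undefined"
        )
    numerator = marginal(wm.model, {**cond, **outcome})
    return numerator / denominator
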
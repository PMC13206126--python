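"""Causal objective functions and their reduction to a single query.

An objective L(u) = Σᵢ wᵢ · Pr(yᵢ under do(xᵢ), wᵢ under do(vᵢ) | eᵢ, u)
is a weighted sum of counterfactual probabilities sharing the unit
variables U.  The *objective model* joins one parallel-worlds model per
component through the shared units and adds a mixture variable H whose
prior carries the (normalized) weights; the CPTs of the outcome copies
are rewritten so that, conditional on H = hᵢ, only component i behaves
stochastically while every other component's outcomes are clamped to
their target states.  L(u) then equals Σwᵢ · Pr′(e1 | u, e2) for the
evidence split e1 = outcome states, e2 = interventions ∪ component
evidence ∪ equality clamps, turning unit selection into a Reverse-MAP
query.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .factors import Instantiation, Variable
from .model import Model, ModelValidationError, UnknownVariableError
from .worlds import ZeroEvidenceError, counterfactual_query, world_name

__all__ = [
    "ObjectiveComponent",
    "ObjectiveFunction",
    "ObjectiveModel",
    "build_objective_model",
    "objective_query",
    "evaluate_objective_brute",
    "brute_select",
    "benefit_function",
    "multi_treatment_objective",
    "objective_to_json",
    "objective_from_json",
    "ObjectiveError",
]


class ObjectiveError(ValueError):
    """The objective function violates a structural requirement."""


@dataclass(frozen=True)
class ObjectiveComponent:
    """One weighted counterfactual term of an objective function.

    ``do1``/``out1`` are the intervention and outcome of the first
    counterfactual arm, ``do2``/``out2`` of the second; ``evidence`` is
    real-world evidence.  Any of the arms or the evidence may be empty.
    """

    weight: float
    do1: Mapping[str, str] = field(default_factory=dict)
    out1: Mapping[str, str] = field(default_factory=dict)
    do2: Mapping[str, str] = field(default_factory=dict)
    out2: Mapping[str, str] = field(default_factory=dict)
    evidence: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ObjectiveError("component weights must be non-negative")
        for name in ("do1", "out1", "do2", "out2", "evidence"):
            object.__setattr__(self, name, dict(getattr(self, name)))
        treatments = set(self.do1) | set(self.do2)
        outcomes = set(self.out1) | set(self.out2)
        clash = treatments & outcomes
        if clash:
            raise ObjectiveError(
                f"treatment and outcome variables must be disjoint; got {sorted(clash)}"
            )
        if not outcomes:
            raise ObjectiveError("a component needs at least one outcome variable")


@dataclass(frozen=True)
class ObjectiveFunction:
    """Shared unit variables plus n weighted counterfactual components."""

    units: tuple[str, ...]
    components: tuple[ObjectiveComponent, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "units", tuple(self.units))
        object.__setattr__(self, "components", tuple(self.components))
        if not self.units:
            raise ObjectiveError("at least one unit variable is required")
        if not self.components:
            raise ObjectiveError("at least one component is required")
        if len(set(self.units)) != len(self.units):
            raise ObjectiveError("duplicate unit variables")

    @property
    def weight_sum(self) -> float:
        return float(sum(c.weight for c in self.components))

    def validate(self, model: Model) -> None:
        """Check the structural constraints of the objective against a model."""
        graph = model.graph()
        unit_set = set(self.units)
        for u in self.units:
            if u not in model.variables:
                raise UnknownVariableError(f"unknown unit variable {u!r}")
        root_set = set(model.roots)
        forbidden: set[str] = set()
        for comp in self.components:
            for inst in (comp.do1, comp.out1, comp.do2, comp.out2, comp.evidence):
                model.check_instantiation(inst)
                for name in inst:
                    if name in unit_set:
                        raise ObjectiveError(
                            f"unit variable {name!r} used as treatment/outcome/evidence"
                        )
                    if name in root_set:
                        raise ObjectiveError(
                            f"variable {name!r} must be endogenous to appear in a component"
                        )
            forbidden |= set(comp.do1) | set(comp.do2) | set(comp.out1) | set(comp.out2)
        for var in forbidden:
            bad = unit_set & nx.descendants(graph, var)
            if bad:
                raise ObjectiveError(
                    f"unit variables {sorted(bad)} are descendants of "
                    f"treatment/outcome variable {var!r}"
                )
        if self.weight_sum <= 0:
            raise ObjectiveError("all component weights are zero")


@dataclass
class ObjectiveModel:
    """The joined meta-model and the Reverse-MAP query it supports."""

    model: Model
    base: Model
    objective: ObjectiveFunction
    targets: tuple[str, ...]  # query targets within the objective model
    target_to_unit: dict[str, str]
    e1: dict[str, str]  # outcome evidence (before the conditioning bar)
    e2: dict[str, str]  # interventions, component evidence, equality clamps
    weight_sum: float
    h_name: str
    clamp_names: tuple[str, ...]
    worlds_per_component: tuple[tuple[int, ...], ...]

    @property
    def n(self) -> int:
        return len(self.objective.components)


def _component_worlds(
    comp: ObjectiveComponent, has_internal_units: bool, force_triplet: bool
) -> tuple[int, ...]:
    worlds: list[int] = []
    if force_triplet or comp.evidence or has_internal_units:
        worlds.append(0)
    if force_triplet or comp.do1 or comp.out1:
        worlds.append(1)
    if force_triplet or comp.do2 or comp.out2:
        worlds.append(2)
    return tuple(worlds)


def build_objective_model(
    model: Model,
    objective: ObjectiveFunction,
    *,
    force_triplet: bool = False,
    h_name: str = "H",
) -> ObjectiveModel:
    """Construct the objective model and its Reverse-MAP evidence split.

    Each component contributes the smallest sufficient parallel-worlds
    model (twin when its evidence is empty, triplet otherwise, always
    triplet when forced); root units are shared as single nodes, internal
    units get one equality-constraint child clamped in e2; the mixture
    variable H (prior wᵢ/Σw) parents every outcome copy.
    """
    if model.kind != "scm":
        raise ModelValidationError("objective models are built over SCMs")
    objective.validate(model)
    comps = objective.components
    n = len(comps)
    s = objective.weight_sum
    root_set = set(model.roots)
    unit_roots = [u for u in objective.units if u in root_set]
    internal_units = [u for u in objective.units if u not in root_set]
    worlds_per_comp = tuple(
        _component_worlds(c, bool(internal_units), force_triplet) for c in comps
    )

    variables: list[Variable] = []
    parents: dict[str, tuple[str, ...]] = {}
    tables: dict[str, np.ndarray] = {}
    seen: set[str] = set()

    def add(var: Variable, ps: tuple[str, ...], table: np.ndarray) -> None:
        if var.name in seen:
            raise ModelValidationError(f"objective-model naming collision on {var.name!r}")
        seen.add(var.name)
        variables.append(var)
        parents[var.name] = ps
        tables[var.name] = table

    # shared unit roots keep their base names
    for u in unit_roots:
        base = model.variables[u]
        add(Variable(u, base.states), (), model.cpts[u].values.copy())

    # mixture variable
    h_var = Variable(h_name, tuple(f"h{i}" for i in range(1, n + 1)))
    add(h_var, (), np.array([c.weight / s for c in comps]))

    def copy_name(base_name: str, comp_idx: int, world: int) -> str:
        if base_name in unit_roots:
            return base_name
        if base_name in root_set:
            return f"{base_name}{comp_idx}"
        return world_name(base_name, world, str(comp_idx))

    e1: dict[str, str] = {}
    e2: dict[str, str] = {}

    for ci, comp in enumerate(comps, start=1):
        worlds = worlds_per_comp[ci - 1]
        interventions = {1: comp.do1, 2: comp.do2}
        outcomes = {1: comp.out1, 2: comp.out2}
        # non-unit roots: one copy per component, shared across its worlds
        for r in model.roots:
            if r in unit_roots:
                continue
            base = model.variables[r]
            add(Variable(f"{r}{ci}", base.states), (), model.cpts[r].values.copy())
        for x in model.endogenous:
            base = model.variables[x]
            for w in worlds:
                name = copy_name(x, ci, w)
                var = Variable(name, base.states)
                do_w = interventions.get(w, {})
                if x in do_w:
                    point = np.zeros(var.cardinality)
                    point[var.index(do_w[x])] = 1.0
                    add(var, (), point)
                    e2[name] = do_w[x]
                    continue
                ps = tuple(copy_name(p, ci, w) for p in model.parents[x])
                table = model.cpts[x].values
                if x in outcomes.get(w, {}):
                    zi = base.index(outcomes[w][x])
                    forced = np.zeros_like(table)
                    forced[..., zi] = 1.0
                    stacked = np.stack(
                        [table if j == ci - 1 else forced for j in range(n)], axis=0
                    )
                    add(var, (h_name,) + ps, stacked)
                    e1[name] = outcomes[w][x]
                else:
                    add(var, ps, table.copy())
        for ename, estate in comp.evidence.items():
            e2[copy_name(ename, ci, 0)] = estate

    # equality-constraint children for internal unit variables
    clamp_names: list[str] = []
    for u in internal_units:
        copies = tuple(copy_name(u, ci, 0) for ci in range(1, n + 1))
        eq_name = f"EQ_{u}"
        while eq_name in seen:
            eq_name += "_"
        k = model.variables[u].cardinality
        table = np.zeros((k,) * n + (2,))
        for idx in np.ndindex(*(k,) * n):
            same = len(set(idx)) == 1
            table[idx + (0,)] = 1.0 if same else 0.0
            table[idx + (1,)] = 0.0 if same else 1.0
        add(Variable(eq_name, ("eq", "neq")), copies, table)
        clamp_names.append(eq_name)
        e2[eq_name] = "eq"

    joined = Model(variables, parents, tables, "scm", validate=False)
    joined.validate()

    targets: list[str] = []
    target_to_unit: dict[str, str] = {}
    for u in objective.units:
        t = u if u in unit_roots else copy_name(u, 1, 0)
        targets.append(t)
        target_to_unit[t] = u
    return ObjectiveModel(
        joined,
        model,
        objective,
        tuple(targets),
        target_to_unit,
        e1,
        e2,
        s,
        h_name,
        tuple(clamp_names),
        worlds_per_comp,
    )


def objective_query(om: ObjectiveModel) -> tuple[tuple[str, ...], dict, dict]:
    """The Reverse-MAP query (targets, e1, e2) encoded by an objective model.

    Maximizing Pr′(e1 | u, e2) over u and rescaling by Σwᵢ yields L(u*).
    """
    return om.targets, dict(om.e1), dict(om.e2)


# ----------------------------------------------------------------------
# brute-force reference


def evaluate_objective_brute(
    model: Model, objective: ObjectiveFunction, unit: Instantiation
) -> float:
    """L(u) by evaluating every component as a separate counterfactual query.

    The reference oracle: Σᵢ wᵢ · Pr(out1ᵢ under do1ᵢ, out2ᵢ under do2ᵢ |
    eᵢ, u).  A unit whose conditioning event has probability zero scores 0.
    """
    missing = set(objective.units) - set(unit)
    if missing:
        raise ValueError(f"unit instantiation must cover {sorted(missing)}")
    total = 0.0
    for comp in objective.components:
        evidence = {**comp.evidence, **{k: unit[k] for k in objective.units}}
        try:
            p = counterfactual_query(
                model, comp.do1, comp.out1, comp.do2, comp.out2, evidence
            )
        except ZeroEvidenceError:
            return 0.0
        total += comp.weight * p
    return total


def brute_select(
    model: Model, objective: ObjectiveFunction
) -> tuple[float, dict[str, str], dict[tuple[str, ...], float]]:
    """Exhaustive unit selection: every unit scored by the brute oracle.

    Iterates units in odometer order over the declared unit variables and
    their state orders; the first maximum wins.
    """
    import itertools

    state_lists = [model.variables[u].states for u in objective.units]
    best_score, best_unit = -1.0, None
    table: dict[tuple[str, ...], float] = {}
    for states in itertools.product(*state_lists):
        unit = dict(zip(objective.units, states))
        score = evaluate_objective_brute(model, objective, unit)
        table[states] = score
        if score > best_score + 1e-15:
            best_score, best_unit = score, unit
    return best_score, best_unit, table


# ----------------------------------------------------------------------
# objective templates


def benefit_function(
    treatment: str,
    outcome: str,
    units: Sequence[str],
    beta: float = 1.0,
    gamma: float = 0.0,
    theta: float = 0.0,
    delta: float = 0.0,
    *,
    treated: str = "1",
    untreated: str = "0",
    success: str = "1",
    failure: str = "0",
) -> ObjectiveFunction:
    """The four-component benefit function over one treatment and one outcome.

    β weighs responders (y under x, y′ under x′), γ always-takers, θ
    always-deniers and δ contrarians.  With β = γ = θ = δ = 1 the four
    response types partition the outcome space and every unit scores 1.
    """
    x, x_ = {treatment: treated}, {treatment: untreated}
    y, y_ = {outcome: success}, {outcome: failure}
    return ObjectiveFunction(
        tuple(units),
        (
            ObjectiveComponent(beta, do1=x, out1=y, do2=x_, out2=y_),
            ObjectiveComponent(gamma, do1=x, out1=y, do2=x_, out2=y),
            ObjectiveComponent(theta, do1=x, out1=y_, do2=x_, out2=y_),
            ObjectiveComponent(delta, do1=x, out1=y_, do2=x_, out2=y),
        ),
    )


def multi_treatment_objective(
    treatments: Sequence[tuple[str, str, float]],
    outcome: tuple[str, str],
    evidence: Mapping[str, str],
    units: Sequence[str],
) -> ObjectiveFunction:
    """One component per candidate intervention, sharing outcome and evidence.

    ``treatments`` lists (variable, intervened state, weight) triples; each
    component asks for the probability that the outcome variable would take
    its target state under that single intervention, given the shared
    real-world evidence.
    """
    out_var, out_state = outcome
    comps = tuple(
        ObjectiveComponent(
            w, do1={t: ts}, out1={out_var: out_state}, evidence=dict(evidence)
        )
        for t, ts, w in treatments
    )
    return ObjectiveFunction(tuple(units), comps)


# ----------------------------------------------------------------------
# JSON I/O


def objective_to_json(objective: ObjectiveFunction) -> dict:
    return {
        "units": list(objective.units),
        "components": [
            {
                "weight": c.weight,
                "do1": dict(c.do1),
                "out1": dict(c.out1),
                "do2": dict(c.do2),
                "out2": dict(c.out2),
                "evidence": dict(c.evidence),
            }
            for c in objective.components
        ],
    }


def objective_from_json(data: Mapping) -> ObjectiveFunction:
    comps = tuple(
        ObjectiveComponent(
            float(c["weight"]),
            c.get("do1", {}),
            c.get("out1", {}),
            c.get("do2", {}),
            c.get("out2", {}),
            c.get("evidence", {}),
        )
        for c in data["components"]
    )
    return ObjectiveFunction(tuple(data["units"]), comps)


def save_objective(objective: ObjectiveFunction, path) -> None:
    with open(path, "w") as fh:
        json.dump(objective_to_json(objective), fh, indent=1)


def load_objective(path) -> ObjectiveFunction:
    with open(path) as fh:
        return objective_from_json(json.load(fh))
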
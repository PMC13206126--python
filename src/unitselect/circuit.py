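"""Decision arithmetic circuits compiled from variable elimination.

Compiling the VE computation symbolically yields a circuit whose sum
nodes all have the decision form Σ_x λ_x · n_x for the states x of the
variable being eliminated.  Such circuits are decomposable, smooth and
deterministic, and when compiled along a target-constrained order they
remain deterministic after projecting on the targets, which enables
linear-time MAP (sums over target-dependent nodes become maxima) and
linear-time Reverse-MAP (a single bottom-up pass carrying a pair of
values per target-independent node and dividing on the fly).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .elimination import Order, minfill_order
from .factors import Instantiation, Variable
from .model import Model
from .worlds import ZeroEvidenceError

__all__ = [
    "Circuit",
    "IndicatorNode",
    "ParamNode",
    "SumNode",
    "ProductNode",
    "PropertyReport",
    "compile_ac",
    "check_properties",
    "evaluate",
    "map_ac",
    "rmap_ac",
    "quotient_parametrization",
    "save_circuit",
    "load_circuit",
    "CircuitError",
]


class CircuitError(ValueError):
    pass


class _Node:
    __slots__ = ("id",)


class IndicatorNode(_Node):
    __slots__ = ("var", "state_idx")

    def __init__(self, var: Variable, state_idx: int) -> None:
        self.var = var
        self.state_idx = state_idx

    @property
    def state(self) -> str:
        return self.var.states[self.state_idx]


class ParamNode(_Node):
    __slots__ = ("value", "index")

    def __init__(self, value: float, index: int) -> None:
        self.value = float(value)
        self.index = index  # position in Circuit.param_values


class SumNode(_Node):
    __slots__ = ("children", "dvar")

    def __init__(self, children: Sequence[_Node], dvar: Variable) -> None:
        self.children = tuple(children)
        self.dvar = dvar


class ProductNode(_Node):
    __slots__ = ("children",)

    def __init__(self, children: Sequence[_Node]) -> None:
        self.children = tuple(children)


@dataclass
class Circuit:
    """A rooted DAG of sum/product/indicator/parameter nodes.

    ``nodes`` is topologically ordered (children before parents) and
    ``param_values`` holds the current parametrization, one entry per
    parameter node; reparametrizing shares the structure.
    """

    nodes: list
    root: _Node
    params: list
    param_values: np.ndarray
    variables: tuple[Variable, ...]
    targets: tuple[str, ...] = ()

    @property
    def size(self) -> int:
        """Node count plus edge count: the cost measure of circuit traversals."""
        edges = sum(
            len(n.children) for n in self.nodes if isinstance(n, (SumNode, ProductNode))
        )
        return len(self.nodes) + edges

    def with_params(self, values: np.ndarray) -> "Circuit":
        values = np.asarray(values, dtype=float)
        if values.shape != self.param_values.shape:
            raise CircuitError("parametrization has wrong length")
        return Circuit(
            self.nodes, self.root, self.params, values, self.variables, self.targets
        )

    def depends_on(self, names: Iterable[str]) -> np.ndarray:
        """Per-node flag: does the subcircuit mention any of ``names``?"""
        name_set = set(names)
        dep = np.zeros(len(self.nodes), dtype=bool)
        for node in self.nodes:
            if isinstance(node, IndicatorNode):
                dep[node.id] = node.var.name in name_set
            elif isinstance(node, (SumNode, ProductNode)):
                dep[node.id] = any(dep[c.id] for c in node.children)
        return dep

    def vars_below(self) -> list[set]:
        """Per-node set of variables mentioned by indicators in the subcircuit."""
        out: list[set] = [set() for _ in self.nodes]
        for node in self.nodes:
            if isinstance(node, IndicatorNode):
                out[node.id] = {node.var.name}
            elif isinstance(node, (SumNode, ProductNode)):
                acc: set = set()
                for c in node.children:
                    acc |= out[c.id]
                out[node.id] = acc
        return out


class _Builder:
    def __init__(self) -> None:
        self.nodes: list = []
        self.params: list = []
        self.indicators: dict[tuple[str, int], IndicatorNode] = {}

    def _register(self, node: _Node) -> _Node:
        node.id = len(self.nodes)
        self.nodes.append(node)
        return node

    def indicator(self, var: Variable, state_idx: int) -> IndicatorNode:
        key = (var.name, state_idx)
        if key not in self.indicators:
            node = IndicatorNode(var, state_idx)
            self._register(node)
            self.indicators[key] = node
        return self.indicators[key]

    def param(self, value: float) -> ParamNode:
        node = ParamNode(value, len(self.params))
        self._register(node)
        self.params.append(node)
        return node

    def product(self, children: Sequence[_Node]) -> _Node:
        flat: list[_Node] = []
        for c in children:
            if isinstance(c, ProductNode):
                flat.extend(c.children)  # splice: intermediates are consumed once
            else:
                flat.append(c)
        if len(flat) == 1:
            return flat[0]
        return self._register(ProductNode(flat))

    def sum(self, children: Sequence[_Node], dvar: Variable) -> SumNode:
        return self._register(SumNode(children, dvar))


def compile_ac(
    model: Model, targets: Sequence[str] = (), order: Order | None = None
) -> Circuit:
    """Compile a model into a decision-AC by symbolic variable elimination.

    Eliminating variable V turns each reduced-scope entry into the sum
    Σ_v λ_v · n_v over all states of V (a smooth decision node with
    dvar = V); CPT entries become parameter nodes and multiplications
    become product nodes.  A target-constrained order guarantees that no
    target-decision sum sits below a non-target one, so the circuit
    supports linear-time MAP and Reverse-MAP over the targets.
    """
    targets = tuple(targets)
    if order is None:
        order = minfill_order(model, targets)
    if set(order.names) != set(model.variables):
        raise CircuitError("order is not a permutation of the model's variables")
    order.split(targets)  # raises ConstraintError if not target-constrained

    b = _Builder()
    factors: list[tuple[tuple[Variable, ...], np.ndarray]] = []
    for name in model.variables:
        cpt = model.cpts[name]
        arr = np.empty(cpt.values.shape, dtype=object)
        for idx in np.ndindex(*cpt.values.shape):
            arr[idx] = b.param(cpt.values[idx])
        factors.append((cpt.scope, arr))

    for name in order.names:
        gathered = [(i, s, a) for i, (s, a) in enumerate(factors) if any(v.name == name for v in s)]
        if not gathered:
            continue
        var = next(v for _, s, _ in gathered for v in s if v.name == name)
        union: list[Variable] = []
        for _, s, _ in gathered:
            union.extend(v for v in s if v.name != name and all(u.name != v.name for u in union))
        pos = {v.name: i for i, v in enumerate(union)}
        shape = tuple(v.cardinality for v in union)
        out = np.empty(shape, dtype=object)
        extractors = []
        for _, s, a in gathered:
            axes = [(pos[v.name] if v.name != name else -1) for v in s]
            extractors.append((axes, a))
        for idx in np.ndindex(*shape) if shape else ((),):
            terms = []
            for v_idx in range(var.cardinality):
                children: list[_Node] = [b.indicator(var, v_idx)]
                for axes, a in extractors:
                    sub = tuple(v_idx if ax < 0 else idx[ax] for ax in axes)
                    children.append(a[sub])
                terms.append(b.product(children))
            out[idx] = b.sum(terms, var)
        keep = [f for i, f in enumerate(factors) if i not in {g[0] for g in gathered}]
        factors = keep + [(tuple(union), out)]

    residual = [a[()] for _, a in factors]
    root = b.product(residual) if len(residual) != 1 else residual[0]
    if not isinstance(root, (SumNode, ProductNode, ParamNode, IndicatorNode)):
        raise CircuitError("compilation produced no root")  # pragma: no cover
    values = np.array([p.value for p in b.params])
    return Circuit(b.nodes, root, b.params, values, tuple(model.variables.values()), targets)


# ----------------------------------------------------------------------
# evaluation


def _indicator_value(node: IndicatorNode, e: Mapping[str, str]) -> float:
    state = e.get(node.var.name)
    return 1.0 if state is None or node.var.index(state) == node.state_idx else 0.0


def evaluate(ac: Circuit, e: Instantiation | None = None) -> float:
    """Bottom-up circuit value at (possibly partial) evidence e.

    Indicators incompatible with e become 0, all others 1; for a
    decomposable and smooth circuit representing Pr this returns the
    marginal Pr(e), and the joint probability at full instantiations.
    """
    e = dict(e or {})
    vals = np.empty(len(ac.nodes))
    for node in ac.nodes:
        if isinstance(node, IndicatorNode):
            vals[node.id] = _indicator_value(node, e)
        elif isinstance(node, ParamNode):
            vals[node.id] = ac.param_values[node.index]
        elif isinstance(node, SumNode):
            vals[node.id] = sum(vals[c.id] for c in node.children)
        else:
            vals[node.id] = np.prod([vals[c.id] for c in node.children])
    return float(vals[ac.root.id])


# ----------------------------------------------------------------------
# property checking


@dataclass
class PropertyReport:
    decomposable: bool
    smooth: bool
    decision: bool
    prop1_order: bool  # no target-decision sum below a non-target-decision sum
    prop1_indicators: bool  # every indicator attached at a decision node of its var
    u_deterministic: bool | None  # empirical, None when the unit space is too large
    violations: list = field(default_factory=list)

    @property
    def all_ok(self) -> bool:
        checks = [
            self.decomposable,
            self.smooth,
            self.decision,
            self.prop1_order,
            self.prop1_indicators,
        ]
        if self.u_deterministic is not None:
            checks.append(self.u_deterministic)
        return all(checks)


def check_properties(
    ac: Circuit, targets: Sequence[str] = (), max_unit_space: int = 16
) -> PropertyReport:
    """Structural and empirical checks of the decision-AC contracts.

    Decomposability, smoothness and the decision property are verified
    structurally, as are the two ordering/attachment conditions required
    for linear-time MAP.  Determinism after projecting on the targets is
    verified empirically by evaluating the circuit at every unit input
    when the unit space has at most ``max_unit_space`` instantiations.
    """
    targets = tuple(targets) or ac.targets
    vars_below = ac.vars_below()
    violations: list[str] = []
    decomposable = smooth = decision = True
    attached: set[int] = set()

    for node in ac.nodes:
        if isinstance(node, ProductNode):
            seen: set = set()
            for c in node.children:
                if vars_below[c.id] & seen:
                    decomposable = False
                    violations.append(f"product {node.id} repeats {vars_below[c.id] & seen}")
                seen |= vars_below[c.id]
        elif isinstance(node, SumNode):
            sets = [frozenset(vars_below[c.id]) for c in node.children]
            if len(set(sets)) > 1:
                smooth = False
                violations.append(f"sum {node.id} has unequal child scopes")
            states_seen: set[int] = set()
            for c in node.children:
                inds = (
                    [c]
                    if isinstance(c, IndicatorNode)
                    else [
                        g
                        for g in (c.children if isinstance(c, ProductNode) else ())
                        if isinstance(g, IndicatorNode) and g.var.name == node.dvar.name
                    ]
                )
                inds = [i for i in inds if isinstance(i, IndicatorNode) and i.var.name == node.dvar.name]
                if len(inds) != 1 or inds[0].state_idx in states_seen:
                    decision = False
                    violations.append(f"sum {node.id} is not a decision on {node.dvar.name}")
                    break
                states_seen.add(inds[0].state_idx)
                attached.add(inds[0].id)

    prop1_indicators = all(
        node.id in attached for node in ac.nodes if isinstance(node, IndicatorNode)
    )
    if not prop1_indicators:
        violations.append("indicator not attached at a decision node of its variable")

    target_set = set(targets)
    dep_below = np.zeros(len(ac.nodes), dtype=bool)  # any target-decision sum below
    prop1_order = True
    for node in ac.nodes:
        if isinstance(node, (SumNode, ProductNode)):
            below = any(dep_below[c.id] for c in node.children)
            if isinstance(node, SumNode):
                if node.dvar.name not in target_set and below:
                    prop1_order = False
                    violations.append(
                        f"non-target sum {node.id} sits above a target-decision sum"
                    )
                dep_below[node.id] = below or node.dvar.name in target_set
            else:
                dep_below[node.id] = below

    u_det: bool | None = None
    if target_set:
        tvars = [v for v in ac.variables if v.name in target_set]
        space = int(np.prod([v.cardinality for v in tvars])) if tvars else 0
        if 0 < space <= max_unit_space:
            import itertools

            u_det = True
            dep = ac.depends_on(target_set)
            for combo in itertools.product(*[v.states for v in tvars]):
                u = {v.name: s for v, s in zip(tvars, combo)}
                vals = np.empty(len(ac.nodes))
                for node in ac.nodes:
                    if isinstance(node, IndicatorNode):
                        vals[node.id] = _indicator_value(node, u)
                    elif isinstance(node, ParamNode):
                        vals[node.id] = ac.param_values[node.index]
                    elif isinstance(node, SumNode):
                        vals[node.id] = sum(vals[c.id] for c in node.children)
                        if dep[node.id]:
                            nonzero = sum(1 for c in node.children if vals[c.id] > 0)
                            if nonzero > 1:
                                u_det = False
                                violations.append(
                                    f"sum {node.id} has {nonzero} non-zero children at u={u}"
                                )
                    else:
                        vals[node.id] = np.prod([vals[c.id] for c in node.children])
    return PropertyReport(
        decomposable, smooth, decision, prop1_order, prop1_indicators, u_det, violations
    )


# ----------------------------------------------------------------------
# MAP and Reverse-MAP traversals


def _decode(ac: Circuit, choice: Mapping[int, int], dep: np.ndarray, targets: set) -> dict:
    """Descend through maximizing children reading decision states."""
    assignment: dict[str, str] = {}
    stack = [ac.root]
    while stack:
        node = stack.pop()
        if not dep[node.id]:
            continue
        if isinstance(node, ProductNode):
            stack.extend(node.children)
        elif isinstance(node, SumNode):
            child = node.children[choice[node.id]]
            if node.dvar.name in targets:
                picked = child if isinstance(child, IndicatorNode) else next(
                    g
                    for g in (child.children if isinstance(child, ProductNode) else (child,))
                    if isinstance(g, IndicatorNode) and g.var.name == node.dvar.name
                )
                assignment[node.dvar.name] = picked.state
            stack.append(child)
    for v in ac.variables:
        if v.name in targets:
            assignment.setdefault(v.name, v.states[0])
    return {name: assignment[name] for name in sorted(targets)}


def map_ac(
    ac: Circuit, targets: Sequence[str], e: Instantiation | None = None
) -> tuple[float, dict[str, str]]:
    """max_u Pr(u, e) in one bottom-up pass over a target-deterministic AC.

    Indicators of target variables are fixed to 1 and every sum node that
    depends on a target becomes a max node; the argmax is decoded by
    descending through maximizing children (ties to the first state).
    """
    target_set = set(targets)
    e = {k: v for k, v in (e or {}).items() if k not in target_set}
    dep = ac.depends_on(target_set)
    vals = np.empty(len(ac.nodes))
    choice: dict[int, int] = {}
    for node in ac.nodes:
        if isinstance(node, IndicatorNode):
            vals[node.id] = 1.0 if node.var.name in target_set else _indicator_value(node, e)
        elif isinstance(node, ParamNode):
            vals[node.id] = ac.param_values[node.index]
        elif isinstance(node, SumNode):
            cv = [vals[c.id] for c in node.children]
            if dep[node.id]:
                best = int(np.argmax(cv))
                choice[node.id] = best
                vals[node.id] = cv[best]
            else:
                vals[node.id] = sum(cv)
        else:
            vals[node.id] = np.prod([vals[c.id] for c in node.children])
    return float(vals[ac.root.id]), _decode(ac, choice, dep, target_set)


def rmap_ac(
    ac: Circuit,
    targets: Sequence[str],
    e1: Instantiation,
    e2: Instantiation,
) -> tuple[float, dict[str, str], dict]:
    """max_u Pr(e1 | u, e2) by the two-evidence single traversal.

    Every target-independent node carries the pair (value under e1 ∪ e2,
    value under e2); a target-dependent node consuming such a child takes
    the ratio of its pair (0/0 = 0), target-dependent sums maximize and
    products multiply.  Each node is visited exactly once, so the run is
    linear in the circuit size; visit counters are returned as evidence.
    """
    target_set = set(targets)
    if (set(e1) & target_set) or (set(e2) & target_set) or (set(e1) & set(e2)):
        raise ValueError("targets, e1 and e2 must be pairwise disjoint")
    if evaluate(ac, dict(e2)) <= 0.0:
        raise ZeroEvidenceError("Pr(e2) = 0: the Reverse-MAP conditional is undefined")

    e12 = {**e1, **e2}
    n = len(ac.nodes)
    val1 = np.empty(n)
    val2 = np.empty(n)
    val = np.empty(n)
    dep = ac.depends_on(target_set)
    visits = np.zeros(n, dtype=int)
    choice: dict[int, int] = {}

    def ratio(c) -> float:
        if dep[c.id]:
            return val[c.id]
        if val2[c.id] == 0.0:
            return 0.0  # val1 <= val2 entrywise, so this is 0/0
        return val1[c.id] / val2[c.id]

    for node in ac.nodes:
        visits[node.id] += 1
        if isinstance(node, IndicatorNode):
            if node.var.name in target_set:
                val[node.id] = 1.0
            else:
                val1[node.id] = _indicator_value(node, e12)
                val2[node.id] = _indicator_value(node, e2)
        elif isinstance(node, ParamNode):
            val1[node.id] = val2[node.id] = ac.param_values[node.index]
        elif not dep[node.id]:
            if isinstance(node, SumNode):
                val1[node.id] = sum(val1[c.id] for c in node.children)
                val2[node.id] = sum(val2[c.id] for c in node.children)
            else:
                val1[node.id] = np.prod([val1[c.id] for c in node.children])
                val2[node.id] = np.prod([val2[c.id] for c in node.children])
        else:
            ratios = [ratio(c) for c in node.children]
            if isinstance(node, SumNode):
                best = int(np.argmax(ratios))
                choice[node.id] = best
                val[node.id] = ratios[best]
            else:
                val[node.id] = float(np.prod(ratios))

    root = ac.root
    value = float(val[root.id]) if dep[root.id] else (
        ratio(root)
    )
    assignment = _decode(ac, choice, dep, target_set)
    diagnostics = {
        "visits_max": int(visits.max()),
        "visits_total": int(visits.sum()),
        "size": ac.size,
    }
    return value, assignment, diagnostics


def quotient_parametrization(ac: Circuit, theta1: np.ndarray, theta2: np.ndarray) -> Circuit:
    """Circuit computing Pr1/Pr2 by dividing corresponding parameters.

    Requires the support condition (θ2 zero implies θ1 zero along every
    complete subcircuit); parameters divide elementwise with 0/0 = 0.
    """
    t1 = np.asarray(theta1, dtype=float)
    t2 = np.asarray(theta2, dtype=float)
    if t1.shape != t2.shape or t1.shape != ac.param_values.shape:
        raise CircuitError("parametrizations must match the circuit's parameter count")
    from .factors import SupportViolationError

    if np.any((t2 == 0.0) & (t1 > 0.0)):
        raise SupportViolationError("theta1 > 0 where theta2 = 0")
    out = np.divide(t1, np.where(t2 == 0.0, 1.0, t2))
    out[t2 == 0.0] = 0.0
    return ac.with_params(out)


def select_units_ac(model: Model, objective):
    """Optimal unit and L(u*) via circuit compilation of the objective model."""
    from .objective import build_objective_model

    om = build_objective_model(model, objective)
    ac = compile_ac(om.model, om.targets)
    value, assignment, diagnostics = rmap_ac(ac, om.targets, om.e1, om.e2)
    return (
        value * om.weight_sum,
        {om.target_to_unit[k]: v for k, v in assignment.items()},
        diagnostics,
    )


# ----------------------------------------------------------------------
# line-oriented serialization


def save_circuit(ac: Circuit, path) -> None:
    """Write the circuit in a line-oriented text format (one node per line)."""
    with open(path, "w") as fh:
        fh.write(f"decision-ac {len(ac.nodes)} root {ac.root.id}\n")
        for v in ac.variables:
            fh.write("var " + v.name + " " + " ".join(v.states) + "\n")
        if ac.targets:
            fh.write("targets " + " ".join(ac.targets) + "\n")
        for node in ac.nodes:
            if isinstance(node, IndicatorNode):
                fh.write(f"{node.id} I {node.var.name} {node.state_idx}\n")
            elif isinstance(node, ParamNode):
                fh.write(f"{node.id} P {float(ac.param_values[node.index])!r}\n")
            elif isinstance(node, SumNode):
                kids = " ".join(str(c.id) for c in node.children)
                fh.write(f"{node.id} S {node.dvar.name} {kids}\n")
            else:
                kids = " ".join(str(c.id) for c in node.children)
                fh.write(f"{node.id} * {kids}\n")


def load_circuit(path) -> Circuit:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header = lines[0].split()
    if header[0] != "decision-ac":
        raise CircuitError("not a decision-ac file")
    root_id = int(header[3])
    variables: dict[str, Variable] = {}
    targets: tuple[str, ...] = ()
    b = _Builder()
    nodes: dict[int, _Node] = {}
    values: list[float] = []
    for line in lines[1:]:
        parts = line.split()
        if parts[0] == "var":
            variables[parts[1]] = Variable(parts[1], tuple(parts[2:]))
            continue
        if parts[0] == "targets":
            targets = tuple(parts[1:])
            continue
        nid, kind = int(parts[0]), parts[1]
        if kind == "I":
            node = IndicatorNode(variables[parts[2]], int(parts[3]))
            b._register(node)
        elif kind == "P":
            node = ParamNode(float(parts[2]), len(b.params))
            b._register(node)
            b.params.append(node)
            values.append(float(parts[2]))
        elif kind == "S":
            node = b.sum([nodes[int(i)] for i in parts[3:]], variables[parts[2]])
        else:
            node = b._register(ProductNode([nodes[int(i)] for i in parts[2:]]))
        nodes[nid] = node
    return Circuit(
        b.nodes,
        nodes[root_id],
        b.params,
        np.array(values),
        tuple(variables.values()),
        targets,
    )
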
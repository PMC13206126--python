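"""Variable elimination for MAP and Reverse-MAP queries.

MAP_VE sums out the non-target variables and then maximizes the targets
out of the residual factors, so it needs an elimination order that places
the targets last.  RMAP_VE runs the sum pass twice — once under evidence
e1 ∪ e2 and once under e2 alone — along the identical order, divides the
two residual factor sets pairwise (their one-to-one correspondence is
maintained structurally), and maximizes the targets out of the quotients,
yielding max_u Pr(e1 | u, e2) together with the maximizing instantiation
decoded from argmax witnesses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .elimination import Order, minfill_order, scope_width
from .factors import (
    Factor,
    Instantiation,
    Witness,
    divide,
    evidence_factor,
    max_out,
    multiply,
    ones_factor,
    product,
    sum_out,
)
from .model import Model
from .worlds import ZeroEvidenceError

MAX_EXHAUSTIVE = 4096  # unit-space bound for materializing full score tables

__all__ = [
    "InferenceResult",
    "eliminate",
    "marginal",
    "map_ve",
    "rmap_ve",
    "select_units_ve",
]


@dataclass
class InferenceResult:
    """Value and argmax of a MAP/Reverse-MAP query, plus run diagnostics."""

    value: float
    assignment: dict[str, str]
    scores: Factor | None = None
    order: Order | None = None
    width: int = -1
    diagnostics: dict = field(default_factory=dict)

    def score_table(self) -> "np.ndarray":
        if self.scores is None:
            raise ValueError("run with exhaustive=True to materialize scores")
        return self.scores.values


def eliminate(
    op: str, factors: Iterable[Factor], order: Sequence[str]
) -> tuple[list[Factor], list[Witness]]:
    """Eliminate the variables in ``order`` from a factor set by sum or max.

    For each variable, the factors mentioning it are multiplied, the
    variable is summed or maximized out, and the product's operands are
    replaced by the result.  Max elimination retains argmax witnesses for
    later decoding.  Variables mentioned by no factor are skipped.
    """
    if op not in ("sum", "max"):
        raise ValueError(f"unknown elimination operation {op!r}")
    live = list(factors)
    witnesses: list[Witness] = []
    for name in order:
        idxs = [i for i, f in enumerate(live) if f.mentions(name)]
        if not idxs:
            continue
        prod = live[idxs[0]]
        for i in idxs[1:]:
            prod = multiply(prod, live[i])
        if op == "sum":
            new = sum_out(prod, name)
        else:
            new, witness = max_out(prod, name)
            witnesses.append(witness)
        live[idxs[0]] = new
        for i in reversed(idxs[1:]):
            del live[i]
    return live, witnesses


def _evidence_factors(model: Model, e: Instantiation) -> list[Factor]:
    model.check_instantiation(e)
    return [evidence_factor(model.variables[n], s) for n, s in sorted(e.items())]


def marginal(model: Model, evidence: Instantiation, order: Order | None = None) -> float:
    """Pr(evidence) by sum-elimination of every variable."""
    factors = model.factors() + _evidence_factors(model, evidence)
    names = order.names if order is not None else minfill_order(model).names
    residual, _ = eliminate("sum", factors, names)
    return product(residual).scalar


def _decode(
    witnesses: list[Witness], targets: Sequence[str], model: Model
) -> dict[str, str]:
    """Trace argmax witnesses backwards into a full target assignment.

    Targets never touched by a witness (e.g. targets mentioned by no
    residual factor) default to their first state, the global tie rule.
    """
    assignment: dict[str, str] = {}
    for witness in reversed(witnesses):
        assignment[witness.var.name] = witness.state(assignment)
    for name in targets:
        assignment.setdefault(name, model.variables[name].states[0])
    return {name: assignment[name] for name in targets}


def _score_factor(factors: list[Factor], targets: Sequence[str], model: Model) -> Factor:
    """Product of residual factors expanded over the full target space."""
    table = product(factors)
    for name in targets:
        if not table.mentions(name):
            table = multiply(table, ones_factor(model.variables[name]))
    pos = {n: i for i, n in enumerate(targets)}
    perm = sorted(range(len(table.scope)), key=lambda a: pos[table.scope[a].name])
    return Factor(
        tuple(table.scope[a] for a in perm), np.transpose(table.values, perm), check=False
    )


def _unit_space(model: Model, targets: Sequence[str]) -> int:
    size = 1
    for name in targets:
        size *= model.variables[name].cardinality
    return size


def map_ve(
    model: Model,
    targets: Sequence[str],
    e: Instantiation,
    order: Order | None = None,
    *,
    exhaustive: bool = False,
) -> InferenceResult:
    """max_u Pr(u, e) with its maximizing instantiation (MAP).

    Requires — and checks — a target-constrained elimination order; the
    default is a constrained minfill order.
    """
    targets = tuple(targets)
    if set(targets) & set(e):
        raise ValueError("targets and evidence variables must be disjoint")
    if order is None:
        order = minfill_order(model, targets)
    prefix, suffix = order.split(targets)

    factors = model.factors() + _evidence_factors(model, e)
    width = scope_width([{v.name for v in f.scope} for f in factors], order.names).width
    summed, _ = eliminate("sum", factors, prefix)
    scores = _score_factor(summed, targets, model) if (
        exhaustive and _unit_space(model, targets) <= MAX_EXHAUSTIVE
    ) else None
    residual, witnesses = eliminate("max", summed, suffix)
    value = product(residual).scalar
    assignment = _decode(witnesses, targets, model)
    return InferenceResult(value, assignment, scores, order, width)


def rmap_ve(
    model: Model,
    targets: Sequence[str],
    e1: Instantiation,
    e2: Instantiation,
    order: Order | None = None,
    *,
    exhaustive: bool = False,
) -> InferenceResult:
    """max_u Pr(e1 | u, e2) with its maximizing instantiation (Reverse-MAP).

    Pass 1 sums out non-targets under e1 ∪ e2, pass 2 under e2 alone (the
    e1 indicators are replaced by vacuous all-ones factors so both passes
    manipulate structurally identical factor sets along the identical
    order).  The residual sets are divided pairwise with 0/0 = 0 and the
    targets are maximized out of the quotients.  Targets u with
    Pr(u, e2) = 0 score 0; if Pr(e2) itself is 0 the conditional is
    undefined and :class:`ZeroEvidenceError` is raised.
    """
    targets = tuple(targets)
    if (set(targets) & set(e1)) or (set(targets) & set(e2)) or (set(e1) & set(e2)):
        raise ValueError("targets, e1 and e2 must be pairwise disjoint")
    if order is None:
        order = minfill_order(model, targets)
    prefix, suffix = order.split(targets)

    model.check_instantiation(e1)
    lam1 = [evidence_factor(model.variables[n], s) for n, s in sorted(e1.items())]
    ones = [ones_factor(model.variables[n]) for n, _ in sorted(e1.items())]
    lam2 = _evidence_factors(model, e2)
    pass1 = model.factors() + lam1 + lam2
    pass2 = model.factors() + ones + lam2

    width = scope_width([{v.name for v in f.scope} for f in pass1], order.names).width
    g1, _ = eliminate("sum", pass1, prefix)
    g2, _ = eliminate("sum", pass2, prefix)
    if len(g1) != len(g2) or any(
        {v.name for v in a.scope} != {v.name for v in b.scope} for a, b in zip(g1, g2)
    ):  # pragma: no cover - structural invariant of the two-pass scheme
        raise AssertionError("two-pass factor correspondence broken")

    p_e2, _ = eliminate("sum", [f.copy() for f in g2], suffix)
    if product(p_e2).scalar <= 0.0:
        raise ZeroEvidenceError("Pr(e2) = 0: the Reverse-MAP conditional is undefined")

    quotients = [divide(a, b) for a, b in zip(g1, g2)]
    scores = _score_factor(quotients, targets, model) if (
        exhaustive and _unit_space(model, targets) <= MAX_EXHAUSTIVE
    ) else None
    residual, witnesses = eliminate("max", quotients, suffix)
    value = product(residual).scalar
    assignment = _decode(witnesses, targets, model)
    return InferenceResult(
        value, assignment, scores, order, width, {"factors": len(g1)}
    )


def select_units_ve(model: Model, objective, *, exhaustive: bool = False) -> InferenceResult:
    """Optimal unit and L(u*) by Reverse-MAP VE on the objective model."""
    from .objective import build_objective_model  # local import to avoid a cycle

    om = build_objective_model(model, objective)
    order = minfill_order(om.model, om.targets)
    res = rmap_ve(om.model, om.targets, om.e1, om.e2, order, exhaustive=exhaustive)
    value = res.value * om.weight_sum
    assignment = {om.target_to_unit[n]: s for n, s in res.assignment.items()}
    scores = None
    if res.scores is not None:
        from .factors import Variable

        scope = tuple(
            Variable(om.target_to_unit[v.name], v.states) for v in res.scores.scope
        )
        scores = Factor(scope, res.scores.values * om.weight_sum, check=False)
    return InferenceResult(value, assignment, scores, res.order, res.width, res.diagnostics)
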
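"""Independent brute-force oracles used to validate the inference engines.

Everything here works by exhaustive enumeration of full instantiations or
of exogenous states, never through the variable-elimination or circuit
code paths it is used to check.
"""

from __future__ import annotations

import itertools

import numpy as np

from unitselect.factors import Factor, Variable
from unitselect.model import Model


def all_instantiations(model: Model, names=None):
    names = list(names) if names is not None else list(model.variables)
    for states in itertools.product(*[model.variables[n].states for n in names]):
        yield dict(zip(names, states))


def joint_value(model: Model, inst) -> float:
    """Chain-rule joint probability of a full instantiation (BN or SCM)."""
    p = 1.0
    for name in model.variables:
        p *= model.cpts[name].value(inst)
    return p


def enum_marginal(model: Model, evidence) -> float:
    """Pr(evidence) by summing the chain-rule joint over all completions."""
    total = 0.0
    free = [n for n in model.variables if n not in evidence]
    for inst in all_instantiations(model, free):
        total += joint_value(model, {**inst, **evidence})
    return total


def brute_map(model: Model, targets, e):
    """(max_u Pr(u, e), first maximizing u in declaration-odometer order)."""
    best, best_u = -1.0, None
    for u in all_instantiations(model, targets):
        p = enum_marginal(model, {**u, **e})
        if p > best + 1e-15:
            best, best_u = p, u
    return best, best_u


def brute_rmap(model: Model, targets, e1, e2):
    """(max_u Pr(e1|u,e2), argmax, full score table); zero-mass units score 0."""
    table = {}
    best, best_u = -1.0, None
    for u in all_instantiations(model, targets):
        den = enum_marginal(model, {**u, **e2})
        num = enum_marginal(model, {**u, **e1, **e2})
        score = 0.0 if den == 0.0 else num / den
        table[tuple(u[t] for t in targets)] = score
        if score > best + 1e-15:
            best, best_u = score, u
    return best, best_u, table


def forward_sim(model: Model, exogenous, do):
    """Propagate exogenous states through the structural equations."""
    values = {**dict(exogenous), **dict(do)}
    for name in model.topological_order():
        if name in values:
            continue
        cpt = model.cpts[name]
        var = cpt.scope[-1]
        row = {p.name: values[p.name] for p in cpt.scope[:-1]}
        values[name] = next(
            s for s in var.states if cpt.value({**row, var.name: s}) > 0.5
        )
    return values


def brute_counterfactual(model: Model, do1, out1, do2, out2, evidence):
    """Pr(out1 under do1, out2 under do2 | evidence) by exogenous enumeration."""
    num = den = 0.0
    roots = model.roots
    for states in itertools.product(*[model.variables[r].states for r in roots]):
        exo = dict(zip(roots, states))
        theta = 1.0
        for r in roots:
            theta *= model.cpts[r].value(exo)
        real = forward_sim(model, exo, {})
        if any(real[k] != v for k, v in evidence.items()):
            continue
        den += theta
        w1 = forward_sim(model, exo, do1)
        w2 = forward_sim(model, exo, do2)
        if all(w1[k] == v for k, v in out1.items()) and all(
            w2[k] == v for k, v in out2.items()
        ):
            num += theta
    if den == 0.0:
        raise ZeroDivisionError("conditioning event has probability zero")
    return num / den


def brute_factor_product(f: Factor, g: Factor) -> Factor:
    """Entrywise product over the joint scope by explicit enumeration."""
    scope = f.scope + tuple(v for v in g.scope if all(u.name != v.name for u in f.scope))
    values = np.zeros(tuple(v.cardinality for v in scope))
    for idx in np.ndindex(*values.shape):
        inst = {v.name: v.states[i] for v, i in zip(scope, idx)}
        values[idx] = f.value(inst) * g.value(inst)
    return Factor(scope, values)


def random_bn(rng: np.random.Generator, n: int, max_states: int = 4) -> Model:
    """A random stochastic BN over a random DAG (for learning tests)."""
    names = [f"X{i}" for i in range(n)]
    variables = [
        Variable(name, tuple(f"s{j}" for j in range(int(rng.integers(2, max_states + 1)))))
        for name in names
    ]
    parents = {}
    tables = {}
    for i, var in enumerate(variables):
        k = int(rng.integers(0, min(i, 2) + 1))
        ps = tuple(names[j] for j in sorted(rng.choice(i, size=k, replace=False))) if k else ()
        parents[var.name] = ps
        shape = tuple(variables[names.index(p)].cardinality for p in ps)
        rows = int(np.prod(shape)) if shape else 1
        table = rng.dirichlet(np.ones(var.cardinality), size=rows)
        tables[var.name] = table.reshape(shape + (var.cardinality,))
    return Model(variables, parents, tables, "bn")


def assert_optimal(score_table, best_score, assignment, units, tol=1e-9):
    """The returned assignment must attain the brute-force optimum.

    When the optimum is unique (gap above 1e-7) the assignment must match
    the brute argmax exactly; under exact ties any optimal unit is valid.
    """
    key = tuple(assignment[u] for u in units)
    assert abs(score_table[key] - best_score) <= tol, (
        f"returned unit {key} scores {score_table[key]}, optimum is {best_score}"
    )
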
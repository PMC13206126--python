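"""Random SCM benchmarks, complexity reports and the case-study pipeline.

The generator follows the common recipe for counterfactual benchmarks:
sample a random DAG over binary nodes with a bounded in-degree, then give
every internal node a fresh, unique root parent so that all uncertainty
lives in the roots and the internal tables can be made functional.  Units
drawn among the added roots are external (removing them leaves the graph
connected), which makes the instances provably hard for constrained
elimination orders — the constrained width is then at least the number of
unit variables.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .elimination import minfill_order, order_width
from .factors import Variable
from .inference import select_units_ve
from .learn import binarize, bn_to_scm, fit_bn
from .model import Model
from .objective import (
    ObjectiveFunction,
    benefit_function,
    build_objective_model,
    multi_treatment_objective,
)
from .worlds import build_worlds, counterfactual_query

__all__ = [
    "BenchmarkSpec",
    "random_scm",
    "random_instance",
    "complexity_report",
    "case_study_pipeline",
    "InstanceError",
]

# default benefit-function weight profile: responders dominate but all four
# response types stay active, so ties are rare and every component is
# exercised by the objective model
DEFAULT_BENEFIT_WEIGHTS = (0.6, 0.2, 0.15, 0.05)


class InstanceError(RuntimeError):
    """No valid problem instance could be drawn from the sampled SCM."""


@dataclass(frozen=True)
class BenchmarkSpec:
    """Parameters of the random SCM / unit-selection instance generator.

    ``n0`` is the node count of the initial DAG before unique root parents
    are added (the final SCM has ``2·n0 − 1`` nodes); ``p`` bounds the
    in-degree; ``ur`` is the fraction of roots used as unit variables.
    """

    n0: int
    seed: int
    p: int = 6
    ur: float = 0.5
    benefit_weights: tuple[float, float, float, float] = DEFAULT_BENEFIT_WEIGHTS

    def __post_init__(self) -> None:
        if self.n0 < 1:
            raise ValueError("n0 must be positive")
        if self.p < 1:
            raise ValueError("max parent count must be at least 1")
        if not 0 < self.ur <= 1:
            raise ValueError("unit fraction must lie in (0, 1]")

    def to_json(self) -> dict:
        return asdict(self)


def random_scm(spec: BenchmarkSpec, rng: np.random.Generator | None = None) -> Model:
    """Sample a binary SCM: random DAG plus one unique root parent per internal node.

    Internal structural equations are random deterministic functions of
    all parents; root priors are drawn from a symmetric Dirichlet.  Fixed
    seeds give bit-identical models.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    names = [f"V{i}" for i in range(1, spec.n0 + 1)]
    parents: dict[str, tuple[str, ...]] = {names[0]: ()}
    for i in range(1, spec.n0):
        k = int(rng.integers(1, min(spec.p, i) + 1))
        chosen = rng.choice(i, size=k, replace=False)
        parents[names[i]] = tuple(names[j] for j in sorted(chosen))

    variables: list[Variable] = []
    tables: dict[str, np.ndarray] = {}
    order: list[str] = []
    for name in names:
        if parents[name]:
            u_name = f"U{name[1:]}"
            order.append(u_name)
            parents[u_name] = ()
            parents[name] = parents[name] + (u_name,)
        order.append(name)
    for name in order:
        variables.append(Variable(name, ("0", "1")))
        ps = parents[name]
        if not ps:
            tables[name] = rng.dirichlet(np.ones(2))
        else:
            rows = 2 ** len(ps)
            picks = rng.integers(0, 2, size=rows)
            table = np.zeros((rows, 2))
            table[np.arange(rows), picks] = 1.0
            tables[name] = table.reshape((2,) * len(ps) + (2,))
    return Model(variables, parents, tables, "scm")


def random_instance(
    spec: BenchmarkSpec, max_retries: int = 50
) -> tuple[Model, ObjectiveFunction]:
    """Sample (SCM, benefit objective): outcome Y from the leaves, treatment X
    from Y's endogenous ancestors, units among the roots.

    Unit variables are drawn from the added unique root parents first (so
    they are external by construction) and only fall back to original
    roots when the requested fraction exceeds their number.  SCMs with no
    leaf owning an endogenous ancestor are resampled with a derived seed.
    """
    import networkx as nx

    for attempt in range(max_retries):
        seed = spec.seed + attempt * 10007
        rng = np.random.default_rng(seed)
        model = random_scm(spec, rng)
        graph = model.graph()
        children = model.children()
        endo = set(model.endogenous)
        leaves = [n for n in endo if not children[n]]
        eligible = [
            (y, sorted(set(nx.ancestors(graph, y)) & endo)) for y in leaves
        ]
        eligible = [(y, xs) for y, xs in eligible if xs]
        if not eligible:
            continue
        y, xs = eligible[int(rng.integers(len(eligible)))]
        x = xs[int(rng.integers(len(xs)))]
        roots = list(model.roots)
        added = [r for r in roots if r.startswith("U")]
        original = [r for r in roots if not r.startswith("U")]
        k = min(math.ceil(spec.ur * len(roots)), len(roots))
        if k <= len(added):
            idx = rng.choice(len(added), size=k, replace=False)
            units = tuple(sorted(added[i] for i in idx))
        else:
            idx = rng.choice(len(original), size=k - len(added), replace=False)
            units = tuple(sorted(added + [original[i] for i in idx]))
        objective = benefit_function(x, y, units, *spec.benefit_weights)
        objective.validate(model)
        return model, objective
    raise InstanceError(
        f"no instance with an endogenous treatment after {max_retries} resamples"
    )


def instance_to_json(model: Model, objective: ObjectiveFunction, spec: BenchmarkSpec) -> dict:
    from .objective import objective_to_json

    return {
        "spec": spec.to_json(),
        "model": model.to_json(),
        "objective": objective_to_json(objective),
    }


def complexity_report(
    instances: Sequence[tuple[Model, ObjectiveFunction]],
    aggregate: bool = False,
) -> pd.DataFrame:
    """Structural complexity of the three solution strategies per instance.

    Reports, per instance: the constrained minfill width ``w`` of the base
    SCM (MAP cost exponent), the node count ``n1`` and constrained width
    ``w1`` of the objective model (Reverse-MAP cost exponent), and the
    twin-model node count ``n2`` with the baseline exponent ``w2`` =
    number of units + unconstrained twin width (exhaustive enumeration
    evaluates the objective once per unit on the twin model).  Models are
    not pruned, so the reported quantities depend only on structure.
    """
    rows = []
    for model, objective in instances:
        units = list(objective.units)
        w = order_width(model, minfill_order(model, units)).width
        om = build_objective_model(model, objective)
        w1 = order_width(om.model, minfill_order(om.model, om.targets)).width
        twin = build_worlds(model, worlds=(1, 2)).model
        w2 = len(units) + order_width(twin, minfill_order(twin)).width
        rows.append(
            {
                "n": len(model.variables),
                "R": len(model.roots),
                "units": len(units),
                "w": w,
                "n1": len(om.model.variables),
                "w1": w1,
                "n2": len(twin.variables),
                "w2": w2,
            }
        )
    report = pd.DataFrame(rows)
    if aggregate and len(report):
        report = report.groupby(["n", "units"], as_index=False).mean()
    return report


def case_study_pipeline(
    data: pd.DataFrame,
    dag: Mapping[str, Sequence[str]],
    objective: ObjectiveFunction | Mapping,
    smoothing: float = 1.0,
    thresholds: Mapping[str, float] | None = None,
) -> dict:
    """Data table + causal DAG + objective → per-unit counterfactual scores.

    Runs the four-stage recipe: binarize the observed columns, fit a BN on
    the DAG by smoothed maximum likelihood, convert it to a Markovian SCM
    by the exact inverse-CDF construction, then score every unit
    instantiation with both the VE and the circuit solver (they must
    agree).  Returns the score table (one row per unit, one column per
    component plus the total L), the fitted models and the optimum.
    """
    import itertools

    from .circuit import select_units_ac

    if not isinstance(objective, ObjectiveFunction):
        objective = multi_treatment_objective(
            [tuple(t) for t in objective["treatments"]],
            tuple(objective["outcome"]),
            objective.get("evidence", {}),
            objective["units"],
        )
    binary, used_thresholds = binarize(data, thresholds, columns=list(dag))
    bn = fit_bn(dag, binary, smoothing)
    scm = bn_to_scm(bn)
    objective.validate(scm)

    res = select_units_ve(scm, objective, exhaustive=True)
    ac_value, ac_unit, _ = select_units_ac(scm, objective)

    units = list(objective.units)
    rows = []
    state_lists = [scm.variables[u].states for u in units]
    for states in itertools.product(*state_lists):
        unit = dict(zip(units, states))
        row = dict(unit)
        total = 0.0
        for i, comp in enumerate(objective.components, start=1):
            evidence = {**comp.evidence, **unit}
            try:
                p = counterfactual_query(
                    scm, comp.do1, comp.out1, comp.do2, comp.out2, evidence
                )
            except Exception:
                p = 0.0
            row[f"component_{i}"] = p
            total += comp.weight * p
        row["L"] = total
        rows.append(row)
    scores = pd.DataFrame(rows)
    return {
        "scores": scores,
        "bn": bn,
        "scm": scm,
        "thresholds": used_thresholds,
        "best_unit": res.assignment,
        "best_value": res.value,
        "ac_best_unit": ac_unit,
        "ac_best_value": ac_value,
        "smoothing": smoothing,
    }
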
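"""Discrete Bayesian networks and structural causal models.

A :class:`Model` is a DAG over discrete variables with one conditional
probability table per variable.  A model flagged as an SCM keeps all
randomness in its root (exogenous) priors: every internal CPT is
*functional*, i.e. contains only 0/1 entries and therefore encodes a
structural equation.  Models serialize to a versioned JSON dialect and can
be imported from BIF files.
"""

from __future__ import annotations

import json
import re
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .factors import ATOL, Factor, Instantiation, UnknownStateError, Variable

FORMAT_VERSION = 1
_FUNCTIONAL_TOL = 1e-12

__all__ = [
    "Model",
    "load_model",
    "save_model",
    "joint_probability",
    "ModelValidationError",
    "CyclicGraphError",
    "NormalizationError",
    "NotFunctionalError",
    "UnknownVariableError",
]


class ModelValidationError(ValueError):
    """Base class for model validation failures."""


class CyclicGraphError(ModelValidationError):
    pass


class NormalizationError(ModelValidationError):
    pass


class NotFunctionalError(ModelValidationError):
    """An SCM-flagged model has a stochastic internal CPT."""


class UnknownVariableError(ModelValidationError):
    pass


class Model:
    """A discrete BN or SCM: DAG, state spaces and one CPT per variable.

    The CPT of variable ``X`` with parents ``P`` is stored as a factor over
    scope ``(*P, X)`` whose rows (fixing a parent instantiation) sum to one.
    Declaration order of variables and states is significant: it fixes
    odometer order in serialization and the tie-breaking order of argmax
    operations.
    """

    def __init__(
        self,
        variables: Sequence[Variable],
        parents: Mapping[str, Sequence[str]],
        tables: Mapping[str, np.ndarray | Sequence[float]],
        kind: str = "bn",
        *,
        validate: bool = True,
    ) -> None:
        if kind not in ("bn", "scm"):
            raise ModelValidationError(f"unknown model kind {kind!r}")
        self.kind = kind
        self.variables: dict[str, Variable] = {}
        for v in variables:
            if v.name in self.variables:
                raise ModelValidationError(f"duplicate variable {v.name!r}")
            self.variables[v.name] = v
        self.parents: dict[str, tuple[str, ...]] = {}
        for name in self.variables:
            ps = tuple(parents.get(name, ()))
            for p in ps:
                if p not in self.variables:
                    raise UnknownVariableError(
                        f"variable {name!r} declares unknown parent {p!r}"
                    )
            self.parents[name] = ps
        for name in parents:
            if name not in self.variables:
                raise UnknownVariableError(f"parent map names unknown variable {name!r}")

        self.cpts: dict[str, Factor] = {}
        for name, var in self.variables.items():
            if name not in tables:
                raise ModelValidationError(f"missing table for variable {name!r}")
            scope = tuple(self.variables[p] for p in self.parents[name]) + (var,)
            self.cpts[name] = Factor(scope, np.asarray(tables[name], dtype=float))
        if validate:
            self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        graph = self.graph()
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise CyclicGraphError(f"parent map contains a cycle through {cycle[0][0]!r}")
        for name, cpt in self.cpts.items():
            rows = cpt.values.sum(axis=-1)
            if np.any(np.abs(rows - 1.0) > ATOL):
                raise NormalizationError(
                    f"CPT rows of variable {name!r} do not sum to 1 "
                    f"(worst row sums to {rows.flat[np.argmax(np.abs(rows - 1.0))]:.12g})"
                )
        if self.kind == "scm":
            for name in self.endogenous:
                if not self.is_functional(name):
                    raise NotFunctionalError(
                        f"internal variable {name!r} of an SCM must have a "
                        "functional (0/1) CPT"
                    )

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        for name, ps in self.parents.items():
            g.add_edges_from((p, name) for p in ps)
        return g

    # ------------------------------------------------------------------
    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.variables)

    @property
    def roots(self) -> tuple[str, ...]:
        """Exogenous variables: those without parents."""
        return tuple(n for n in self.variables if not self.parents[n])

    @property
    def endogenous(self) -> tuple[str, ...]:
        """Internal variables: those with at least one parent."""
        return tuple(n for n in self.variables if self.parents[n])

    def children(self) -> dict[str, tuple[str, ...]]:
        out: dict[str, list[str]] = {n: [] for n in self.variables}
        for name, ps in self.parents.items():
            for p in ps:
                out[p].append(name)
        return {n: tuple(c) for n, c in out.items()}

    def is_functional(self, name: str) -> bool:
        values = self.cpts[name].values
        return bool(
            np.all(
                (np.abs(values) <= _FUNCTIONAL_TOL)
                | (np.abs(values - 1.0) <= _FUNCTIONAL_TOL)
            )
        )

    def topological_order(self) -> tuple[str, ...]:
        seen: set[str] = set()
        order: list[str] = []
        pending = dict(self.parents)
        while pending:
            ready = [n for n, ps in pending.items() if all(p in seen for p in ps)]
            for n in ready:
                order.append(n)
                seen.add(n)
                del pending[n]
        return tuple(order)

    def check_instantiation(self, inst: Instantiation) -> None:
        for name, state in inst.items():
            if name not in self.variables:
                raise UnknownVariableError(f"unknown variable {name!r}")
            self.variables[name].index(state)  # raises UnknownStateError

    # ------------------------------------------------------------------
    def factors(self) -> list[Factor]:
        """The CPT factors, in variable declaration order."""
        return [self.cpts[name] for name in self.variables]

    def copy(self) -> "Model":
        return Model(
            list(self.variables.values()),
            dict(self.parents),
            {n: f.values.copy() for n, f in self.cpts.items()},
            self.kind,
            validate=False,
        )

    # ------------------------------------------------------------------
    def to_json(self) -> dict:
        return {
            "format": "unitselect-model",
            "version": FORMAT_VERSION,
            "kind": self.kind,
            "variables": [
                {"name": v.name, "states": list(v.states)} for v in self.variables.values()
            ],
            "parents": {n: list(ps) for n, ps in self.parents.items() if ps},
            "tables": {n: f.values.reshape(-1).tolist() for n, f in self.cpts.items()},
        }

    @classmethod
    def from_json(cls, data: Mapping) -> "Model":
        variables = [Variable(v["name"], tuple(v["states"])) for v in data["variables"]]
        return cls(variables, data.get("parents", {}), data["tables"], data.get("kind", "bn"))


def save_model(model: Model, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_json(), fh, indent=1)


def load_model(path, format: str | None = None) -> Model:
    """Load a model from JSON (native dialect) or BIF.

    The format is inferred from the file extension when not given.  BIF
    import is read-only and yields a BN-kind model unless every internal
    CPT happens to be functional.
    """
    fmt = format
    if fmt is None:
        fmt = "bif" if str(path).lower().endswith(".bif") else "json"
    if fmt == "json":
        with open(path) as fh:
            return Model.from_json(json.load(fh))
    if fmt == "bif":
        with open(path) as fh:
            return _parse_bif(fh.read())
    raise ValueError(f"unknown model format {fmt!r}")


# ----------------------------------------------------------------------
# SCM joint semantics


def joint_probability(model: Model, inst: Instantiation) -> float:
    """Joint probability of a full instantiation under SCM semantics.

    Returns the product of exogenous priors when the instantiation is
    consistent with every structural equation, and zero otherwise.
    """
    if model.kind != "scm":
        raise ModelValidationError("joint_probability requires an SCM-kind model")
    missing = set(model.variables) - set(inst)
    if missing:
        raise ValueError(f"instantiation must cover all variables; missing {sorted(missing)}")
    model.check_instantiation(inst)
    prob = 1.0
    for name in model.roots:
        prob *= model.cpts[name].value(inst)
    for name in model.endogenous:
        if model.cpts[name].value(inst) < 0.5:  # functional entry: 0 or 1
            return 0.0
    return prob


# ----------------------------------------------------------------------
# BIF import

_BIF_VARIABLE = re.compile(
    r"variable\s+([\w\-\.]+)\s*\{[^}]*?type\s+discrete\s*\[\s*\d+\s*\]\s*"
    r"\{([^}]*)\}\s*;[^}]*\}",
    re.S,
)
_BIF_PROBABILITY = re.compile(
    r"probability\s*\(\s*([\w\-\.]+)\s*(?:\|\s*([^)]+))?\)\s*\{(.*?)\}",
    re.S,
)


def _parse_bif(text: str) -> Model:
    text = re.sub(r"//[^\n]*", "", text)
    variables: dict[str, Variable] = {}
    for m in _BIF_VARIABLE.finditer(text):
        name = m.group(1)
        states = tuple(s.strip() for s in m.group(2).split(",") if s.strip())
        variables[name] = Variable(name, states)
    parents: dict[str, tuple[str, ...]] = {}
    tables: dict[str, np.ndarray] = {}
    for m in _BIF_PROBABILITY.finditer(text):
        child = m.group(1)
        if child not in variables:
            raise UnknownVariableError(f"BIF probability block for unknown variable {child!r}")
        ps = tuple(p.strip() for p in (m.group(2) or "").split(",") if p.strip())
        parents[child] = ps
        body = m.group(3)
        var = variables[child]
        shape = tuple(variables[p].cardinality for p in ps) + (var.cardinality,)
        table = np.zeros(shape)
        table_m = re.search(r"table([^;]*);", body)
        if table_m:
            values = [float(x) for x in re.split(r"[,\s]+", table_m.group(1).strip()) if x]
            table = np.asarray(values).reshape(shape)
        else:
            for row in re.finditer(r"\(([^)]*)\)\s*([^;]*);", body):
                labels = [s.strip() for s in row.group(1).split(",")]
                if len(labels) != len(ps):
                    raise ModelValidationError(
                        f"BIF row for {child!r} lists {len(labels)} parent states, "
                        f"expected {len(ps)}"
                    )
                idx = tuple(variables[p].index(s) for p, s in zip(ps, labels))
                values = [float(x) for x in re.split(r"[,\s]+", row.group(2).strip()) if x]
                table[idx] = values
        tables[child] = table
    missing = set(variables) - set(tables)
    if missing:
        raise ModelValidationError(f"BIF file lacks probability blocks for {sorted(missing)}")
    model = Model(list(variables.values()), parents, tables, "bn")
    if all(model.is_functional(n) for n in model.endogenous):
        model.kind = "scm"
    return model
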
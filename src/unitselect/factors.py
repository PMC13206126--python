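"""Discrete variables, instantiations and factor algebra.

A :class:`Factor` maps every full instantiation of an ordered variable scope
to a non-negative real.  Conditional probability tables, evidence indicators
and all intermediate tables produced by variable elimination are factors.
The four operations used throughout inference are multiplication, summing
out, maximizing out (with argmax bookkeeping) and division with the
convention 0/0 = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

ATOL = 1e-9

__all__ = [
    "Variable",
    "Factor",
    "Witness",
    "multiply",
    "sum_out",
    "max_out",
    "divide",
    "evidence_factor",
    "ones_factor",
    "ScopeError",
    "SupportViolationError",
    "UnknownStateError",
]


class ScopeError(ValueError):
    """An operation was applied to factors with incompatible scopes."""


class SupportViolationError(ValueError):
    """Division f/g requested where g is zero but f is not."""


class UnknownStateError(ValueError):
    """A state label is not declared for its variable."""


@dataclass(frozen=True)
class Variable:
    """A discrete variable with a fixed, ordered state space.

    The declaration order of ``states`` is the tie-breaking order used by
    every argmax in the package.
    """

    name: str
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(str(s) for s in self.states))
        if len(self.states) < 1:
            raise ValueError(f"variable {self.name!r} needs at least one state")
        if len(set(self.states)) != len(self.states):
            raise ValueError(f"variable {self.name!r} has duplicate state labels")

    @property
    def cardinality(self) -> int:
        return len(self.states)

    def index(self, state: str) -> int:
        try:
            return self.states.index(str(state))
        except ValueError:
            raise UnknownStateError(
                f"state {state!r} is not declared for variable {self.name!r}"
            ) from None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Variable({self.name!r}, {list(self.states)!r})"


# An instantiation is a plain mapping from variable name to state label.
Instantiation = Mapping[str, str]


@dataclass(frozen=True)
class Witness:
    """Argmax bookkeeping produced by :func:`max_out`.

    ``indices[inst]`` holds the state index of ``var`` maximizing the factor
    at each instantiation of the reduced scope (first state on ties).
    """

    var: Variable
    scope: tuple[Variable, ...]
    indices: np.ndarray

    def state(self, assignment: Mapping[str, str]) -> str:
        idx = tuple(v.index(assignment[v.name]) for v in self.scope)
        return self.var.states[int(self.indices[idx])]


class Factor:
    """A table over an ordered scope of discrete variables.

    ``values`` has one axis per scope variable, in scope order.  A scalar
    factor has an empty scope and a single value.
    """

    __slots__ = ("scope", "values")

    def __init__(
        self,
        scope: Sequence[Variable],
        values: np.ndarray | Iterable[float] | float,
        *,
        check: bool = True,
    ) -> None:
        self.scope: tuple[Variable, ...] = tuple(scope)
        shape = tuple(v.cardinality for v in self.scope)
        arr = np.asarray(values, dtype=float)
        if arr.shape != shape:
            arr = arr.reshape(shape)
        self.values = arr
        if check:
            names = [v.name for v in self.scope]
            if len(set(names)) != len(names):
                raise ScopeError(f"duplicate variables in scope {names}")
            if np.any(self.values < -ATOL):
                raise ValueError("factor values must be non-negative")

    # ------------------------------------------------------------------
    @property
    def is_scalar(self) -> bool:
        return not self.scope

    @property
    def scalar(self) -> float:
        if not self.is_scalar:
            raise ScopeError("factor is not scalar")
        return float(self.values)

    def mentions(self, name: str) -> bool:
        return any(v.name == name for v in self.scope)

    def variable(self, name: str) -> Variable:
        for v in self.scope:
            if v.name == name:
                return v
        raise ScopeError(f"variable {name!r} not in scope")

    def value(self, assignment: Mapping[str, str]) -> float:
        """Look up the factor value at a full instantiation of its scope."""
        idx = tuple(v.index(assignment[v.name]) for v in self.scope)
        return float(self.values[idx])

    def copy(self) -> "Factor":
        return Factor(self.scope, self.values.copy(), check=False)

    def __mul__(self, other: "Factor") -> "Factor":
        return multiply(self, other)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Factor({[v.name for v in self.scope]}, shape={self.values.shape})"


# ----------------------------------------------------------------------
# factor operations


def _align(f: Factor, scope: tuple[Variable, ...]) -> np.ndarray:
    """View ``f.values`` broadcastable against the union ``scope``."""
    pos = {v.name: i for i, v in enumerate(scope)}
    order = sorted(range(len(f.scope)), key=lambda a: pos[f.scope[a].name])
    arr = np.transpose(f.values, order) if order != list(range(len(f.scope))) else f.values
    in_f = {v.name for v in f.scope}
    shape = tuple(v.cardinality if v.name in in_f else 1 for v in scope)
    return arr.reshape(shape)


def multiply(f: Factor, g: Factor) -> Factor:
    """Product of two factors over the union of their scopes."""
    scope = f.scope + tuple(v for v in g.scope if not f.mentions(v.name))
    return Factor(scope, _align(f, scope) * _align(g, scope), check=False)


def sum_out(f: Factor, var: Variable | str) -> Factor:
    """Sum a variable out of a factor, shrinking its scope by one."""
    name = var if isinstance(var, str) else var.name
    axis = next((i for i, v in enumerate(f.scope) if v.name == name), None)
    if axis is None:
        raise ScopeError(f"cannot sum out {name!r}: not in scope")
    scope = f.scope[:axis] + f.scope[axis + 1 :]
    return Factor(scope, f.values.sum(axis=axis), check=False)


def max_out(f: Factor, var: Variable | str) -> tuple[Factor, Witness]:
    """Maximize a variable out of a factor, recording the argmax states.

    Ties resolve to the first state in declaration order.
    """
    name = var if isinstance(var, str) else var.name
    axis = next((i for i, v in enumerate(f.scope) if v.name == name), None)
    if axis is None:
        raise ScopeError(f"cannot max out {name!r}: not in scope")
    scope = f.scope[:axis] + f.scope[axis + 1 :]
    reduced = Factor(scope, f.values.max(axis=axis), check=False)
    witness = Witness(f.scope[axis], scope, np.argmax(f.values, axis=axis))
    return reduced, witness


def divide(f: Factor, g: Factor, *, strict: bool = True) -> Factor:
    """Entrywise quotient of two same-scope factors with 0/0 = 0.

    With ``strict`` the support condition (g zero implies f zero) is
    enforced and its violation raises :class:`SupportViolationError`.
    """
    if {v.name for v in f.scope} != {v.name for v in g.scope}:
        raise ScopeError(
            f"divide needs identical scopes, got {[v.name for v in f.scope]} "
            f"vs {[v.name for v in g.scope]}"
        )
    den = _align(g, f.scope).reshape(f.values.shape)
    zero = den == 0.0
    if strict and np.any(zero & (f.values > ATOL)):
        raise SupportViolationError("f > 0 where g = 0 in factor division")
    out = np.asarray(np.divide(f.values, np.where(zero, 1.0, den)))
    out[np.asarray(zero)] = 0.0
    return Factor(f.scope, out, check=False)


def evidence_factor(var: Variable, state: str) -> Factor:
    """Indicator factor over ``{var}``: one at ``state``, zero elsewhere."""
    values = np.zeros(var.cardinality)
    values[var.index(state)] = 1.0
    return Factor((var,), values, check=False)


def ones_factor(var: Variable) -> Factor:
    """All-ones factor over ``{var}`` (a vacuous evidence indicator)."""
    return Factor((var,), np.ones(var.cardinality), check=False)


def product(factors: Iterable[Factor]) -> Factor:
    """Multiply a collection of factors (scalar 1 for an empty collection)."""
    result: Factor | None = None
    for f in factors:
        result = f if result is None else multiply(result, f)
    if result is None:
        return Factor((), 1.0, check=False)
    return result
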
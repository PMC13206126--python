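"""Learning a BN from a discrete data table and converting it to an SCM.

The conversion introduces, for each internal variable X with CPT Pr(X|P),
one fresh exogenous root U_X whose states are the intervals cut out of
(0, 1] by the union of the cumulative sums of all rows of the CPT.  The
structural equation maps (p, u) to the state whose cumulative interval
under parent row p contains u's interval.  Marginalizing U_X recovers
Pr(X|P) exactly, and the number of states of U_X is minimal for an
inverse-CDF construction that uses a single shared partition.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .factors import ATOL, Variable
from .model import Model, ModelValidationError

__all__ = ["fit_bn", "binarize", "bn_to_scm"]

_CUT_DECIMALS = 12


def binarize(
    data: pd.DataFrame,
    thresholds: Mapping[str, float] | None = None,
    columns: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Median-split numeric columns into binary 0/1 columns.

    A value strictly above the threshold maps to state 1.  Columns already
    taking values in {0, 1} pass through unchanged (their threshold is
    reported as 0.5).  Re-applying the returned thresholds is idempotent.
    Constant columns trigger a warning and become all-zero.
    """
    thresholds = dict(thresholds or {})
    out = {}
    used: dict[str, float] = {}
    cols = list(columns) if columns is not None else list(data.columns)
    for col in cols:
        series = pd.to_numeric(data[col])
        if col in thresholds:
            t = float(thresholds[col])
        elif set(series.unique()) <= {0, 1}:
            t = 0.5
        else:
            t = float(series.median())
            if series.nunique() == 1:
                warnings.warn(
                    f"column {col!r} is constant; binarized to all zeros", stacklevel=2
                )
        used[col] = t
        out[col] = (series > t).astype(int)
    return pd.DataFrame(out, index=data.index), used


def fit_bn(
    dag: Mapping[str, Sequence[str]],
    data: pd.DataFrame,
    smoothing: float = 1.0,
    states: Mapping[str, Sequence[str]] | None = None,
) -> Model:
    """Maximum-likelihood CPTs with uniform (add-``smoothing``) smoothing.

    ``dag`` maps every variable to its parents (roots map to an empty
    sequence).  State spaces default to the sorted distinct values found in
    each column; pass ``states`` to fix them explicitly (required for
    states never observed).
    """
    names = list(dag)
    for name in names:
        if name not in data.columns:
            raise ValueError(f"data has no column for variable {name!r}")
    variables: dict[str, Variable] = {}
    codes: dict[str, np.ndarray] = {}
    for name in names:
        col = data[name].astype(str)
        labels = (
            tuple(str(s) for s in states[name])
            if states and name in states
            else tuple(sorted(col.unique()))
        )
        if not labels:
            raise ValueError(f"variable {name!r} has no declared or observed states")
        variables[name] = Variable(name, labels)
        cat = pd.Categorical(col, categories=labels)
        if (cat.codes < 0).any():
            bad = sorted(set(col) - set(labels))
            raise ValueError(f"column {name!r} contains undeclared states {bad}")
        codes[name] = np.asarray(cat.codes)

    tables: dict[str, np.ndarray] = {}
    for name in names:
        ps = tuple(dag[name])
        shape = tuple(variables[p].cardinality for p in ps) + (variables[name].cardinality,)
        counts = np.full(shape, float(smoothing))
        np.add.at(counts, tuple(codes[p] for p in ps) + (codes[name],), 1.0)
        rows = counts.sum(axis=-1, keepdims=True)
        if np.any(rows == 0):
            raise ZeroDivisionError(
                f"variable {name!r} has an unobserved parent configuration and "
                "smoothing is 0; cannot normalize"
            )
        tables[name] = counts / rows
    return Model(list(variables.values()), dict(dag), tables, "bn")


def bn_to_scm(model: Model, prefix: str = "U_") -> Model:
    """Exact inverse-CDF conversion of a BN into a Markovian SCM.

    Every internal variable X gains a fresh root parent ``U_X`` carrying all
    of its conditional uncertainty; the CPT of X becomes functional.  The
    original CPTs are recovered exactly when the added roots are summed out.
    """
    variables = list(model.variables.values())
    parents = {n: tuple(ps) for n, ps in model.parents.items()}
    tables = {n: f.values.copy() for n, f in model.cpts.items()}

    for name in model.endogenous:
        var = model.variables[name]
        cpt = model.cpts[name].values
        k = var.cardinality
        rows = cpt.reshape(-1, k)
        if np.any(np.abs(rows.sum(axis=1) - 1.0) > ATOL):
            raise ModelValidationError(f"CPT of {name!r} is not row-normalized")
        cums = np.cumsum(rows, axis=1)
        cums[:, -1] = 1.0
        cuts = np.unique(np.round(cums[:, :-1], _CUT_DECIMALS))
        cuts = cuts[(cuts > 0.0) & (cuts < 1.0)]
        bounds = np.concatenate(([0.0], cuts, [1.0]))
        m = len(bounds) - 1

        u_name = prefix + name
        while u_name in model.variables or u_name in [v.name for v in variables]:
            u_name += "_"
        u_var = Variable(u_name, tuple(f"u{i}" for i in range(m)))
        prior = np.diff(bounds)

        mids = (bounds[:-1] + bounds[1:]) / 2.0
        # state of X for parent row p and interval j: first state whose
        # cumulative value covers the interval midpoint
        func = np.zeros((rows.shape[0], m, k))
        for p in range(rows.shape[0]):
            states = np.searchsorted(np.round(cums[p], _CUT_DECIMALS), mids, side="left")
            func[p, np.arange(m), np.minimum(states, k - 1)] = 1.0
        recovered = np.tensordot(prior, func, axes=([0], [1]))
        if np.any(np.abs(recovered - rows) > ATOL):  # pragma: no cover - construction guard
            raise AssertionError(f"inverse-CDF conversion failed to recover CPT of {name!r}")

        parent_shape = tuple(model.variables[p].cardinality for p in model.parents[name])
        variables.append(u_var)
        parents[u_name] = ()
        tables[u_name] = prior
        parents[name] = model.parents[name] + (u_name,)
        tables[name] = func.reshape(parent_shape + (m, k))

    return Model(variables, parents, tables, "scm")
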
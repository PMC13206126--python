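import itertools

import numpy as np
import pytest

from unitselect.factors import Variable
from unitselect.model import Model


def _functional(bits: int, fn) -> np.ndarray:
    """Binary functional CPT from a python function of parent state indices."""
    rows = 2**bits
    table = np.zeros((rows, 2))
    for r in range(rows):
        idx = tuple((r >> (bits - 1 - i)) & 1 for i in range(bits))
        table[r, fn(*idx)] = 1.0
    return table.reshape((2,) * bits + (2,))


@pytest.fixture(scope="session")
def worked_trace_model() -> Model:
    """Five-variable SCM with parents A→B, A→C, {B,C}→D, C→E.

    Its CPT factor list is fA(A) fB(AB) fC(AC) fD(BCD) fE(CE); the worked
    elimination trace with evidence on E uses the order E,D,C,B,A.
    """
    V = {x: Variable(x, ("0", "1")) for x in "ABCDE"}
    return Model(
        list(V.values()),
        {"B": ("A",), "C": ("A",), "D": ("B", "C"), "E": ("C",)},
        {
            "A": [0.5, 0.5],
            "B": _functional(1, lambda a: a),
            "C": _functional(1, lambda a: 1 - a),
            "D": _functional(2, lambda b, c: b & c),
            "E": _functional(1, lambda c: c),
        },
        "scm",
    )


@pytest.fixture(scope="session")
def confounded_scm() -> Model:
    """U confounds X and Y: X = U xor UX, Y = (X or U) xor UY.

    Small enough for exhaustive enumeration yet exhibiting confounding,
    so Pr(y|do(x)) differs from Pr(y|x).
    """
    U = Variable("U", ("0", "1"))
    UX = Variable("UX", ("0", "1"))
    UY = Variable("UY", ("0", "1"))
    X = Variable("X", ("0", "1"))
    Y = Variable("Y", ("0", "1"))
    tX = np.zeros((2, 2, 2))
    tY = np.zeros((2, 2, 2, 2))
    for u, ux in itertools.product(range(2), repeat=2):
        tX[u, ux, u ^ ux] = 1.0
    for u, x, uy in itertools.product(range(2), repeat=3):
        tY[u, x, uy, (x | u) ^ uy] = 1.0
    return Model(
        [U, UX, UY, X, Y],
        {"X": ("U", "UX"), "Y": ("U", "X", "UY")},
        {"U": [0.4, 0.6], "UX": [0.7, 0.3], "UY": [0.9, 0.1], "X": tX, "Y": tY},
        "scm",
    )


@pytest.fixture(scope="session")
def small_instances():
    """A reusable corpus of 40 random (SCM, benefit objective) pairs."""
    from unitselect.benchgen import BenchmarkSpec, random_instance

    corpus = []
    for seed in range(40):
        n0 = 3 + seed % 3
        corpus.append(random_instance(BenchmarkSpec(n0=n0, seed=seed, ur=0.5)))
    return corpus
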
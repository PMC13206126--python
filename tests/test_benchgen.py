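import numpy as np
import pandas as pd
import pytest

from oracles import forward_sim
from unitselect.benchgen import (
    BenchmarkSpec,
    case_study_pipeline,
    complexity_report,
    random_instance,
    random_scm,
)
from unitselect.elimination import is_external
from unitselect.model import Model


def test_degenerate_single_node():
    m = random_scm(BenchmarkSpec(n0=1, seed=0))
    assert m.names == ("V1",)
    assert m.roots == ("V1",)


def test_every_internal_node_has_unique_root_parent():
    m = random_scm(BenchmarkSpec(n0=8, seed=3))
    children = m.children()
    for name in m.endogenous:
        added = [p for p in m.parents[name] if p == f"U{name[1:]}"]
        assert len(added) == 1
        assert children[added[0]] == (name,)  # unique to this internal node
    # all internal CPTs are functional, all states binary
    for name in m.variables:
        assert m.variables[name].cardinality == 2
    assert m.kind == "scm"


def test_generator_is_seed_deterministic():
    a = random_scm(BenchmarkSpec(n0=6, seed=11))
    b = random_scm(BenchmarkSpec(n0=6, seed=11))
    assert a.to_json() == b.to_json()
    c = random_scm(BenchmarkSpec(n0=6, seed=12))
    assert c.to_json() != a.to_json()


def test_instance_respects_structural_constraints():
    for seed in range(10):
        model, objective = random_instance(BenchmarkSpec(n0=4, seed=seed, ur=0.5))
        objective.validate(model)  # raises on any violation
        x = next(iter(objective.components[0].do1))
        y = next(iter(objective.components[0].out1))
        assert x in model.endogenous and y in model.endogenous
        import networkx as nx

        assert x in nx.ancestors(model.graph(), y)


def test_ur_one_uses_all_roots():
    model, objective = random_instance(BenchmarkSpec(n0=4, seed=2, ur=1.0))
    assert set(objective.units) == set(model.roots)


def test_generated_units_are_external():
    for seed in range(30):
        model, objective = random_instance(BenchmarkSpec(n0=3 + seed % 3, seed=seed, ur=0.5))
        assert is_external(model, objective.units)


def test_complexity_report_invariants(small_instances):
    report = complexity_report(small_instances[:12])
    assert list(report.columns) == ["n", "R", "units", "w", "n1", "w1", "n2", "w2"]
    # the objective model is never easier than the base model, and the
    # baseline exponent always pays for enumerating the unit space
    assert (report.w1 >= report.w).all()
    assert (report.w2 >= report.units).all()
    # external units force the constrained width up to the unit count
    assert (report.w >= report.units).all()


def test_twin_bound_on_report(small_instances):
    """Evidence-free benefit objectives obey the twin width bound w1 <= 2w+2."""
    report = complexity_report(small_instances[:12])
    assert (report.w1 <= 2 * report.w + 2).all()


def synthetic_reef_scm():
    """A small hand-built SCM resembling an ecological regime-shift model.

    Synthetic stand-in: three stable unit roots drive two intervenable
    mid-layer variables and a binary outcome.
    """
    import itertools

    from unitselect.factors import Variable

    D = Variable("D", ("0", "1"))
    W = Variable("W", ("0", "1"))
    UN = Variable("UN", ("0", "1"))
    UH = Variable("UH", ("0", "1"))
    UY = Variable("UY", ("0", "1"))
    N = Variable("N", ("0", "1"))
    Hb = Variable("Hb", ("0", "1"))
    Y = Variable("Y", ("0", "1"))
    tN = np.zeros((2, 2, 2))
    tH = np.zeros((2, 2, 2))
    tY = np.zeros((2, 2, 2, 2, 2))
    for w, un in itertools.product(range(2), repeat=2):
        tN[w, un, w & un] = 1.0
    for d, uh in itertools.product(range(2), repeat=2):
        tH[d, uh, d | uh] = 1.0
    for n, h, d, uy in itertools.product(range(2), repeat=4):
        tY[n, h, d, uy, ((n & (1 - h)) | (1 - d)) ^ uy] = 1.0
    return Model(
        [D, W, UN, UH, UY, N, Hb, Y],
        {"N": ("W", "UN"), "Hb": ("D", "UH"), "Y": ("N", "Hb", "D", "UY")},
        {
            "D": [0.45, 0.55],
            "W": [0.6, 0.4],
            "UN": [0.5, 0.5],
            "UH": [0.7, 0.3],
            "UY": [0.85, 0.15],
            "N": tN,
            "Hb": tH,
            "Y": tY,
        },
        "scm",
    )


def sample_dataframe(model: Model, n_rows: int, seed: int) -> pd.DataFrame:
    """Forward-sample complete observations from an SCM."""
    rng = np.random.default_rng(seed)
    rows = []
    roots = model.roots
    observed = [n for n in model.variables if not n.startswith("U")]
    for _ in range(n_rows):
        exo = {}
        for r in roots:
            p = model.cpts[r].values
            exo[r] = model.variables[r].states[rng.choice(len(p), p=p)]
        values = forward_sim(model, exo, {})
        rows.append({k: int(values[k]) for k in observed})
    return pd.DataFrame(rows)


def test_case_study_pipeline_recovers_generating_cpts():
    """Fitting on large samples from a known SCM recovers its observed CPTs."""
    truth = synthetic_reef_scm()
    data = sample_dataframe(truth, 4000, seed=0)
    dag = {"D": (), "W": (), "N": ("W",), "Hb": ("D",), "Y": ("N", "Hb", "D")}
    objective = {
        "units": ["D", "W"],
        "treatments": [["N", "0", 0.4], ["Hb", "1", 0.6]],
        "outcome": ["Y", "0"],
        "evidence": {"Y": "1"},
    }
    result = case_study_pipeline(data, dag, objective, smoothing=1.0)
    bn = result["bn"]
    # observed-variable conditionals of the generating SCM, by enumeration
    from oracles import enum_marginal

    for w in "01":
        num = enum_marginal(truth, {"W": w, "N": "1"})
        den = enum_marginal(truth, {"W": w})
        got = bn.cpts["N"].value({"W": w, "N": "1"})
        assert got == pytest.approx(num / den, abs=0.06)


def test_case_study_pipeline_scores_and_agreement():
    truth = synthetic_reef_scm()
    data = sample_dataframe(truth, 300, seed=1)
    dag = {"D": (), "W": (), "N": ("W",), "Hb": ("D",), "Y": ("N", "Hb", "D")}
    objective = {
        "units": ["D", "W"],
        "treatments": [["N", "0", 0.4], ["Hb", "1", 0.6]],
        "outcome": ["Y", "0"],
        "evidence": {"Y": "1"},
    }
    result = case_study_pipeline(data, dag, objective, smoothing=1.0)
    scores = result["scores"]
    assert len(scores) == 4  # 2 binary units -> 4 rows
    assert set(scores.columns) == {"D", "W", "component_1", "component_2", "L"}
    # VE and AC solvers agree on value and optimal unit
    assert result["best_value"] == pytest.approx(result["ac_best_value"], abs=1e-9)
    assert result["best_unit"] == result["ac_best_unit"]
    # the score table's maximum matches the solver's optimum
    assert scores.L.max() == pytest.approx(result["best_value"], abs=1e-9)
    best_row = scores.loc[scores.L.idxmax()]
    assert {u: best_row[u] for u in ("D", "W")} == result["best_unit"]


def test_three_binary_units_emit_eight_rows():
    truth = synthetic_reef_scm()
    data = sample_dataframe(truth, 200, seed=2)
    dag = {"D": (), "W": (), "N": ("W",), "Hb": ("D",), "Y": ("N", "Hb", "D")}
    objective = {
        "units": ["D", "W", "UN"],
        "treatments": [["N", "0", 0.5], ["Hb", "1", 0.5]],
        "outcome": ["Y", "0"],
        "evidence": {"Y": "1"},
    }
    # UN is not observed; use the fitted SCM's own hidden root instead
    from unitselect.learn import binarize, bn_to_scm, fit_bn
    from unitselect.objective import multi_treatment_objective
    from unitselect.inference import select_units_ve

    binary, _ = binarize(data, columns=list(dag))
    scm = bn_to_scm(fit_bn(dag, binary, 1.0))
    L = multi_treatment_objective(
        [("N", "0", 0.5), ("Hb", "1", 0.5)],
        ("Y", "0"),
        {"Y": "1"},
        ("D", "W", "U_N"),
    )
    res = select_units_ve(scm, L, exhaustive=True)
    assert res.scores.values.size >= 8  # 3 unit variables, >= 2 states each
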
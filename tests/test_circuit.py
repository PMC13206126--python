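import numpy as np
import pytest

from oracles import all_instantiations, brute_rmap, enum_marginal
from unitselect.benchgen import BenchmarkSpec, random_instance, random_scm
from unitselect.circuit import (
    Circuit,
    ProductNode,
    SumNode,
    _Builder,
    check_properties,
    compile_ac,
    evaluate,
    load_circuit,
    map_ac,
    quotient_parametrization,
    rmap_ac,
    save_circuit,
    select_units_ac,
)
from unitselect.elimination import ConstraintError, Order
from unitselect.factors import SupportViolationError, Variable
from unitselect.inference import map_ve, rmap_ve, select_units_ve
from unitselect.model import Model, joint_probability
from unitselect.objective import brute_select
from unitselect.worlds import ZeroEvidenceError


def test_single_root_circuit_structure():
    m = Model([Variable("X", ("0", "1"))], {}, {"X": [0.3, 0.7]})
    ac = compile_ac(m)
    root = ac.root
    assert isinstance(root, SumNode) and root.dvar.name == "X"
    assert evaluate(ac, {"X": "0"}) == pytest.approx(0.3)
    assert evaluate(ac, {"X": "1"}) == pytest.approx(0.7)
    assert evaluate(ac) == pytest.approx(1.0)
    # MAP over the single root returns the larger prior entry
    value, assignment = map_ac(ac, ("X",))
    assert value == pytest.approx(0.7)
    assert assignment == {"X": "1"}


def test_compile_rejects_unconstrained_order(confounded_scm):
    bad = Order(tuple(confounded_scm.variables))
    with pytest.raises(ConstraintError):
        compile_ac(confounded_scm, ("U",), bad)


def test_compiled_circuit_properties(confounded_scm):
    ac = compile_ac(confounded_scm, ("U", "UY"))
    report = check_properties(ac, ("U", "UY"))
    assert report.decomposable
    assert report.smooth
    assert report.decision
    assert report.prop1_order
    assert report.prop1_indicators
    assert report.u_deterministic
    assert report.all_ok


@pytest.mark.parametrize("seed", range(20))
def test_property_sweep_on_random_instances(seed):
    model, objective = random_instance(BenchmarkSpec(n0=3 + seed % 3, seed=seed, ur=0.5))
    from unitselect.objective import build_objective_model

    om = build_objective_model(model, objective)
    ac = compile_ac(om.model, om.targets)
    assert check_properties(ac, om.targets).all_ok


def test_evaluate_full_partial_and_empty(confounded_scm):
    ac = compile_ac(confounded_scm, ("U",))
    for inst in all_instantiations(confounded_scm):
        assert evaluate(ac, inst) == pytest.approx(
            joint_probability(confounded_scm, inst), abs=1e-12
        )
    for partial in ({}, {"Y": "1"}, {"X": "0", "Y": "1"}):
        assert evaluate(ac, partial) == pytest.approx(
            enum_marginal(confounded_scm, partial), abs=1e-12
        )


def test_smoothness_violation_detected():
    b = _Builder()
    A = Variable("A", ("0", "1"))
    B = Variable("B", ("0", "1"))
    la0 = b.indicator(A, 0)
    la1 = b.indicator(A, 1)
    lb0 = b.indicator(B, 0)
    p = b.param(0.5)
    child1 = b.product([la0, p])  # mentions {A}
    child2 = b.product([la1, lb0])  # mentions {A, B}
    root = b.sum([child1, child2], A)
    ac = Circuit(b.nodes, root, b.params, np.array([0.5]), (A, B))
    report = check_properties(ac)
    assert not report.smooth
    assert report.decomposable


def test_decomposability_violation_detected():
    b = _Builder()
    A = Variable("A", ("0", "1"))
    la0 = b.indicator(A, 0)
    root = b._register(ProductNode((la0, la0)))
    ac = Circuit(b.nodes, root, b.params, np.array([]), (A,))
    assert not check_properties(ac).decomposable


def test_map_ac_empty_targets_reduces_to_evaluate(confounded_scm):
    ac = compile_ac(confounded_scm, ())
    value, assignment = map_ac(ac, (), {"Y": "1"})
    assert value == pytest.approx(evaluate(ac, {"Y": "1"}))
    assert assignment == {}


@pytest.mark.parametrize("seed", range(25))
def test_map_ac_matches_map_ve(seed):
    rng = np.random.default_rng(seed)
    model = random_scm(BenchmarkSpec(n0=int(rng.integers(2, 5)), seed=seed + 300))
    roots = list(model.roots)
    targets = tuple(sorted(rng.choice(roots, size=min(2, len(roots)), replace=False)))
    rest = [n for n in model.variables if n not in targets]
    e = {rest[-1]: "1"} if seed % 2 else {}
    ac = compile_ac(model, targets)
    value, assignment = map_ac(ac, targets, e)
    res = map_ve(model, targets, e)
    assert value == pytest.approx(res.value, abs=1e-9)
    assert enum_marginal(model, {**assignment, **e}) == pytest.approx(
        res.value, abs=1e-9
    )


@pytest.mark.parametrize("seed", range(30))
def test_rmap_ac_matches_rmap_ve_and_enumeration(seed):
    rng = np.random.default_rng(seed)
    model = random_scm(BenchmarkSpec(n0=int(rng.integers(2, 5)), seed=seed + 700))
    roots = list(model.roots)
    targets = tuple(sorted(rng.choice(roots, size=min(2, len(roots)), replace=False)))
    rest = [n for n in model.variables if n not in targets]
    e1 = {rest[0]: "1"}
    e2 = {rest[1]: "0"} if len(rest) > 1 and seed % 2 else {}
    ac = compile_ac(model, targets)
    try:
        value, assignment, diag = rmap_ac(ac, targets, e1, e2)
    except ZeroEvidenceError:
        assert enum_marginal(model, e2) == pytest.approx(0.0, abs=1e-12)
        return
    res = rmap_ve(model, targets, e1, e2)
    best, _, table = brute_rmap(model, targets, e1, e2)
    assert value == pytest.approx(res.value, abs=1e-9)
    assert value == pytest.approx(best, abs=1e-9)
    assert table[tuple(assignment[t] for t in targets)] == pytest.approx(
        best, abs=1e-9
    )
    assert diag["visits_max"] == 1


def test_rmap_ac_vacuous_e1_returns_one(confounded_scm):
    ac = compile_ac(confounded_scm, ("U",))
    value, assignment, _ = rmap_ac(ac, ("U",), {}, {"X": "1"})
    assert value == pytest.approx(1.0)
    assert assignment == {"U": "0"}  # tie: first state


def test_rmap_ac_visits_every_node_once(confounded_scm):
    ac = compile_ac(confounded_scm, ("U", "UY"))
    _, _, diag = rmap_ac(ac, ("U", "UY"), {"Y": "1"}, {"X": "1"})
    assert diag["visits_total"] == len(ac.nodes)
    assert diag["visits_max"] == 1


def test_select_units_ac_matches_ve_and_brute(small_instances):
    for model, objective in small_instances[:10]:
        value, unit, _ = select_units_ac(model, objective)
        res = select_units_ve(model, objective)
        best, _, table = brute_select(model, objective)
        assert value == pytest.approx(res.value, abs=1e-9)
        assert value == pytest.approx(best, abs=1e-9)
        assert table[tuple(unit[u] for u in objective.units)] == pytest.approx(
            best, abs=1e-9
        )


def test_quotient_self_is_one_on_support(confounded_scm):
    ac = compile_ac(confounded_scm, ())
    q = quotient_parametrization(ac, ac.param_values, ac.param_values)
    for inst in all_instantiations(confounded_scm):
        p = joint_probability(confounded_scm, inst)
        assert evaluate(q, inst) == pytest.approx(1.0 if p > 0 else 0.0, abs=1e-12)


def test_quotient_uniform_denominator_scales_by_state_space(confounded_scm):
    """With a uniform parametrization below, the quotient is 2^n · Pr1."""
    ac = compile_ac(confounded_scm, ())
    uniform = np.full_like(ac.param_values, 0.5)
    q = quotient_parametrization(ac, ac.param_values, uniform)
    n = len(confounded_scm.variables)
    for inst in all_instantiations(confounded_scm):
        assert evaluate(q, inst) == pytest.approx(
            (2.0**n) * joint_probability(confounded_scm, inst), abs=1e-9
        )


@pytest.mark.parametrize("seed", range(10))
def test_quotient_random_parametrizations_pointwise(seed):
    rng = np.random.default_rng(seed)
    model = random_scm(BenchmarkSpec(n0=int(rng.integers(2, 4)), seed=seed + 40))
    ac = compile_ac(model, ())
    theta1 = rng.random(ac.param_values.shape)
    theta2 = rng.random(ac.param_values.shape) + 0.1
    ac1 = ac.with_params(theta1)
    ac2 = ac.with_params(theta2)
    q = quotient_parametrization(ac, theta1, theta2)
    for inst in all_instantiations(model):
        v2 = evaluate(ac2, inst)
        want = evaluate(ac1, inst) / v2 if v2 > 0 else 0.0
        assert evaluate(q, inst) == pytest.approx(want, abs=1e-9)


def test_quotient_support_violation_raises(confounded_scm):
    ac = compile_ac(confounded_scm, ())
    theta2 = ac.param_values.copy()
    theta1 = np.ones_like(theta2)
    theta2[np.argmax(theta2 > 0)] = 0.0
    with pytest.raises(SupportViolationError):
        quotient_parametrization(ac, theta1, theta2)


def test_circuit_serialization_roundtrip(tmp_path, confounded_scm):
    ac = compile_ac(confounded_scm, ("U",))
    path = tmp_path / "model.ac"
    save_circuit(ac, path)
    back = load_circuit(path)
    assert len(back.nodes) == len(ac.nodes)
    assert back.targets == ac.targets
    for inst in all_instantiations(confounded_scm):
        assert evaluate(back, inst) == pytest.approx(evaluate(ac, inst), abs=1e-12)
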
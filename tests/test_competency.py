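import numpy as np
import pytest
from rdflib import Graph, RDF

from fairpredict import (
    ActivityRecord,
    RunRecord,
    StepSpec,
    WorkflowSpec,
    answer_cq,
    build_paper_fixture,
    describe_workflow,
    diff_versions,
    link_revision,
    record_execution,
    step_order,
)
from fairpredict.competency import CQ_IDS
from fairpredict.provenance import DUL, Namespaces, PPLAN, PWO

import oracles

NS = Namespaces()
OP = NS.opredict
V01 = str(OP["Plan_Main_Protocol_v01"])


def _random_spec(rng, wf_id="Workflow_R", version="0.1"):
    n = int(rng.integers(2, 7))
    kinds = [("manual", "script")[rng.integers(0, 2)] for _ in range(n)]
    steps = tuple(
        StepSpec(step_id=f"Step_{wf_id}_{i}", label=f"step {i}", kind=kinds[i])
        for i in range(n)
    )
    return WorkflowSpec(
        workflow_id=wf_id, version=version, created="2020-01-01",
        modified="2020-01-02", creator="Ada", steps=steps,
    )


# ------------------------------------------------------------- error paths

def test_unknown_cq_and_missing_params_rejected():
    g = Graph()
    with pytest.raises(ValueError, match="unknown competency"):
        answer_cq(g, "9.9")
    with pytest.raises(ValueError, match="requires parameters"):
        answer_cq(g, "1.1")
    with pytest.raises(ValueError, match="unsafe IRI"):
        answer_cq(g, "1.1", {"workflow": "bad iri> ."})


@pytest.mark.parametrize("cq_id", CQ_IDS)
def test_every_cq_on_empty_graph_returns_no_rows(cq_id):
    g = NS.graph()
    params = {"workflow": V01, "old": V01, "new": str(OP["Plan_Main_Protocol_v02"])}
    assert answer_cq(g, cq_id, params).rows == ()


# ------------------------------------------------------------ fixture facts

def test_cq11_fixture_download_step_is_manual():
    result = answer_cq(build_paper_fixture(), "1.1", {"workflow": V01})
    by_step = {r[0]: r[1] for r in result.rows}
    assert by_step[str(OP["Step_Download_Drugbank_dataset"])] == "manual"


def test_cq13_fixture_recovers_drugbank_distribution():
    result = answer_cq(build_paper_fixture(), "1.3", {"workflow": V01})
    urls = {r[2] for r in result.rows}
    assert urls == {"http://download.bio2rdf.org/files/release/4/drugbank/drugbank.nq.gz"}


def test_cq35_fixture_recovers_accuracy_value():
    result = answer_cq(build_paper_fixture(), "3.5")
    accuracy_rows = [
        r for r in result.rows
        if str(OP["ModelEvaluation_Accuracy_Execution_1546302862"]) in r
    ]
    assert accuracy_rows and accuracy_rows[0][-1] == "0.833336"
    assert accuracy_rows[0][1] == "0.1"  # executed under protocol v0.1


def test_cq31_fixture_lists_both_versions_with_revision():
    result = answer_cq(build_paper_fixture(), "3.1")
    versions = {r[1]: r[5] for r in result.rows}
    assert set(versions) == {"0.1", "0.2"}
    assert versions["0.2"] == V01  # v0.2 revises v0.1


def test_cq_results_are_deterministic():
    g = build_paper_fixture()
    assert answer_cq(g, "3.5") == answer_cq(g, "3.5")


# -------------------------------------------------- emit-query consistency

def test_cq11_recovers_random_specs_exactly():
    rng = np.random.default_rng(12)
    for trial in range(5):
        spec = _random_spec(rng, wf_id=f"Workflow_T{trial}")
        g = describe_workflow(spec)
        result = answer_cq(g, "1.1", {"workflow": str(OP[spec.workflow_id])})
        got = {(r[0], r[1]) for r in result.rows}
        want = {(str(OP[s.step_id]), s.kind) for s in spec.steps}
        assert got == want


def test_cq35_recovers_run_metrics_exactly():
    spec = _random_spec(np.random.default_rng(5), wf_id="Workflow_M")
    metrics = (("Accuracy", "0.91", "2020-01-01T00:00:00.000"),
               ("RocAuc", "0.87", "2020-01-01T00:00:01.000"))
    run = RunRecord(
        run_id="99",
        activities=(ActivityRecord(spec.steps[0].step_id, "t0", "t1", metrics=metrics),),
    )
    g = describe_workflow(spec) + record_execution(spec, run)
    result = answer_cq(g, "3.5")
    got = {(r[-2].rsplit("_", 1)[-1], r[-1]) for r in result.rows}
    assert got == {("Accuracy", "0.91"), ("RocAuc", "0.87")}
    assert {r[1] for r in result.rows} == {spec.version}


def test_cq12_returns_manual_step_agents():
    spec = WorkflowSpec(
        workflow_id="W_A", version="1", created="", modified="", creator="Ada",
        steps=(
            StepSpec("sA", "a", "manual", agents=(("Remzi", "Creator"),)),
            StepSpec("sB", "b", "script", agents=(("Ada", "Developer"),)),
        ),
    )
    result = answer_cq(describe_workflow(spec), "1.2", {"workflow": str(OP["W_A"])})
    assert {(r[1], r[2]) for r in result.rows} == {
        (str(OP["Agent_Remzi"]), str(OP["Role_Creator"]))
    }


# -------------------------------------------------------------- step order

def test_step_order_linear_chain():
    spec = _random_spec(np.random.default_rng(1), wf_id="Workflow_C")
    g = describe_workflow(spec)
    order = [str(s) for s in step_order(g, str(OP[spec.workflow_id]))]
    assert order == [str(OP[s.step_id]) for s in spec.steps]


def test_step_order_on_random_dags_is_topological():
    rng = np.random.default_rng(8)
    for trial in range(5):
        n = int(rng.integers(3, 8))
        ids = [f"Step_D{trial}_{i}" for i in range(n)]
        edges = [
            (ids[i], ids[j])
            for i in range(n) for j in range(i + 1, n)
            if rng.random() < 0.4
        ] or [(ids[0], ids[1])]
        spec = WorkflowSpec(
            workflow_id=f"Workflow_D{trial}", version="1", created="", modified="",
            creator="A",
            steps=tuple(StepSpec(s, s, "script") for s in ids),
            precedence=tuple(edges),
        )
        g = describe_workflow(spec)
        order = step_order(g, str(OP[spec.workflow_id]))
        reachable = {str(x) for x in order}
        edge_strs = [(str(OP[a]), str(OP[b])) for a, b in edges]
        assert oracles.is_topological([str(x) for x in order], edge_strs)
        assert str(OP[ids[0]]) in reachable


def test_step_order_cycle_rejected():
    g = NS.graph()
    g.add((OP["w"], PWO.hasFirstStep, OP["a"]))
    g.add((OP["a"], DUL.precedes, OP["b"]))
    g.add((OP["b"], DUL.precedes, OP["a"]))
    with pytest.raises(ValueError, match="cycle"):
        step_order(g, str(OP["w"]))


def test_step_order_requires_first_step():
    with pytest.raises(ValueError, match="first step"):
        step_order(NS.graph(), str(OP["nowhere"]))


# ------------------------------------------------------------ version diff

def _two_version_graph():
    """v1 has plans P_reuse1, P_reuse2, P_old_changed, P_dropped;
    v2 reuses the first two, revises the third, adds P_new."""
    g = NS.graph()
    for wf, steps in (
        ("V1", [("s1", "P_reuse1"), ("s2", "P_reuse2"), ("s3", "P_old_changed"),
                ("s4", "P_dropped")]),
        ("V2", [("t1", "P_reuse1"), ("t2", "P_reuse2"), ("t3", "P_new_changed"),
                ("t4", "P_new")]),
    ):
        for sid, plan in steps:
            g.add((OP[sid], PPLAN.isStepOfPlan, OP[wf]))
            g.add((OP[sid], RDF.type, PPLAN.Step))
            g.add((OP[sid], DUL.isDescribedBy, OP[plan]))
            g.add((OP[plan], RDF.type, PPLAN.Plan))
    from fairpredict.provenance import PROV

    g.add((OP["P_new_changed"], PROV.wasRevisionOf, OP["P_old_changed"]))
    return g


def test_diff_versions_classifies_plans():
    g = _two_version_graph()
    diff = diff_versions(g, str(OP["V1"]), str(OP["V2"]))
    assert diff.removed == {str(OP["P_dropped"])}
    assert diff.changed == {str(OP["P_new_changed"])}
    assert diff.added == {str(OP["P_new"])}
    result = answer_cq(g, "3.2", {"old": str(OP["V1"]), "new": str(OP["V2"])})
    assert set(result.rows) == {
        (str(OP["P_dropped"]), "removed"),
        (str(OP["P_new_changed"]), "changed"),
        (str(OP["P_new"]), "added"),
    }


def test_diff_same_version_is_empty():
    g = _two_version_graph()
    diff = diff_versions(g, str(OP["V1"]), str(OP["V1"]))
    assert not diff.removed and not diff.changed and not diff.added


def test_diff_unknown_version_rejected():
    with pytest.raises(ValueError, match="unknown workflow version"):
        diff_versions(_two_version_graph(), str(OP["V9"]), str(OP["V1"]))


def test_cq33_finds_automatized_steps():
    old = WorkflowSpec(
        workflow_id="W_old", version="0.1", created="", modified="", creator="A",
        steps=(StepSpec("m1", "download", "manual"),),
    )
    new = WorkflowSpec(
        workflow_id="W_new", version="0.2", created="", modified="", creator="A",
        steps=(StepSpec("m1_v2", "download", "script", revision_of="Plan_m1"),),
    )
    g = describe_workflow(old) + describe_workflow(new) + link_revision(new, old)
    result = answer_cq(g, "3.3", {"old": str(OP["W_old"]), "new": str(OP["W_new"])})
    assert set(result.rows) == {(str(OP["Plan_m1"]), str(OP["Plan_m1_v2"]))}
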
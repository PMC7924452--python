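import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fairpredict import (
    build_similarity_matrices,
    description_cosine,
    information_content,
    jaccard_similarity,
    normalized_local_alignment,
    ppi_closeness,
    semantic_set_similarity,
)
from fairpredict.kb_synth import OntologyDAG, ProteinNetwork
from fairpredict.similarity import DISEASE_MEASURES, DRUG_MEASURES

import oracles


# ----------------------------------------------------------------- jaccard

@pytest.mark.parametrize(
    "a, b, expected",
    [
        ({1, 2, 3}, {1, 2, 3}, 1.0),
        ({1, 2}, {3, 4}, 0.0),
        ({1, 2, 3}, {2, 3, 4}, 0.5),
        (set(), set(), 0.0),
        (set(), {1}, 0.0),
    ],
)
def test_jaccard_examples(a, b, expected):
    assert jaccard_similarity(a, b) == pytest.approx(expected)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.frozensets(st.integers(0, 30), max_size=15),
    st.frozensets(st.integers(0, 30), max_size=15),
)
def test_jaccard_is_a_bounded_symmetric_similarity(a, b):
    s = jaccard_similarity(a, b)
    assert 0.0 <= s <= 1.0
    assert s == jaccard_similarity(b, a)
    if a:
        assert jaccard_similarity(a, a) == 1.0


# --------------------------------------------------------------- alignment

def test_alignment_self_is_one():
    assert normalized_local_alignment("MKTAYIAKQR", "MKTAYIAKQR") == pytest.approx(1.0)


def test_alignment_no_positive_score_is_zero():
    assert normalized_local_alignment("AAAA", "PPPP") == 0.0


def test_alignment_empty_sequence_rejected():
    with pytest.raises(ValueError):
        normalized_local_alignment("", "MKT")


@pytest.mark.parametrize(
    "s1, s2",
    [
        ("MKTAYIAKQRQI", "MKTAYIAKQRQV"),  # one substitution
        ("ACDEFGHIKLMN", "ACDEFGIKLMNP"),
        ("WWWWYYYYFFFF", "WWWYYYYFFFFC"),
    ],
)
def test_alignment_matches_dp_oracle(s1, s2):
    assert normalized_local_alignment(s1, s2) == pytest.approx(
        oracles.normalized_sw(s1, s2), abs=1e-9
    )


# ------------------------------------------------------- information content

def _toy_dag():
    #       r
    #      / \
    #     a   b
    #    / \   \
    #   c   d   e
    edges = {("a", "r"), ("b", "r"), ("c", "a"), ("d", "a"), ("e", "b")}
    return OntologyDAG(terms=("r", "a", "b", "c", "d", "e"), edges=frozenset(edges), root="r")


def test_ic_root_is_zero_and_counting_matches():
    dag = _toy_dag()
    # term "a" (incl. descendants c, d) annotated to 2 of 8 entities
    ann = {f"e{i}": {"b"} for i in range(6)}
    ann["e6"] = {"c"}
    ann["e7"] = {"d"}
    ic = information_content(dag, ann)
    assert ic["r"] == 0.0
    assert ic["a"] == pytest.approx(-np.log(0.25))  # 1.386
    edges = {"a": ["r"], "b": ["r"], "c": ["a"], "d": ["a"], "e": ["b"]}
    expected = oracles.ic_counts(edges, "r", dag.terms, ann)
    for t in dag.terms:
        assert ic[t] == pytest.approx(expected[t])


def test_ic_monotone_along_every_edge(small_kb):
    ann = {p.protein_id: set(p.go_terms) for p in small_kb.proteins}
    ic = information_content(small_kb.go_dag, ann)
    for child, parent in small_kb.go_dag.edges:
        assert ic[child] >= ic[parent] - 1e-12


def test_ic_rejects_foreign_terms():
    with pytest.raises(ValueError):
        information_content(_toy_dag(), {"x": {"zz"}})


# ------------------------------------------------------- semantic similarity

def test_semantic_identity_on_max_ic_leaf():
    dag = _toy_dag()
    ann = {f"e{i}": {"b"} for i in range(7)}
    ann["e7"] = {"c"}  # c is rare -> max IC
    ic = information_content(dag, ann)
    assert ic["c"] == max(ic.values())  # the rare leaf attains max corpus IC
    assert semantic_set_similarity({"c"}, {"c"}, dag, ic) == pytest.approx(1.0)


def test_semantic_root_only_overlap_is_zero():
    dag = _toy_dag()
    ann = {"e0": {"c"}, "e1": {"e"}}
    ic = information_content(dag, ann)
    # c and e share only the root ancestor
    assert semantic_set_similarity({"c"}, {"e"}, dag, ic) == 0.0


def test_semantic_bma_matches_enumeration_oracle():
    dag = _toy_dag()
    ann = {"e0": {"c"}, "e1": {"d", "e"}, "e2": {"b"}, "e3": {"a", "e"}}
    ic = information_content(dag, ann)
    edges = {"a": ["r"], "b": ["r"], "c": ["a"], "d": ["a"], "e": ["b"]}
    tA, tB = {"c", "d", "e"}, {"d", "b"}
    assert semantic_set_similarity(tA, tB, dag, ic) == pytest.approx(
        oracles.resnik_bma(tA, tB, edges, ic)
    )


def test_semantic_empty_set_warns_and_returns_zero():
    dag = _toy_dag()
    ic = information_content(dag, {"e0": {"c"}})
    with pytest.warns(UserWarning):
        assert semantic_set_similarity(set(), {"c"}, dag, ic) == 0.0


# ------------------------------------------------------------ ppi closeness

def _chain_net():
    nodes = ("p1", "p2", "p3", "p4", "q1")
    edges = frozenset({("p1", "p2"), ("p2", "p3"), ("p3", "p4")})
    return ProteinNetwork(nodes=nodes, edges=edges)


def test_ppi_shared_target_is_one():
    assert ppi_closeness(_chain_net(), {"p1"}, {"p1", "p4"}) == pytest.approx(1.0)


def test_ppi_disconnected_is_zero():
    assert ppi_closeness(_chain_net(), {"p1"}, {"q1"}) == 0.0


def test_ppi_distance_two_matches_bfs_oracle():
    net = _chain_net()
    edges = sorted(net.edges)
    assert oracles.bfs_distance(edges, "p1", "p3") == 2
    assert ppi_closeness(net, {"p1"}, {"p3"}, decay=1.0) == pytest.approx(np.exp(-2))
    assert ppi_closeness(net, {"p1"}, {"p3", "q1"}) == pytest.approx(
        oracles.ppi_max_closeness(edges, {"p1"}, {"p3", "q1"})
    )


def test_ppi_invalid_decay_rejected():
    with pytest.raises(ValueError):
        ppi_closeness(_chain_net(), {"p1"}, {"p2"}, decay=0)


# ------------------------------------------------------------------- cosine

@pytest.mark.parametrize(
    "va, vb, expected",
    [
        (((0, 1), (1, 1)), ((0, 1), (1, 1)), 1.0),
        (((0, 1),), ((1, 2),), 0.0),
        (((0, 1), (1, 1)), ((0, 1), (2, 1)), 0.5),
        ((), ((0, 1),), 0.0),
    ],
)
def test_cosine_examples(va, vb, expected):
    assert description_cosine(va, vb) == pytest.approx(expected)


# ------------------------------------------------------------ full matrices

def test_seven_matrices_with_expected_shapes(small_kb, small_matrices):
    assert set(small_matrices) == set(DRUG_MEASURES) | set(DISEASE_MEASURES)
    for mid in DRUG_MEASURES:
        assert len(small_matrices[mid].ids) == len(small_kb.drugs)
    for mid in DISEASE_MEASURES:
        assert len(small_matrices[mid].ids) == len(small_kb.diseases)


def test_matrices_symmetric_bounded_unit_diagonal(small_matrices):
    for mat in small_matrices.values():
        v = mat.values
        assert np.allclose(v, v.T)
        assert v.min() >= 0.0 and v.max() <= 1.0
        assert np.allclose(np.diag(v), 1.0)


def test_matrix_entries_match_per_pair_calls(small_kb, small_matrices):
    """20 random entries per measure equal direct elementary-op calls."""
    rng = np.random.default_rng(0)
    drugs = {d.drug_id: d for d in small_kb.drugs}
    diseases = {s.disease_id: s for s in small_kb.diseases}
    proteins = {p.protein_id: p for p in small_kb.proteins}
    go_ic = information_content(
        small_kb.go_dag, {p.protein_id: set(p.go_terms) for p in small_kb.proteins}
    )
    hpo_ic = information_content(
        small_kb.hpo_dag, {s.disease_id: set(s.phenotype_terms) for s in small_kb.diseases}
    )

    def drug_pair_value(mid, a, b):
        da, db = drugs[a], drugs[b]
        if mid == "chemical":
            return jaccard_similarity(da.fingerprint, db.fingerprint)
        if mid == "side_effect":
            return jaccard_similarity(da.side_effects, db.side_effects)
        if mid == "ppi":
            return ppi_closeness(small_kb.ppi, da.targets, db.targets)
        best = 0.0
        for pa in sorted(da.targets):
            for pb in sorted(db.targets):
                if mid == "target_seq":
                    v = (
                        1.0
                        if pa == pb
                        else normalized_local_alignment(
                            proteins[pa].sequence, proteins[pb].sequence
                        )
                    )
                else:  # go
                    v = (
                        1.0
                        if pa == pb
                        else semantic_set_similarity(
                            proteins[pa].go_terms, proteins[pb].go_terms,
                            small_kb.go_dag, go_ic,
                        )
                    )
                best = max(best, v)
        return best

    for mid in DRUG_MEASURES:
        mat = small_matrices[mid]
        for _ in range(20):
            i, j = rng.integers(0, len(mat.ids), size=2)
            a, b = mat.ids[i], mat.ids[j]
            if a == b:
                continue
            assert mat.loc(a, b) == pytest.approx(drug_pair_value(mid, a, b), abs=1e-9), mid

    for _ in range(20):
        i, j = rng.integers(0, len(small_kb.diseases), size=2)
        a, b = small_matrices["mesh"].ids[i], small_matrices["mesh"].ids[j]
        if a == b:
            continue
        assert small_matrices["mesh"].loc(a, b) == pytest.approx(
            description_cosine(diseases[a].description_vector, diseases[b].description_vector)
        )
        assert small_matrices["hpo"].loc(a, b) == pytest.approx(
            semantic_set_similarity(
                diseases[a].phenotype_terms, diseases[b].phenotype_terms,
                small_kb.hpo_dag, hpo_ic,
            )
        )


def test_cluster_separation_in_every_measure(clean_kb):
    """Noise-free clusters: mean within-cluster similarity exceeds
    mean between-cluster similarity for all 7 measures."""
    mats = build_similarity_matrices(clean_kb)
    clusters = {**clean_kb.drug_clusters, **clean_kb.disease_clusters}
    for mid, mat in mats.items():
        within, between = [], []
        n = len(mat.ids)
        for i in range(n):
            for j in range(i + 1, n):
                v = mat.values[i, j]
                same = clusters[mat.ids[i]] == clusters[mat.ids[j]]
                (within if same else between).append(v)
        assert np.mean(within) > np.mean(between), mid


def test_empty_kb_rejected(small_kb):
    import dataclasses

    empty = dataclasses.replace(small_kb, drugs=[])
    with pytest.raises(ValueError):
        build_similarity_matrices(empty)
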
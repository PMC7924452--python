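"""Competency-question answering over workflow-provenance graphs.

The 13 questions fall in three groups: manual steps (CQ1.1-1.4),
workflow abstraction levels (CQ2.1-2.4) and versioning of workflows and
executions (CQ3.1-3.5).  Each is answered by a standalone SPARQL 1.1
query shipped under ``queries/`` (transitive step ordering uses property
paths); workflow and version IRIs are injected by string-safe template
substitution, so the same files can be run against an external store.
Result rows are canonicalized by lexicographic sort, making every
answer deterministic for a fixed graph.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from string import Template

from rdflib import Graph, URIRef

from .provenance import DUL, PPLAN, PWO

__all__ = ["CQResult", "VersionDiff", "answer_cq", "step_order", "diff_versions", "CQ_IDS"]

CQ_IDS = (
    "1.1", "1.2", "1.3", "1.4",
    "2.1", "2.2", "2.3", "2.4",
    "3.1", "3.2", "3.3", "3.4", "3.5",
)

#: which template parameters each question requires
_PARAMS = {
    "1.1": ("workflow",),
    "1.2": ("workflow",),
    "1.3": ("workflow",),
    "1.4": ("workflow",),
    "2.1": ("workflow",),
    "2.2": ("workflow",),
    "2.3": (),
    "2.4": (),
    "3.1": (),
    "3.2": ("old", "new"),
    "3.3": ("old", "new"),
    "3.4": ("old", "new"),
    "3.5": (),
}


@dataclass(frozen=True)
class CQResult:
    cq_id: str
    columns: tuple
    rows: tuple  # sorted tuples of strings ("" for unbound)


@dataclass(frozen=True)
class VersionDiff:
    removed: frozenset
    changed: frozenset  # new-version plans carrying a revision link
    added: frozenset

    def __post_init__(self):
        if self.removed & self.changed or self.changed & self.added or self.removed & self.added:
            raise ValueError("removed/changed/added sets must be pairwise disjoint")


def _load_query(name: str) -> str:
    return resources.files("fairpredict.queries").joinpath(f"{name}.rq").read_text()


def _iri(value) -> str:
    text = str(value)
    if not re.fullmatch(r"[^<>\"{}|^`\\\s]+", text):
        raise ValueError(f"unsafe IRI {text!r}")
    return f"<{text}>"


def _run(g: Graph, name: str, params: dict) -> tuple:
    query = Template(_load_query(name)).substitute(
        {k: _iri(v) for k, v in params.items()}
    )
    res = g.query(query)
    columns = tuple(str(v) for v in res.vars)
    rows = sorted(
        tuple("" if b is None else str(b) for b in row) for row in res
    )
    return columns, tuple(rows)


def answer_cq(g: Graph, cq_id: str, params: dict | None = None) -> CQResult:
    """Answer one competency question on a conforming provenance graph.

    ``params`` supplies the workflow IRI (CQ1.x, CQ2.1-2.2) or the
    ``old``/``new`` version IRIs (CQ3.2-3.4).
    """
    params = dict(params or {})
    if cq_id not in CQ_IDS:
        raise ValueError(f"unknown competency question {cq_id!r}")
    missing = [p for p in _PARAMS[cq_id] if p not in params]
    if missing:
        raise ValueError(f"CQ{cq_id} requires parameters: {missing}")
    params = {k: params[k] for k in _PARAMS[cq_id]}

    if cq_id == "3.2":
        try:
            diff = diff_versions(g, params["old"], params["new"])
        except ValueError:
            # query semantics: versions absent from the graph bind nothing
            return CQResult(cq_id=cq_id, columns=("plan", "change"), rows=())
        rows = sorted(
            [(p, "removed") for p in diff.removed]
            + [(p, "changed") for p in diff.changed]
            + [(p, "added") for p in diff.added]
        )
        return CQResult(cq_id=cq_id, columns=("plan", "change"), rows=tuple(rows))
    if cq_id == "3.4":
        rows = []
        for kind in ("removed", "changed", "added"):
            _, sub = _run(g, f"cq3_4_{kind}", params)
            rows.extend((r[-1], kind) for r in sub)
        return CQResult(cq_id=cq_id, columns=("distribution", "change"), rows=tuple(sorted(rows)))

    name = "cq" + cq_id.replace(".", "_")
    columns, rows = _run(g, name, params)
    if cq_id == "1.1":
        kind = {True: "manual", False: "script"}
        rows = tuple(
            sorted(
                (r[0], kind[r[1].endswith("ManualTask")], *r[2:]) for r in rows
            )
        )
        columns = ("step", "kind") + columns[2:]
    return CQResult(cq_id=cq_id, columns=columns, rows=rows)


def step_order(g: Graph, workflow) -> list:
    """Ordered steps of a workflow: start at ``pwo:hasFirstStep`` and
    follow ``dul:precedes`` (topological order, lexicographic ties)."""
    wf = URIRef(str(workflow))
    first = g.value(wf, PWO.hasFirstStep)
    if first is None:
        raise ValueError(f"workflow {workflow} has no first step")
    # reachable precedence subgraph
    nodes, edges = {first}, []
    frontier = [first]
    while frontier:
        n = frontier.pop()
        for succ in g.objects(n, DUL.precedes):
            edges.append((n, succ))
            if succ not in nodes:
                nodes.add(succ)
                frontier.append(succ)
    import networkx as nx

    dag = nx.DiGraph(edges)
    dag.add_nodes_from(nodes)
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("step precedence contains a cycle")
    order = list(nx.lexicographical_topological_sort(dag, key=str))
    return order


def _version_plans(g: Graph, version) -> set:
    wf = URIRef(str(version))
    if (wf, None, None) not in g and (None, None, wf) not in g:
        raise ValueError(f"unknown workflow version {version}")
    plans = set()
    for step in g.subjects(PPLAN.isStepOfPlan, wf):
        for plan in g.objects(step, DUL.isDescribedBy):
            plans.add(str(plan))
    return plans


def diff_versions(g: Graph, v_old, v_new) -> VersionDiff:
    """Instruction-plan diff between two workflow versions."""
    old_plans = _version_plans(g, v_old)
    new_plans = _version_plans(g, v_new)
    _, changed_rows = _run(g, "cq3_2_changed", {"old": v_old, "new": v_new})
    changed_new = {r[1] for r in changed_rows}
    changed_old = {r[0] for r in changed_rows}
    removed = old_plans - new_plans - changed_old
    added = new_plans - old_plans - changed_new
    return VersionDiff(
        removed=frozenset(removed),
        changed=frozenset(changed_new - removed - added),
        added=frozenset(added),
    )
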
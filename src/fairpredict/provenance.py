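"""Unified semantic workflow model: prospective, retrospective, versioned.

A workflow is a ``dul:Workflow`` and ``p-plan:Plan`` whose steps
(``p-plan:Step``, additionally typed ``bpmn:ManualTask`` or
``bpmn:ScriptTask`` and with an EDAM operation class) are lightweight
pointers ordered by ``pwo:hasFirstStep`` / ``dul:precedes``.  Each step
is decoupled from its instruction through
``p-plan:Step dul:isDescribedBy p-plan:Plan``; instructions bind
variables to dataset distributions through ``prov:qualifiedUsage``, and
agent roles attach to instructions through reified ``prov:Association``
nodes (``prov:agent`` / ``prov:hadRole`` / ``prov:hadPlan``).

Executions are ``p-plan:Activity`` nodes linked to their step with
``p-plan:correspondsToStep``; every evaluation metric becomes an
``mls:ModelEvaluation`` / ``opmw:WorkflowExecutionArtifact`` whose value
sits in ``dc:description`` and whose timestamp hangs off a
``prov:qualifiedGeneration``.  Versioning uses ``dc:hasVersion`` plus
``prov:wasRevisionOf`` links between versions of workflows and of
individual instructions.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
from rdflib import Graph, Literal, Namespace, RDF, RDFS
from rdflib.namespace import XSD
from rdflib.compare import isomorphic

__all__ = [
    "DEFAULT_BASE",
    "Namespaces",
    "DatasetDistribution",
    "StepSpec",
    "WorkflowSpec",
    "ActivityRecord",
    "RunRecord",
    "describe_workflow",
    "record_execution",
    "link_revision",
    "build_paper_fixture",
    "serialize_turtle",
    "parse_turtle",
    "graphs_isomorphic",
]

DEFAULT_BASE = "https://w3id.org/fair/plex"

PPLAN = Namespace("http://purl.org/net/p-plan#")
PROV = Namespace("http://www.w3.org/ns/prov#")
DUL = Namespace("http://www.ontologydesignpatterns.org/ont/dul/DUL.owl#")
PWO = Namespace("http://purl.org/spar/pwo/")
DCAT_NS = Namespace("http://www.w3.org/ns/dcat#")
MLS = Namespace("http://www.w3.org/ns/mls#")
OPMW = Namespace("http://www.opmw.org/ontology/")
EDAM = Namespace("http://edamontology.org/")
DC = Namespace("http://purl.org/dc/terms/")


class Namespaces:
    """Prefix bindings; the workflow and BPMN namespaces are minted
    under a configurable base."""

    def __init__(self, base: str = DEFAULT_BASE):
        self.base = base.rstrip("/#")
        self.opredict = Namespace(self.base + "/")
        self.bpmn = Namespace(self.base + "/bpmn#")

    def bind(self, g: Graph) -> Graph:
        g.bind("p-plan", PPLAN)
        g.bind("prov", PROV)
        g.bind("dul", DUL)
        g.bind("pwo", PWO)
        g.bind("dcat", DCAT_NS)
        g.bind("mls", MLS)
        g.bind("opmw", OPMW)
        g.bind("edam", EDAM)
        g.bind("dc", DC)
        g.bind("bpmn", self.bpmn)
        g.bind("opredict", self.opredict)
        return g

    def graph(self) -> Graph:
        return self.bind(Graph())


_DEFAULT_NS = Namespaces()

_TASK_CLASS = {"manual": "ManualTask", "script": "ScriptTask"}


@dataclass(frozen=True)
class DatasetDistribution:
    dist_id: str
    label: str
    download_url: str
    media_type: str

    def __post_init__(self):
        if not self.download_url:
            raise ValueError("distribution requires a download URL")


@dataclass(frozen=True)
class StepSpec:
    step_id: str
    label: str
    kind: str  # "manual" | "script"
    operation: str = "operation_2409"  # EDAM operation short id
    instruction: str = ""
    language: str = "English"
    language_kind: str = "natural"  # "natural" | "computer"
    language_version: str = ""
    input_vars: tuple = ()
    output_vars: tuple = ()
    usages: tuple = ()  # (distribution_id, variable_id) bindings
    described_by: str | None = None  # higher-level instruction plan id
    revision_of: str | None = None  # instruction plan id in the prior version
    agents: tuple = ()  # (agent_id, role) pairs

    def __post_init__(self):
        if self.kind not in _TASK_CLASS:
            raise ValueError(f"step kind must be 'manual' or 'script', got {self.kind!r}")

    @property
    def plan_id(self) -> str:
        return f"Plan_{self.step_id}"


@dataclass(frozen=True)
class WorkflowSpec:
    workflow_id: str
    version: str
    created: str
    modified: str
    creator: str
    steps: tuple  # ordered StepSpecs; consecutive steps form the precedence chain
    prior_version: str | None = None
    distributions: tuple = ()
    precedence: tuple = ()  # optional explicit (step_id, step_id) edges

    def __post_init__(self):
        if not self.steps:
            raise ValueError("workflow needs at least one step")
        ids = [s.step_id for s in self.steps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate step ids")

    def precedence_edges(self) -> list:
        if self.precedence:
            return list(self.precedence)
        ids = [s.step_id for s in self.steps]
        return list(zip(ids, ids[1:]))


@dataclass(frozen=True)
class ActivityRecord:
    step_id: str
    start: str  # ISO-8601, millisecond precision
    end: str
    metrics: tuple = ()  # (measure_name, value, timestamp)


@dataclass(frozen=True)
class RunRecord:
    run_id: str
    activities: tuple
    agent: str = "JupyterKernel"
    agent_version: str = "python3"


# --------------------------------------------------------------------------
# emitters
# --------------------------------------------------------------------------

def _language_node(g, ns, step: StepSpec):
    safe = step.language.replace(" ", "_").replace(".", "_")
    node = ns.opredict[f"LinguisticSystem_{step.language_kind}_{safe}"]
    g.add((node, RDF.type, DC.LinguisticSystem))
    g.add((node, RDFS.label, Literal(step.language)))
    if step.language_version:
        g.add((node, DC.hasVersion, Literal(step.language_version)))
    return node


def describe_workflow(spec: WorkflowSpec, ns: Namespaces | None = None) -> Graph:
    """Emit the prospective provenance graph of a workflow version."""
    ns = ns or _DEFAULT_NS
    dag = nx.DiGraph(spec.precedence_edges())
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("cyclic step precedence")

    g = ns.graph()
    wf = ns.opredict[spec.workflow_id]
    g.add((wf, RDF.type, PPLAN.Plan))
    g.add((wf, RDF.type, DUL.Workflow))
    g.add((wf, DC.created, Literal(spec.created)))
    g.add((wf, DC.modified, Literal(spec.modified)))
    g.add((wf, DC.creator, ns.opredict[f"Agent_{spec.creator}"]))
    g.add((wf, DC.hasVersion, Literal(spec.version)))
    g.add((wf, DC.description, Literal(f"{spec.workflow_id} v.{spec.version}")))
    g.add((wf, RDFS.label, Literal(spec.workflow_id.replace("_", " "))))
    g.add((wf, PROV.wasAttributedTo, ns.opredict[f"Agent_{spec.creator}"]))
    g.add((ns.opredict[f"Agent_{spec.creator}"], RDF.type, PROV.Agent))
    if spec.prior_version:
        g.add((wf, PROV.wasRevisionOf, ns.opredict[spec.prior_version]))
    g.add((wf, PWO.hasFirstStep, ns.opredict[spec.steps[0].step_id]))

    for dist in spec.distributions:
        dnode = ns.opredict[dist.dist_id]
        g.add((dnode, RDF.type, DCAT_NS.Distribution))
        g.add((dnode, RDFS.label, Literal(dist.label)))
        g.add((dnode, DCAT_NS.downloadURL, Literal(dist.download_url)))
        g.add((dnode, DCAT_NS.mediaType, ns.opredict[dist.media_type]))

    for step in spec.steps:
        snode = ns.opredict[step.step_id]
        plan = ns.opredict[step.plan_id]
        g.add((snode, RDF.type, PPLAN.Step))
        g.add((snode, RDF.type, ns.bpmn[_TASK_CLASS[step.kind]]))
        g.add((snode, RDF.type, EDAM[step.operation]))
        g.add((snode, PPLAN.isStepOfPlan, wf))
        g.add((snode, DUL.isDescribedBy, plan))
        g.add((snode, RDFS.label, Literal(step.label)))
        for var in step.input_vars:
            vnode = ns.opredict[f"Variable_{var}"]
            g.add((snode, PPLAN.hasInputVar, vnode))
            g.add((vnode, RDF.type, PPLAN.Variable))
            g.add((vnode, RDFS.label, Literal(var.replace("_", " "))))
        for var in step.output_vars:
            vnode = ns.opredict[f"Variable_{var}"]
            g.add((snode, PPLAN.hasOutputVar, vnode))
            g.add((vnode, RDF.type, PPLAN.Variable))
            g.add((vnode, RDFS.label, Literal(var.replace("_", " "))))

        g.add((plan, RDF.type, PPLAN.Plan))
        g.add((plan, DC.description, Literal(step.instruction or step.label)))
        g.add((plan, DC.language, _language_node(g, ns, step)))
        g.add((plan, RDFS.label, Literal(step.label)))
        g.add((plan, DC.creator, ns.opredict[f"Agent_{spec.creator}"]))
        if step.described_by:
            higher = ns.opredict[step.described_by]
            g.add((higher, RDF.type, PPLAN.Plan))
            g.add((plan, DUL.isDescribedBy, higher))
        if step.revision_of:
            g.add((plan, PROV.wasRevisionOf, ns.opredict[step.revision_of]))
        for dist_id, var in step.usages:
            usage = ns.opredict[f"Usage_Bind_{dist_id}_to_{var}"]
            g.add((plan, PROV.qualifiedUsage, usage))
            g.add((usage, RDF.type, PROV.Usage))
            g.add((usage, RDFS.label, Literal(f"Link variable to {dist_id}")))
            g.add((usage, PROV.entity, ns.opredict[dist_id]))
            g.add((usage, PROV.entity, ns.opredict[f"Variable_{var}"]))
            vnode = ns.opredict[f"Variable_{var}"]
            g.add((vnode, RDF.type, PPLAN.Variable))
        for agent, role in step.agents:
            assoc = ns.opredict[f"Association_{agent}_{role}_{step.step_id}"]
            g.add((assoc, RDF.type, PROV.Association))
            g.add((assoc, PROV.agent, ns.opredict[f"Agent_{agent}"]))
            g.add((assoc, PROV.hadRole, ns.opredict[f"Role_{role}"]))
            g.add((assoc, PROV.hadPlan, plan))
            g.add((ns.opredict[f"Agent_{agent}"], RDF.type, PROV.Agent))
            g.add((ns.opredict[f"Role_{role}"], RDF.type, PROV.Role))

    for a, b in spec.precedence_edges():
        g.add((ns.opredict[a], DUL.precedes, ns.opredict[b]))
    return g


def record_execution(spec: WorkflowSpec, run: RunRecord, ns: Namespaces | None = None) -> Graph:
    """Emit the retrospective provenance graph of one execution."""
    ns = ns or _DEFAULT_NS
    step_ids = {s.step_id for s in spec.steps}
    g = ns.graph()
    software = ns.opredict[f"Agent_{run.agent}"]
    if run.activities:
        g.add((software, RDF.type, PROV.SoftwareAgent))
        g.add((software, DC.hasVersion, Literal(run.agent_version)))
    for act in run.activities:
        if act.step_id not in step_ids:
            raise ValueError(f"activity references unknown step {act.step_id!r}")
        anode = ns.opredict[f"Activity_{act.step_id}_Execution_{run.run_id}"]
        g.add((anode, RDF.type, PPLAN.Activity))
        g.add((anode, PPLAN.correspondsToStep, ns.opredict[act.step_id]))
        g.add((anode, PROV.startedAtTime, Literal(act.start, datatype=XSD.dateTime)))
        g.add((anode, PROV.endedAtTime, Literal(act.end, datatype=XSD.dateTime)))
        g.add((anode, PROV.wasAssociatedWith, software))
        for name, value, timestamp in act.metrics:
            ev = ns.opredict[f"ModelEvaluation_{name}_Execution_{run.run_id}"]
            gen = ns.opredict[f"Generation_{name}_Execution_{run.run_id}"]
            g.add((anode, PROV.generated, ev))
            g.add((ev, RDF.type, MLS.ModelEvaluation))
            g.add((ev, RDF.type, OPMW.WorkflowExecutionArtifact))
            g.add((ev, DC.description, Literal(f"{value:.6f}" if isinstance(value, float) else str(value))))
            g.add((ev, MLS.specifiedBy, ns.opredict[f"EvaluationMeasure_{name}"]))
            g.add((ns.opredict[f"EvaluationMeasure_{name}"], RDF.type, MLS.EvaluationMeasure))
            g.add((ev, PROV.qualifiedGeneration, gen))
            g.add((gen, RDF.type, PROV.Generation))
            g.add((gen, PROV.atTime, Literal(timestamp, datatype=XSD.dateTime)))
    return g


def link_revision(new: WorkflowSpec, old: WorkflowSpec, ns: Namespaces | None = None) -> Graph:
    """Emit the evolution graph linking a workflow version to its parent."""
    ns = ns or _DEFAULT_NS
    if new.workflow_id == old.workflow_id:
        raise ValueError("a workflow cannot be a revision of itself")
    g = ns.graph()
    new_node, old_node = ns.opredict[new.workflow_id], ns.opredict[old.workflow_id]
    for node, spec in ((new_node, new), (old_node, old)):
        g.add((node, RDF.type, PPLAN.Plan))
        g.add((node, RDF.type, DUL.Workflow))
        g.add((node, DC.hasVersion, Literal(spec.version)))
    g.add((new_node, PROV.wasRevisionOf, old_node))
    old_plans = {s.plan_id for s in old.steps}
    for step in new.steps:
        if step.revision_of and step.revision_of in old_plans:
            g.add(
                (ns.opredict[step.plan_id], PROV.wasRevisionOf, ns.opredict[step.revision_of])
            )
    return g


# --------------------------------------------------------------------------
# fixture reproducing the published example listings
# --------------------------------------------------------------------------

def build_paper_fixture(ns: Namespaces | None = None) -> Graph:
    """Graph holding the published worked examples of the model.

    Reproduces, triple for triple, the printed prospective listing (the
    DrugBank download step with its instruction, usage, distribution and
    variable), the retrospective listing (execution 1546302862 with its
    six model-evaluation artifacts), and the versioning listing (main
    protocol v0.1 and v0.2), plus the minimal step/plan typing needed to
    query them as one graph.
    """
    ns = ns or _DEFAULT_NS
    g = ns.graph()
    op = ns.opredict

    # -- prospective: the DrugBank download step ---------------------------
    step = op["Step_Download_Drugbank_dataset"]
    g.add((step, RDF.type, ns.bpmn.ManualTask))
    g.add((step, RDF.type, EDAM.operation_2409))
    g.add((step, RDF.type, PPLAN.Step))
    g.add((step, PPLAN.hasOutputVar, op["Variable_Drugbank_dataset_online"]))
    g.add((step, PPLAN.isStepOfPlan, op["Plan_Main_Protocol_v01"]))
    g.add((step, DUL.isDescribedBy, op["Plan_Download_Drugbank_dataset"]))
    g.add((step, DUL.precedes, op["Step_Save_Drugbank_dataset"]))
    g.add((step, RDFS.label, Literal("Download Drugbank dataset")))

    plan = op["Plan_Download_Drugbank_dataset"]
    g.add((plan, RDF.type, PPLAN.Plan))
    g.add((plan, DC.description, Literal("Download Drugbank dataset")))
    g.add((plan, DC.language, op["LinguisticSystem_xsd_language_English"]))
    g.add((plan, RDFS.label, Literal("Download Drugbank dataset")))
    g.add((plan, PROV.qualifiedUsage, op["Usage_Fetch_download_Drugbank_dataset_to_variable"]))

    usage = op["Usage_Fetch_download_Drugbank_dataset_to_variable"]
    g.add((usage, RDF.type, PROV.Usage))
    g.add((usage, RDFS.label, Literal("Link variable to download Drugbank dataset")))
    g.add((usage, PROV.entity, op["Distribution_release-4-drugbank-drugbank.nq.gz"]))
    g.add((usage, PROV.entity, op["Variable_Drugbank_dataset_online"]))

    dist = op["Distribution_release-4-drugbank-drugbank.nq.gz"]
    g.add((dist, RDF.type, DCAT_NS.Distribution))
    g.add((dist, RDFS.label, Literal("release/4/drugbank/drugbank.nq.gz")))
    g.add(
        (
            dist,
            DCAT_NS.downloadURL,
            Literal("http://download.bio2rdf.org/files/release/4/drugbank/drugbank.nq.gz"),
        )
    )
    g.add((dist, DCAT_NS.mediaType, op["DataFormat_nq_compressed_gz"]))

    var = op["Variable_Drugbank_dataset_online"]
    g.add((var, RDF.type, PPLAN.Variable))
    g.add((var, RDFS.label, Literal("Drugbank dataset online")))

    # glue so the step chain is queryable
    save = op["Step_Save_Drugbank_dataset"]
    g.add((save, RDF.type, PPLAN.Step))
    g.add((save, RDF.type, ns.bpmn.ManualTask))
    g.add((save, PPLAN.isStepOfPlan, op["Plan_Main_Protocol_v01"]))
    g.add((save, RDFS.label, Literal("Save Drugbank dataset")))

    # -- retrospective: execution 1546302862 -------------------------------
    run = "1546302862"
    act = op[f"Activity_Model_preparation_train_and_evaluation_Execution_{run}"]
    g.add((act, RDF.type, PPLAN.Activity))
    g.add((act, PPLAN.correspondsToStep, op["Step_Model_preparation_train_and_evaluation"]))
    # artifact local names as printed (Precision lacks the Execution infix)
    for artifact in (
        f"ModelEvaluation_Accuracy_Execution_{run}",
        f"ModelEvaluation_AveragePrecision_Execution_{run}",
        f"ModelEvaluation_F1_Execution_{run}",
        f"ModelEvaluation_Precision_{run}",
        f"ModelEvaluation_Recall_Execution_{run}",
        f"ModelEvaluation_RocAuc_Execution_{run}",
    ):
        g.add((act, PROV.generated, op[artifact]))

    acc = op[f"ModelEvaluation_Accuracy_Execution_{run}"]
    g.add((acc, RDF.type, MLS.ModelEvaluation))
    g.add((acc, DC.description, Literal("0.833336")))
    g.add((acc, MLS.specifiedBy, op["EvaluationMeasure_PredictiveAccuracy"]))
    g.add((acc, PROV.qualifiedGeneration, op[f"Generation_Execution_{run}"]))

    gen = op[f"Generation_Execution_{run}"]
    g.add((gen, RDF.type, PROV.Generation))
    g.add((gen, PROV.atTime, Literal("2019-01-01T00:02:31.011", datatype=XSD.dateTime)))

    # glue: the evaluated step belongs to main protocol v0.1
    mstep = op["Step_Model_preparation_train_and_evaluation"]
    g.add((mstep, RDF.type, PPLAN.Step))
    g.add((mstep, RDF.type, ns.bpmn.ScriptTask))
    g.add((mstep, PPLAN.isStepOfPlan, op["Plan_Main_Protocol_v01"]))
    g.add((mstep, RDFS.label, Literal("Model preparation train and evaluation")))

    # -- versioning: main protocol v0.1 and v0.2 ---------------------------
    v02 = op["Plan_Main_Protocol_v02"]
    g.add((v02, RDF.type, PPLAN.Plan))
    g.add((v02, RDF.type, DUL.Workflow))
    g.add((v02, DC.created, Literal("2019-05-15")))
    g.add((v02, DC.creator, op["Agent_Remzi"]))
    g.add((v02, DC.description, Literal("OpenPREDICT Main Protocol v.0.2")))
    g.add((v02, DC.hasVersion, Literal("0.2")))
    g.add((v02, DC.language, op["LinguisticSystem_xsd_language_English"]))
    g.add((v02, DC.modified, Literal("2019-07-03")))
    g.add((v02, PWO.hasFirstStep, op["Step_Prepare_Input_Data_Files_v02"]))
    g.add((v02, RDFS.label, Literal("Main Protocol v.0.2")))
    g.add((v02, PROV.wasAttributedTo, op["Agent_Remzi"]))
    g.add((v02, PROV.wasRevisionOf, op["Plan_Main_Protocol_v01"]))

    v01 = op["Plan_Main_Protocol_v01"]
    g.add((v01, RDF.type, PPLAN.Plan))
    g.add((v01, RDF.type, DUL.Workflow))
    g.add((v01, DC.created, Literal("2018-11-27")))
    g.add((v01, DC.creator, op["Agent_Remzi"]))
    g.add((v01, DC.description, Literal("OpenPREDICT Main Protocol v.0.1")))
    g.add((v01, DC.hasVersion, Literal("0.1")))
    g.add((v01, DC.language, op["LinguisticSystem_xsd_language_English"]))
    g.add((v01, DC.modified, Literal("2019-05-15")))
    g.add((v01, PWO.hasFirstStep, op["Step_Prepare_Input_Data_Files"]))
    g.add((v01, RDFS.label, Literal("Main Protocol v.0.1")))
    g.add((v01, PROV.wasAttributedTo, op["Agent_Remzi"]))

    g.add((op["Agent_Remzi"], RDF.type, PROV.Agent))
    return g


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

def serialize_turtle(g: Graph) -> str:
    return g.serialize(format="turtle")


def parse_turtle(text: str) -> Graph:
    g = Graph()
    g.parse(data=text, format="turtle")
    return _DEFAULT_NS.bind(g)


def graphs_isomorphic(a: Graph, b: Graph) -> bool:
    return isomorphic(a, b)
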
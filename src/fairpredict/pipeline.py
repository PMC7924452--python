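"""End-to-end orchestration: generate -> similarities -> features -> CV
-> provenance -> competency report, reproducible from one seed.

The run follows the four-step protocol (data preparation, feature
generation, model training and evaluation, presentation of results);
its prospective description, the retrospective trace whose model-
evaluation artifacts carry the aggregated cross-validation metrics, and
every written file are emitted as one provenance record.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace
from datetime import datetime, timedelta
from pathlib import Path

from rdflib import Literal, RDF, RDFS

from . import kb_synth, model_eval, provenance
from .fusion import FusionConfig
from .kb_synth import GeneratorConfig
from .provenance import (
    ActivityRecord,
    DatasetDistribution,
    Namespaces,
    OPMW,
    PROV,
    RunRecord,
    StepSpec,
    WorkflowSpec,
)
from .similarity import SimilarityParams, build_similarity_matrices

__all__ = ["PipelineConfig", "default_workflow_spec", "run_pipeline"]

logger = logging.getLogger(__name__)

#: provenance measure names for the six evaluation metrics
_MEASURE_NAMES = {
    "accuracy": "Accuracy",
    "aupr": "AveragePrecision",
    "f_score": "F1",
    "precision": "Precision",
    "recall": "Recall",
    "roc_auc": "RocAuc",
}


@dataclass(frozen=True)
class PipelineConfig:
    generator: GeneratorConfig = GeneratorConfig()
    fusion: FusionConfig = FusionConfig()
    similarity: SimilarityParams = SimilarityParams()
    strategy: str = "drug_wise"
    k: int = 10
    repetitions: int = 10
    neg_ratio: float = 1.0
    emit_provenance: bool = True
    out_dir: str | None = None
    seed: int = 0
    fixed_clock: bool = False

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "generator" in data:
            data["generator"] = GeneratorConfig(**data["generator"])
        if "fusion" in data:
            data["fusion"] = FusionConfig(**data["fusion"])
        if "similarity" in data:
            data["similarity"] = SimilarityParams(**data["similarity"])
        return cls(**data)


class _Clock:
    """Millisecond ISO-8601 timestamps; fixed mode ticks deterministically."""

    def __init__(self, fixed: bool):
        self.fixed = fixed
        self._tick = itertools.count()
        self._epoch = datetime(2019, 1, 1)

    def now(self) -> str:
        if self.fixed:
            t = self._epoch + timedelta(seconds=next(self._tick))
        else:
            t = datetime.now()
        return t.strftime("%Y-%m-%dT%H:%M:%S.") + f"{t.microsecond // 1000:03d}"


def default_workflow_spec(version: str = "0.1", prior: str | None = None) -> WorkflowSpec:
    """The four-step prediction protocol as a prospective workflow."""
    steps = (
        StepSpec(
            step_id="Step_Prepare_Input_Data",
            label="Prepare input data",
            kind="script",
            operation="operation_2409",
            instruction="Generate or load the knowledge base tables",
            language="Python",
            language_kind="computer",
            language_version="3",
            output_vars=("Knowledge_base_bundle",),
            usages=(("Distribution_kb_manifest", "Knowledge_base_bundle"),),
            agents=(("Runner", "Executor"),),
        ),
        StepSpec(
            step_id="Step_Feature_Generation",
            label="Feature generation",
            kind="script",
            operation="operation_2945",
            instruction="Compute the 7 similarity matrices and fuse the 10 features",
            language="Python",
            language_kind="computer",
            language_version="3",
            input_vars=("Knowledge_base_bundle",),
            output_vars=("Similarity_matrices", "Feature_table"),
            agents=(("Runner", "Executor"),),
        ),
        StepSpec(
            step_id="Step_Model_Training_Evaluation",
            label="Model training and evaluation",
            kind="script",
            operation="operation_2423",
            instruction="Train the logistic classifier under repeated k-fold CV",
            language="Python",
            language_kind="computer",
            language_version="3",
            input_vars=("Feature_table",),
            output_vars=("Evaluation_report",),
            agents=(("Runner", "Executor"),),
        ),
        StepSpec(
            step_id="Step_Present_Results",
            label="Format results for presentation",
            kind="script",
            operation="operation_0337",
            instruction="Serialize the report and provenance graphs",
            language="Python",
            language_kind="computer",
            language_version="3",
            input_vars=("Evaluation_report",),
            output_vars=("Report_files",),
            agents=(("Runner", "Executor"),),
        ),
    )
    distributions = (
        DatasetDistribution(
            dist_id="Distribution_kb_manifest",
            label="kb/manifest.json",
            download_url="file://kb/manifest.json",
            media_type="DataFormat_json",
        ),
    )
    return WorkflowSpec(
        workflow_id=f"Workflow_Prediction_Protocol_v{version.replace('.', '')}",
        version=version,
        created="2019-01-01",
        modified="2019-01-01",
        creator="Runner",
        steps=steps,
        prior_version=prior,
        distributions=distributions,
    )


def run_pipeline(cfg: PipelineConfig):
    """Execute the whole protocol; returns (report, prospective graph,
    retrospective graph)."""
    clock = _Clock(cfg.fixed_clock)
    generator = replace(cfg.generator, seed=cfg.seed)

    logger.info("stage=generate seed=%d n_drugs=%d", cfg.seed, generator.n_drugs)
    try:
        kb = kb_synth.generate_knowledge_base(generator)
    except Exception as exc:
        raise RuntimeError(f"data preparation failed: {exc}") from exc

    logger.info("stage=similarities n_measures=7")
    try:
        matrices = build_similarity_matrices(kb, cfg.similarity)
    except Exception as exc:
        raise RuntimeError(f"feature generation failed: {exc}") from exc

    logger.info(
        "stage=crossval strategy=%s k=%d reps=%d", cfg.strategy, cfg.k, cfg.repetitions
    )
    try:
        report = model_eval.run_cross_validation(
            kb,
            matrices,
            strategy=cfg.strategy,
            k=cfg.k,
            repetitions=cfg.repetitions,
            neg_ratio=cfg.neg_ratio,
            seed=cfg.seed,
            fusion_cfg=cfg.fusion,
        )
    except Exception as exc:
        raise RuntimeError(f"model evaluation failed: {exc}") from exc

    ns = Namespaces()
    spec = default_workflow_spec()
    prospective = provenance.describe_workflow(spec, ns)

    run_id = str(cfg.seed) if cfg.fixed_clock else str(int(datetime.now().timestamp()))
    summary = report.summary
    metrics = tuple(
        (_MEASURE_NAMES[m], summary[m]["mean"], clock.now()) for m in sorted(_MEASURE_NAMES)
    )
    activities = []
    for step in spec.steps:
        start, end = clock.now(), clock.now()
        activities.append(
            ActivityRecord(
                step_id=step.step_id,
                start=start,
                end=end,
                metrics=metrics if step.step_id == "Step_Model_Training_Evaluation" else (),
            )
        )
    run = RunRecord(run_id=run_id, activities=tuple(activities))
    retrospective = provenance.record_execution(spec, run, ns)

    if cfg.out_dir is not None:
        written = _write_artifacts(cfg, kb, matrices, report, prospective, retrospective, ns)
        _reference_artifacts(retrospective, ns, run_id, written)
        (Path(cfg.out_dir) / "retrospective.ttl").write_text(
            provenance.serialize_turtle(retrospective)
        )
    return report, prospective, retrospective


def _write_artifacts(cfg, kb, matrices, report, prospective, retrospective, ns):
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    kb_synth.write_kb(kb, out / "kb")
    written = {"Step_Prepare_Input_Data": ["kb/manifest.json"]}
    sim_dir = out / "similarities"
    sim_dir.mkdir(exist_ok=True)
    feats = []
    for mid, mat in sorted(matrices.items()):
        mat.to_frame().to_csv(sim_dir / f"{mid}.csv")
        feats.append(f"similarities/{mid}.csv")
    written["Step_Feature_Generation"] = feats
    report.write(out / "report.csv", out / "report.json")
    written["Step_Model_Training_Evaluation"] = ["report.csv", "report.json"]
    (out / "prospective.ttl").write_text(provenance.serialize_turtle(prospective))
    written["Step_Present_Results"] = ["prospective.ttl", "retrospective.ttl"]
    return written


def _reference_artifacts(retro, ns, run_id, written):
    for step_id, files in written.items():
        activity = ns.opredict[f"Activity_{step_id}_Execution_{run_id}"]
        for f in files:
            node = ns.opredict[f"Artifact_{f.replace('/', '_').replace('.', '_')}_{run_id}"]
            retro.add((activity, PROV.generated, node))
            retro.add((node, RDF.type, OPMW.WorkflowExecutionArtifact))
            retro.add((node, RDFS.label, Literal(f)))
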
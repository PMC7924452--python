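"""Synthetic knowledge bases with planted drug--disease signal.

The generator emulates the statistical structure that similarity-based
drug repurposing assumes: drugs and diseases fall into latent clusters,
drugs within a cluster share chemical fingerprints, side effects,
protein targets and GO annotations, and gold-standard indications
preferentially link a drug cluster to its matching disease cluster.
All randomness flows from a single integer seed, so a knowledge base is
a pure function of its :class:`GeneratorConfig`.

Also provided: readers for the tab-separated input formats used by the
real pipeline (gold standard, protein--protein interactions, phenotype
annotations), an on-disk bundle format (JSON manifest + CSV/TSV/FASTA),
and the FAIRified RDF representation of the inputs (Bio2RDF-style
interaction nodes, SIO disease/has-phenotype links, DCAT metadata).
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from rdflib import Graph, Literal, Namespace, RDF, RDFS, URIRef
from rdflib.namespace import DCTERMS, DCAT

__all__ = [
    "ConfigurationError",
    "ParseError",
    "GeneratorConfig",
    "DrugRecord",
    "ProteinRecord",
    "DiseaseRecord",
    "OntologyDAG",
    "ProteinNetwork",
    "KnowledgeBase",
    "generate_knowledge_base",
    "load_gold_standard_table",
    "load_ppi_table",
    "load_phenotype_annotations",
    "write_kb",
    "read_kb",
    "emit_input_rdf",
]


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


class ParseError(ValueError):
    """Malformed tabular input; the message names the offending line."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic knowledge-base generator.

    ``signal_strength`` (rho) is the probability that a gold association
    links a drug to a disease of its own latent cluster;
    ``modality_noise`` corrupts every per-entity modality (bit flips,
    term swaps, residue mutations) at the given rate.
    """

    n_drugs: int = 120
    n_diseases: int = 80
    n_proteins: int = 100
    fingerprint_length: int = 166
    n_clusters: int = 10
    signal_strength: float = 0.9
    modality_noise: float = 0.05
    associations_per_drug: float = 2.0
    seed: int = 0
    # secondary sizes (vocabularies and ontologies)
    n_side_effect_terms: int = 120
    vocab_size: int = 300
    n_go_terms: int = 200
    n_hpo_terms: int = 150
    targets_per_cluster: int = 3
    sequence_length: int = 120

    def validate(self) -> None:
        counts = {
            "n_drugs": self.n_drugs,
            "n_diseases": self.n_diseases,
            "n_proteins": self.n_proteins,
            "fingerprint_length": self.fingerprint_length,
            "n_clusters": self.n_clusters,
            "n_side_effect_terms": self.n_side_effect_terms,
            "vocab_size": self.vocab_size,
            "n_go_terms": self.n_go_terms,
            "n_hpo_terms": self.n_hpo_terms,
            "targets_per_cluster": self.targets_per_cluster,
            "sequence_length": self.sequence_length,
        }
        for name, v in counts.items():
            if not isinstance(v, int) or v <= 0:
                raise ConfigurationError(f"{name} must be a positive integer, got {v!r}")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ConfigurationError("signal_strength must lie in [0, 1]")
        if not 0.0 <= self.modality_noise <= 1.0:
            raise ConfigurationError("modality_noise must lie in [0, 1]")
        if self.associations_per_drug <= 0:
            raise ConfigurationError("associations_per_drug must be positive")
        if self.n_clusters > min(self.n_drugs, self.n_diseases):
            raise ConfigurationError("n_clusters exceeds the number of drugs or diseases")


@dataclass(frozen=True)
class DrugRecord:
    drug_id: str
    fingerprint: frozenset  # bit indices in [0, F)
    side_effects: frozenset  # side-effect term ids
    targets: frozenset  # protein ids


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    sequence: str
    go_terms: frozenset


@dataclass(frozen=True)
class DiseaseRecord:
    disease_id: str
    phenotype_terms: frozenset
    description_vector: tuple  # sorted ((term_index, count), ...)


@dataclass(frozen=True)
class OntologyDAG:
    """Rooted is-a DAG: every non-root term reaches the single root."""

    terms: tuple
    edges: frozenset  # (child, parent) pairs
    root: str

    def __post_init__(self):
        parents: dict[str, set] = {t: set() for t in self.terms}
        for child, parent in self.edges:
            if child not in parents or parent not in parents:
                raise ValueError(f"edge ({child}, {parent}) uses unknown term")
            parents[child].add(parent)
        object.__setattr__(self, "_parents", parents)
        # acyclicity + rootedness via memoised ancestor closure
        anc: dict[str, frozenset] = {}
        state: dict[str, int] = {}

        def close(t: str) -> frozenset:
            if t in anc:
                return anc[t]
            if state.get(t) == 1:
                raise ValueError("ontology contains a cycle")
            state[t] = 1
            out = {t}
            for p in parents[t]:
                out |= close(p)
            state[t] = 2
            anc[t] = frozenset(out)
            return anc[t]

        for t in self.terms:
            closure = close(t)
            if self.root not in closure:
                raise ValueError(f"term {t} does not reach the root")
        object.__setattr__(self, "_ancestors", anc)

    def ancestors(self, term: str) -> frozenset:
        """All ancestors of ``term``, inclusive of the term itself."""
        return self._ancestors[term]

    def parents_of(self, term: str) -> frozenset:
        return frozenset(self._parents[term])

    def depth(self, term: str) -> int:
        if term == self.root:
            return 0
        return 1 + min(self.depth(p) for p in self._parents[term])


@dataclass(frozen=True)
class ProteinNetwork:
    """Simple undirected graph over protein ids (no self loops)."""

    nodes: tuple
    edges: frozenset  # frozenset of 2-tuples, each sorted

    def __post_init__(self):
        nodeset = set(self.nodes)
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self loop on {a}")
            if a not in nodeset or b not in nodeset:
                raise ValueError(f"edge ({a}, {b}) uses unknown node")

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


@dataclass
class KnowledgeBase:
    drugs: list
    diseases: list
    proteins: list
    ppi: ProteinNetwork
    go_dag: OntologyDAG
    hpo_dag: OntologyDAG
    vocab_size: int
    gold: set  # {(drug_id, disease_id)}
    gen_seed: int
    gen_config: GeneratorConfig
    drug_clusters: dict = field(default_factory=dict)
    disease_clusters: dict = field(default_factory=dict)
    protein_clusters: dict = field(default_factory=dict)

    def __eq__(self, other):
        if not isinstance(other, KnowledgeBase):
            return NotImplemented
        return (
            self.drugs == other.drugs
            and self.diseases == other.diseases
            and self.proteins == other.proteins
            and self.ppi == other.ppi
            and self.go_dag == other.go_dag
            and self.hpo_dag == other.hpo_dag
            and self.vocab_size == other.vocab_size
            and self.gold == other.gold
            and self.gen_seed == other.gen_seed
            and self.gen_config == other.gen_config
            and self.drug_clusters == other.drug_clusters
            and self.disease_clusters == other.disease_clusters
            and self.protein_clusters == other.protein_clusters
        )

    def validate(self) -> None:
        protein_ids = {p.protein_id for p in self.proteins}
        go_terms = set(self.go_dag.terms)
        hpo_terms = set(self.hpo_dag.terms)
        drug_ids = {d.drug_id for d in self.drugs}
        disease_ids = {d.disease_id for d in self.diseases}
        for d in self.drugs:
            bad = [b for b in d.fingerprint if not 0 <= b < self.gen_config.fingerprint_length]
            if bad:
                raise ValueError(f"{d.drug_id}: fingerprint bits out of range: {bad}")
            if not d.targets <= protein_ids:
                raise ValueError(f"{d.drug_id}: unresolved targets {d.targets - protein_ids}")
        for p in self.proteins:
            if not p.sequence:
                raise ValueError(f"{p.protein_id}: empty sequence")
            if not p.go_terms <= go_terms:
                raise ValueError(f"{p.protein_id}: GO terms outside the DAG")
        for s in self.diseases:
            if not s.phenotype_terms <= hpo_terms:
                raise ValueError(f"{s.disease_id}: phenotype terms outside the DAG")
            if not s.description_vector:
                raise ValueError(f"{s.disease_id}: empty description vector")
        for dr, di in self.gold:
            if dr not in drug_ids or di not in disease_ids:
                raise ValueError(f"gold pair ({dr}, {di}) references unknown entities")


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

def _random_ontology(rng: np.random.Generator, prefix: str, n_terms: int) -> OntologyDAG:
    """Random rooted tree plus ~10% extra is-a edges, minimum depth 4.

    Nodes are indexed so that every parent has a smaller index than its
    child; extra edges also point to smaller indices, which guarantees
    acyclicity by construction.
    """
    terms = [f"{prefix}:{i:07d}" for i in range(n_terms)]
    edges = set()
    # backbone chain of depth 5 guarantees nontrivial depth
    backbone = min(6, n_terms)
    for i in range(1, backbone):
        edges.add((terms[i], terms[i - 1]))
    for i in range(backbone, n_terms):
        parent = int(rng.integers(0, i))
        edges.add((terms[i], terms[parent]))
    n_extra = max(1, n_terms // 10)
    for _ in range(n_extra):
        child = int(rng.integers(1, n_terms))
        parent = int(rng.integers(0, child))
        if (terms[child], terms[parent]) not in edges:
            edges.add((terms[child], terms[parent]))
    return OntologyDAG(terms=tuple(terms), edges=frozenset(edges), root=terms[0])


def _perturb_terms(rng, proto: list, universe: list, noise: float) -> frozenset:
    """Keep each prototype term w.p. 1-noise, else swap for a random one."""
    out = set()
    for t in proto:
        if rng.random() < noise:
            out.add(universe[int(rng.integers(0, len(universe)))])
        else:
            out.add(t)
    if not out:  # records are generated complete
        out.add(proto[0])
    return frozenset(out)


def _mutate_sequence(rng, seq: str, rate: float) -> str:
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = AMINO_ACIDS[int(rng.integers(0, 20))]
    return "".join(chars)


def generate_knowledge_base(config: GeneratorConfig) -> KnowledgeBase:
    """Generate a clustered knowledge base; deterministic in (config, seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    K = config.n_clusters
    noise = config.modality_noise
    rho = config.signal_strength

    go_dag = _random_ontology(rng, "GO", config.n_go_terms)
    hpo_dag = _random_ontology(rng, "HP", config.n_hpo_terms)
    deep_go = [t for t in go_dag.terms if go_dag.depth(t) >= 2] or list(go_dag.terms)
    deep_hpo = [t for t in hpo_dag.terms if hpo_dag.depth(t) >= 2] or list(hpo_dag.terms)
    se_vocab = [f"SE:{i:05d}" for i in range(config.n_side_effect_terms)]

    drug_ids = [f"DR{i:04d}" for i in range(config.n_drugs)]
    disease_ids = [f"DI{i:04d}" for i in range(config.n_diseases)]
    protein_ids = [f"PR{i:04d}" for i in range(config.n_proteins)]

    drug_clusters = {d: i % K for i, d in enumerate(drug_ids)}
    disease_clusters = {d: i % K for i, d in enumerate(disease_ids)}
    protein_clusters = {p: i % K for i, p in enumerate(protein_ids)}

    # cluster prototypes
    F = config.fingerprint_length
    proto_fp = [rng.random(F) < 0.15 for _ in range(K)]
    proto_se = [
        sorted(rng.choice(len(se_vocab), size=min(10, len(se_vocab)), replace=False))
        for _ in range(K)
    ]
    cluster_proteins = {c: [p for p in protein_ids if protein_clusters[p] == c] for c in range(K)}
    proto_targets = [
        sorted(
            rng.choice(
                cluster_proteins[c],
                size=min(config.targets_per_cluster, len(cluster_proteins[c])),
                replace=False,
            )
        )
        for c in range(K)
    ]
    proto_go = [
        [deep_go[j] for j in sorted(rng.choice(len(deep_go), size=min(6, len(deep_go)), replace=False))]
        for _ in range(K)
    ]
    proto_hpo = [
        [deep_hpo[j] for j in sorted(rng.choice(len(deep_hpo), size=min(8, len(deep_hpo)), replace=False))]
        for _ in range(K)
    ]
    proto_seq = [
        "".join(AMINO_ACIDS[int(j)] for j in rng.integers(0, 20, size=config.sequence_length))
        for _ in range(K)
    ]
    proto_desc = []
    for _ in range(K):
        idx = sorted(rng.choice(config.vocab_size, size=min(20, config.vocab_size), replace=False))
        counts = rng.integers(1, 6, size=len(idx))
        proto_desc.append(list(zip((int(i) for i in idx), (int(c) for c in counts))))

    proteins = []
    for p in protein_ids:
        c = protein_clusters[p]
        seq = _mutate_sequence(rng, proto_seq[c], noise)
        terms = _perturb_terms(rng, proto_go[c], list(go_dag.terms), noise)
        proteins.append(ProteinRecord(protein_id=p, sequence=seq, go_terms=terms))

    drugs = []
    for d in drug_ids:
        c = drug_clusters[d]
        flips = rng.random(F) < noise
        bits = np.nonzero(proto_fp[c] ^ flips)[0]
        if bits.size == 0:
            bits = np.array([int(rng.integers(0, F))])
        se = _perturb_terms(rng, [se_vocab[i] for i in proto_se[c]], se_vocab, noise)
        targets = _perturb_terms(rng, list(proto_targets[c]), protein_ids, noise)
        drugs.append(
            DrugRecord(
                drug_id=d,
                fingerprint=frozenset(int(b) for b in bits),
                side_effects=se,
                targets=targets,
            )
        )

    diseases = []
    for s in disease_ids:
        c = disease_clusters[s]
        terms = _perturb_terms(rng, proto_hpo[c], list(hpo_dag.terms), noise)
        vec = {}
        for idx, count in proto_desc[c]:
            if rng.random() < noise:
                idx = int(rng.integers(0, config.vocab_size))
            vec[idx] = vec.get(idx, 0) + count
        diseases.append(
            DiseaseRecord(
                disease_id=s,
                phenotype_terms=terms,
                description_vector=tuple(sorted(vec.items())),
            )
        )

    # PPI graph: dense within clusters, sparse between
    edges = set()
    p_in, p_out = 0.3, 0.01
    for i in range(config.n_proteins):
        for j in range(i + 1, config.n_proteins):
            same = protein_clusters[protein_ids[i]] == protein_clusters[protein_ids[j]]
            if rng.random() < (p_in if same else p_out):
                edges.add((protein_ids[i], protein_ids[j]))
    ppi = ProteinNetwork(nodes=tuple(protein_ids), edges=frozenset(edges))

    # gold standard: drug-cluster c links to disease-cluster c w.p. rho
    cluster_diseases = {c: [s for s in disease_ids if disease_clusters[s] == c] for c in range(K)}
    gold = set()
    for d in drug_ids:
        c = drug_clusters[d]
        n_assoc = max(1, int(rng.poisson(config.associations_per_drug)))
        for _ in range(n_assoc):
            if rng.random() < rho:
                pool = cluster_diseases[c]
            else:
                pool = disease_ids
            gold.add((d, pool[int(rng.integers(0, len(pool)))]))

    kb = KnowledgeBase(
        drugs=drugs,
        diseases=diseases,
        proteins=proteins,
        ppi=ppi,
        go_dag=go_dag,
        hpo_dag=hpo_dag,
        vocab_size=config.vocab_size,
        gold=gold,
        gen_seed=config.seed,
        gen_config=config,
        drug_clusters=drug_clusters,
        disease_clusters=disease_clusters,
        protein_clusters=protein_clusters,
    )
    kb.validate()
    return kb


# --------------------------------------------------------------------------
# tabular readers
# --------------------------------------------------------------------------

_HEADER_TOKENS = {
    "drug", "drug_id", "drugbank_id", "disease", "disease_id", "omim_id",
    "indication", "interactor_a", "interactor_b", "protein_a", "protein_b",
    "term", "term_id", "hpo_id",
}


def _rows(text: str):
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        yield lineno, line.split("\t")


def _is_header(fields) -> bool:
    return any(f.strip().lower() in _HEADER_TOKENS for f in fields)


def load_gold_standard_table(text: str) -> set:
    """Parse a two-column tab-separated gold standard into an association set.

    Duplicate rows collapse (set semantics); a header row is skipped.
    """
    assoc = set()
    first = True
    for lineno, fields in _rows(text):
        if first and _is_header(fields):
            first = False
            continue
        first = False
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise ParseError(f"line {lineno}: expected drug and disease columns")
        assoc.add((fields[0].strip(), fields[1].strip()))
    return assoc


def load_ppi_table(text: str) -> ProteinNetwork:
    """Parse a tab-separated interactor list into a simple undirected graph.

    Self-loop rows are dropped with a warning.
    """
    nodes, edges = set(), set()
    first = True
    for lineno, fields in _rows(text):
        if first and _is_header(fields):
            first = False
            continue
        first = False
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise ParseError(f"line {lineno}: expected two interactor columns")
        a, b = fields[0].strip(), fields[1].strip()
        if a == b:
            warnings.warn(f"line {lineno}: dropping self loop on {a}")
            nodes.add(a)
            continue
        nodes.update((a, b))
        edges.add(tuple(sorted((a, b))))
    return ProteinNetwork(nodes=tuple(sorted(nodes)), edges=frozenset(edges))


def load_phenotype_annotations(text: str) -> dict:
    """Parse disease-id / term-id rows into a disease -> term-set map."""
    out: dict[str, set] = {}
    first = True
    for lineno, fields in _rows(text):
        if first and _is_header(fields):
            first = False
            continue
        first = False
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise ParseError(f"line {lineno}: expected disease and term columns")
        out.setdefault(fields[0].strip(), set()).add(fields[1].strip())
    return out


# --------------------------------------------------------------------------
# on-disk bundle (manifest.json + CSV/TSV + FASTA)
# --------------------------------------------------------------------------

def _join(items) -> str:
    return ";".join(sorted(items))


def write_kb(kb: KnowledgeBase, directory) -> None:
    """Write a KB bundle; byte-identical for identical knowledge bases."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    manifest = {
        "gen_seed": kb.gen_seed,
        "gen_config": asdict(kb.gen_config),
        "vocab_size": kb.vocab_size,
        "go_dag": {
            "terms": list(kb.go_dag.terms),
            "edges": sorted(map(list, kb.go_dag.edges)),
            "root": kb.go_dag.root,
        },
        "hpo_dag": {
            "terms": list(kb.hpo_dag.terms),
            "edges": sorted(map(list, kb.hpo_dag.edges)),
            "root": kb.hpo_dag.root,
        },
        "drug_clusters": kb.drug_clusters,
        "disease_clusters": kb.disease_clusters,
        "protein_clusters": kb.protein_clusters,
        "gold": sorted(map(list, kb.gold)),
    }
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )

    with open(directory / "drugs.csv", "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["drug_id", "fingerprint", "side_effects", "targets"])
        for d in sorted(kb.drugs, key=lambda r: r.drug_id):
            w.writerow(
                [
                    d.drug_id,
                    ";".join(str(b) for b in sorted(d.fingerprint)),
                    _join(d.side_effects),
                    _join(d.targets),
                ]
            )
    with open(directory / "diseases.csv", "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["disease_id", "description_vector"])
        for s in sorted(kb.diseases, key=lambda r: r.disease_id):
            w.writerow(
                [s.disease_id, ";".join(f"{i}:{c}" for i, c in s.description_vector)]
            )
    with open(directory / "ppi.tsv", "w") as fh:
        for n in kb.ppi.nodes:
            fh.write(f"#node\t{n}\n")
        for a, b in sorted(kb.ppi.edges):
            fh.write(f"{a}\t{b}\n")
    with open(directory / "annotations.tsv", "w") as fh:
        for p in sorted(kb.proteins, key=lambda r: r.protein_id):
            for t in sorted(p.go_terms):
                fh.write(f"{p.protein_id}\t{t}\n")
        for s in sorted(kb.diseases, key=lambda r: r.disease_id):
            for t in sorted(s.phenotype_terms):
                fh.write(f"{s.disease_id}\t{t}\n")
    with open(directory / "proteins.fasta", "w") as fh:
        for p in sorted(kb.proteins, key=lambda r: r.protein_id):
            fh.write(f">{p.protein_id}\n{p.sequence}\n")


def read_kb(directory) -> KnowledgeBase:
    """Read a KB bundle written by :func:`write_kb`."""
    from Bio import SeqIO

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    config = GeneratorConfig(**manifest["gen_config"])
    go_dag = OntologyDAG(
        terms=tuple(manifest["go_dag"]["terms"]),
        edges=frozenset(tuple(e) for e in manifest["go_dag"]["edges"]),
        root=manifest["go_dag"]["root"],
    )
    hpo_dag = OntologyDAG(
        terms=tuple(manifest["hpo_dag"]["terms"]),
        edges=frozenset(tuple(e) for e in manifest["hpo_dag"]["edges"]),
        root=manifest["hpo_dag"]["root"],
    )

    sequences = {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(directory / "proteins.fasta"), "fasta")
    }
    go_ann: dict[str, set] = {}
    hpo_ann: dict[str, set] = {}
    for line in (directory / "annotations.tsv").read_text().splitlines():
        ent, term = line.split("\t")
        (go_ann if term.startswith("GO:") else hpo_ann).setdefault(ent, set()).add(term)
    proteins = [
        ProteinRecord(protein_id=p, sequence=seq, go_terms=frozenset(go_ann.get(p, ())))
        for p, seq in sorted(sequences.items())
    ]

    drugs = []
    with open(directory / "drugs.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            drugs.append(
                DrugRecord(
                    drug_id=row["drug_id"],
                    fingerprint=frozenset(
                        int(b) for b in row["fingerprint"].split(";") if b
                    ),
                    side_effects=frozenset(
                        t for t in row["side_effects"].split(";") if t
                    ),
                    targets=frozenset(t for t in row["targets"].split(";") if t),
                )
            )
    diseases = []
    with open(directory / "diseases.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            vec = tuple(
                (int(p.split(":")[0]), int(p.split(":")[1]))
                for p in row["description_vector"].split(";")
                if p
            )
            diseases.append(
                DiseaseRecord(
                    disease_id=row["disease_id"],
                    phenotype_terms=frozenset(hpo_ann.get(row["disease_id"], ())),
                    description_vector=vec,
                )
            )

    nodes, edges = [], set()
    for line in (directory / "ppi.tsv").read_text().splitlines():
        a, b = line.split("\t")
        if a == "#node":
            nodes.append(b)
        else:
            edges.add((a, b))
    ppi = ProteinNetwork(nodes=tuple(nodes), edges=frozenset(edges))

    return KnowledgeBase(
        drugs=drugs,
        diseases=diseases,
        proteins=proteins,
        ppi=ppi,
        go_dag=go_dag,
        hpo_dag=hpo_dag,
        vocab_size=manifest["vocab_size"],
        gold={tuple(p) for p in manifest["gold"]},
        gen_seed=manifest["gen_seed"],
        gen_config=config,
        drug_clusters={k: int(v) for k, v in manifest["drug_clusters"].items()},
        disease_clusters={k: int(v) for k, v in manifest["disease_clusters"].items()},
        protein_clusters={k: int(v) for k, v in manifest["protein_clusters"].items()},
    )


# --------------------------------------------------------------------------
# FAIRified RDF emission
# --------------------------------------------------------------------------

BIO2RDF = Namespace("http://bio2rdf.org/bio2rdf_vocabulary:")
SIO = Namespace("http://semanticscience.org/resource/")
BASE = Namespace("https://w3id.org/fair/plex/data/")

SIO_DISEASE = SIO["SIO_010299"]
SIO_HAS_PHENOTYPE = SIO["SIO_001279"]


def emit_input_rdf(kb: KnowledgeBase) -> Graph:
    """FAIRified RDF view of the knowledge base inputs.

    Each PPI edge becomes an interaction node carrying ``interactor_a``
    and ``interactor_b`` properties (Bio2RDF style); each disease is a
    SIO disease linked to its phenotype terms through the SIO
    has-phenotype relation; the graph carries dataset-level DCAT/Dublin
    Core metadata (title, license, created).
    """
    g = Graph()
    g.bind("bio2rdf", BIO2RDF)
    g.bind("sio", SIO)
    g.bind("dct", DCTERMS)
    g.bind("dcat", DCAT)
    g.bind("data", BASE)

    dataset = BASE["Dataset_synthetic_kb"]
    g.add((dataset, RDF.type, DCAT.Dataset))
    g.add((dataset, DCTERMS.title, Literal("Synthetic drug-repurposing knowledge base")))
    g.add((dataset, DCTERMS.license, URIRef("https://creativecommons.org/licenses/by/4.0/")))
    g.add((dataset, DCTERMS.created, Literal(f"seed-{kb.gen_seed}")))

    for i, (a, b) in enumerate(sorted(kb.ppi.edges)):
        node = BASE[f"Interaction_{a}_{b}"]
        g.add((node, RDF.type, SIO["SIO_000897"]))  # association
        g.add((node, BIO2RDF.interactor_a, BASE[a]))
        g.add((node, BIO2RDF.interactor_b, BASE[b]))
        g.add((node, DCTERMS.isPartOf, dataset))

    for s in kb.diseases:
        node = BASE[s.disease_id]
        g.add((node, RDF.type, SIO_DISEASE))
        g.add((node, RDFS.label, Literal(s.disease_id)))
        for t in sorted(s.phenotype_terms):
            g.add((node, SIO_HAS_PHENOTYPE, BASE[t.replace(":", "_")]))
    return g
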
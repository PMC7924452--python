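"""The seven similarity measures behind the drug--disease classifier.

Five drug--drug measures: Tanimoto/Jaccard on chemical fingerprint
bit-sets (``chemical``) and on side-effect term sets (``side_effect``);
normalized Smith--Waterman alignment of target protein sequences
(``target_seq``); Resnik-style best-match-average semantic similarity of
target GO annotations (``go``); and exponential shortest-path closeness
of targets in the protein--protein interaction network (``ppi``).

Two disease--disease measures: cosine similarity of medical-description
term vectors (``mesh``) and the same semantic-similarity engine on
phenotype term sets (``hpo``).

Composite (drug-level) measures aggregate over target protein pairs by
maximum, keeping the strongest evidence and the [0, 1] range.  An entity
missing a modality scores 0 against everything in that measure, with its
diagonal left at 1, so the matrices stay total.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

from .kb_synth import KnowledgeBase, OntologyDAG, ProteinNetwork

__all__ = [
    "DRUG_MEASURES",
    "DISEASE_MEASURES",
    "AlignmentScoring",
    "SimilarityMatrix",
    "jaccard_similarity",
    "normalized_local_alignment",
    "information_content",
    "semantic_set_similarity",
    "ppi_closeness",
    "description_cosine",
    "build_similarity_matrices",
]

logger = logging.getLogger(__name__)

DRUG_MEASURES = ("chemical", "side_effect", "target_seq", "go", "ppi")
DISEASE_MEASURES = ("mesh", "hpo")


@dataclass(frozen=True)
class AlignmentScoring:
    """Local-alignment scoring scheme (penalties are positive magnitudes)."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self):
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")


@dataclass
class SimilarityMatrix:
    """Symmetric entity x entity similarity matrix with values in [0, 1]."""

    measure_id: str
    ids: tuple
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match the id list")
        self._index = {e: i for i, e in enumerate(self.ids)}

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def indices(self, entities) -> np.ndarray:
        try:
            return np.array([self._index[e] for e in entities], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown entity id {exc.args[0]!r} in {self.measure_id}") from None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    @classmethod
    def from_csv(cls, path, measure_id: str) -> "SimilarityMatrix":
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        return cls(measure_id=measure_id, ids=tuple(df.index), values=df.to_numpy())


# --------------------------------------------------------------------------
# elementary measures
# --------------------------------------------------------------------------

def jaccard_similarity(a, b) -> float:
    """|a ∩ b| / |a ∪ b|; two empty sets score 0."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def _aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(scoring.matrix)
    aligner.open_gap_score = -scoring.gap_open
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


def normalized_local_alignment(
    s1: str, s2: str, scoring: AlignmentScoring | None = None
) -> float:
    """Smith--Waterman score normalized by the self-alignment geometric mean.

    SW(s1,s2) / sqrt(SW(s1,s1) * SW(s2,s2)), clipped to [0, 1].
    """
    if not s1 or not s2:
        raise ValueError("sequences must be nonempty")
    scoring = scoring or AlignmentScoring()
    aligner = _aligner(scoring)
    cross = aligner.score(s1, s2)
    if cross <= 0:
        return 0.0
    denom = np.sqrt(aligner.score(s1, s1) * aligner.score(s2, s2))
    return float(np.clip(cross / denom, 0.0, 1.0))


def information_content(dag: OntologyDAG, annotations: dict) -> dict:
    """Corpus information content per term, in natural-log units.

    Annotation counts propagate to all ancestors; IC(t) =
    -ln(count(t)/count(root)).  Terms never reached by an annotation
    receive a pseudo-count of 1, so their IC is finite.
    """
    terms = set(dag.terms)
    counts = {t: 0 for t in dag.terms}
    n_entities = 0
    for entity, term_set in annotations.items():
        bad = set(term_set) - terms
        if bad:
            raise ValueError(f"{entity}: annotation terms outside the DAG: {sorted(bad)}")
        reached = set()
        for t in term_set:
            reached |= dag.ancestors(t)
        for t in reached:
            counts[t] += 1
        if term_set:
            n_entities += 1
    root_count = counts[dag.root]
    if root_count == 0:
        root_count = 1
    ic = {}
    for t in dag.terms:
        c = counts[t] if counts[t] > 0 else 1
        ic[t] = max(0.0, -np.log(c / root_count))
    return ic


def _mica_ic(dag: OntologyDAG, ic: dict, t1: str, t2: str) -> float:
    common = dag.ancestors(t1) & dag.ancestors(t2)
    return max(ic[t] for t in common)  # root is always common, IC 0


def semantic_set_similarity(tA, tB, dag: OntologyDAG, ic: dict) -> float:
    """Best-match-average Resnik similarity between two term sets.

    Term-pair similarity is IC of the most-informative common ancestor
    normalized by the corpus maximum IC; the set score averages each
    term's best match over both directions.  An empty set scores 0.
    """
    tA, tB = sorted(set(tA)), sorted(set(tB))
    if not tA or not tB:
        warnings.warn("semantic similarity of an empty term set is 0")
        return 0.0
    max_ic = max(ic.values())
    if max_ic <= 0:
        return 0.0
    M = np.array([[_mica_ic(dag, ic, a, b) for b in tB] for a in tA]) / max_ic
    bma = 0.5 * (M.max(axis=1).mean() + M.max(axis=0).mean())
    return float(np.clip(bma, 0.0, 1.0))


def ppi_closeness(net: ProteinNetwork, pA, pB, decay: float = 1.0) -> float:
    """Interaction-network closeness of two target sets.

    Protein-pair similarity is exp(-b * d) with d the unweighted
    shortest-path length (d=0 for a shared protein, disconnected -> 0);
    the set score is the maximum over target pairs.
    """
    if decay <= 0:
        raise ValueError("decay must be positive")
    pA, pB = sorted(set(pA)), sorted(set(pB))
    if not pA or not pB:
        warnings.warn("PPI closeness of an empty target set is 0")
        return 0.0
    g = net.to_networkx()
    best = 0.0
    for a in pA:
        if a not in g:
            continue
        dists = nx.single_source_shortest_path_length(g, a)
        for b in pB:
            d = 0 if a == b else dists.get(b)
            if d is None:
                continue
            best = max(best, float(np.exp(-decay * d)))
    return best


def description_cosine(vA, vB) -> float:
    """Cosine of two nonnegative sparse term-count vectors; zero -> 0."""
    a, b = dict(vA), dict(vB)
    dot = sum(c * b[i] for i, c in a.items() if i in b)
    na = np.sqrt(sum(c * c for c in a.values()))
    nb = np.sqrt(sum(c * c for c in b.values()))
    if na == 0 or nb == 0:
        return 0.0
    return float(np.clip(dot / (na * nb), 0.0, 1.0))


# --------------------------------------------------------------------------
# matrix construction
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SimilarityParams:
    scoring: AlignmentScoring = AlignmentScoring()
    ppi_decay: float = 1.0


def _all_pairs_mica_matrix(dag: OntologyDAG, ic: dict) -> tuple:
    """Dense term x term MICA-IC matrix, normalized by the corpus max IC."""
    terms = list(dag.terms)
    idx = {t: i for i, t in enumerate(terms)}
    T = len(terms)
    anc = np.zeros((T, T), dtype=bool)
    for t in terms:
        for a in dag.ancestors(t):
            anc[idx[t], idx[a]] = True
    ic_vec = np.array([ic[t] for t in terms])
    max_ic = ic_vec.max()
    out = np.zeros((T, T))
    if max_ic > 0:
        masked = np.where(anc, ic_vec[None, :], -np.inf)
        for i in range(T):
            common = np.where(anc[i][None, :], masked, -np.inf)
            out[i] = common.max(axis=1)
        out = np.clip(out / max_ic, 0.0, 1.0)
    return idx, out


def _bma(M: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> float:
    sub = M[np.ix_(rows, cols)]
    return float(0.5 * (sub.max(axis=1).mean() + sub.max(axis=0).mean()))


def _symmetric(measure_id: str, ids, fill) -> SimilarityMatrix:
    n = len(ids)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = fill(i, j)
    return SimilarityMatrix(measure_id=measure_id, ids=tuple(ids), values=np.clip(values, 0.0, 1.0))


def build_similarity_matrices(
    kb: KnowledgeBase, params: SimilarityParams | None = None
) -> dict:
    """Compute the five drug and two disease similarity matrices.

    Returns a dict keyed by measure id.  Protein-level quantities
    (sequence alignment, GO semantic similarity, network closeness) are
    precomputed once per protein pair and aggregated per drug pair by
    maximum over target pairs.
    """
    if not kb.drugs or not kb.diseases:
        raise ValueError("knowledge base has no drugs or no diseases")
    params = params or SimilarityParams()

    drug_ids = [d.drug_id for d in kb.drugs]
    drugs = {d.drug_id: d for d in kb.drugs}
    disease_ids = [s.disease_id for s in kb.diseases]
    diseases = {s.disease_id: s for s in kb.diseases}
    proteins = {p.protein_id: p for p in kb.proteins}
    protein_ids = sorted(proteins)
    pidx = {p: i for i, p in enumerate(protein_ids)}
    P = len(protein_ids)

    # protein-level sequence similarity
    aligner = _aligner(params.scoring)
    self_scores = np.array([aligner.score(proteins[p].sequence, proteins[p].sequence) for p in protein_ids])
    seq_sim = np.eye(P)
    for i in range(P):
        for j in range(i + 1, P):
            cross = aligner.score(proteins[protein_ids[i]].sequence, proteins[protein_ids[j]].sequence)
            v = 0.0 if cross <= 0 else cross / np.sqrt(self_scores[i] * self_scores[j])
            seq_sim[i, j] = seq_sim[j, i] = np.clip(v, 0.0, 1.0)

    # protein-level GO semantic similarity
    go_ic = information_content(
        kb.go_dag, {p.protein_id: set(p.go_terms) for p in kb.proteins}
    )
    go_idx, go_mica = _all_pairs_mica_matrix(kb.go_dag, go_ic)
    go_rows = {
        p: np.array([go_idx[t] for t in sorted(proteins[p].go_terms)], dtype=int)
        for p in protein_ids
    }
    go_sim = np.eye(P)
    for i in range(P):
        ri = go_rows[protein_ids[i]]
        for j in range(i + 1, P):
            rj = go_rows[protein_ids[j]]
            if ri.size and rj.size:
                go_sim[i, j] = go_sim[j, i] = np.clip(_bma(go_mica, ri, rj), 0.0, 1.0)

    # protein-level network closeness
    g = kb.ppi.to_networkx()
    ppi_sim = np.zeros((P, P))
    np.fill_diagonal(ppi_sim, 1.0)
    for i, a in enumerate(protein_ids):
        if a not in g:
            continue
        dists = nx.single_source_shortest_path_length(g, a)
        for b, d in dists.items():
            if b in pidx:
                ppi_sim[i, pidx[b]] = np.exp(-params.ppi_decay * d)

    def max_over_targets(mat):
        def fill(i, j):
            tA = [pidx[p] for p in drugs[drug_ids[i]].targets if p in pidx]
            tB = [pidx[p] for p in drugs[drug_ids[j]].targets if p in pidx]
            if not tA or not tB:
                logger.warning(
                    "drug pair (%s, %s): missing targets; similarity 0",
                    drug_ids[i], drug_ids[j],
                )
                return 0.0
            return float(mat[np.ix_(tA, tB)].max())

        return fill

    matrices = {
        "chemical": _symmetric(
            "chemical",
            drug_ids,
            lambda i, j: jaccard_similarity(
                drugs[drug_ids[i]].fingerprint, drugs[drug_ids[j]].fingerprint
            ),
        ),
        "side_effect": _symmetric(
            "side_effect",
            drug_ids,
            lambda i, j: jaccard_similarity(
                drugs[drug_ids[i]].side_effects, drugs[drug_ids[j]].side_effects
            ),
        ),
        "target_seq": _symmetric("target_seq", drug_ids, max_over_targets(seq_sim)),
        "go": _symmetric("go", drug_ids, max_over_targets(go_sim)),
        "ppi": _symmetric("ppi", drug_ids, max_over_targets(ppi_sim)),
    }

    # disease side
    hpo_ic = information_content(
        kb.hpo_dag, {s.disease_id: set(s.phenotype_terms) for s in kb.diseases}
    )
    hpo_idx, hpo_mica = _all_pairs_mica_matrix(kb.hpo_dag, hpo_ic)
    hpo_rows = {
        s: np.array([hpo_idx[t] for t in sorted(diseases[s].phenotype_terms)], dtype=int)
        for s in disease_ids
    }

    def hpo_fill(i, j):
        ri, rj = hpo_rows[disease_ids[i]], hpo_rows[disease_ids[j]]
        if not (ri.size and rj.size):
            return 0.0
        return _bma(hpo_mica, ri, rj)

    matrices["mesh"] = _symmetric(
        "mesh",
        disease_ids,
        lambda i, j: description_cosine(
            diseases[disease_ids[i]].description_vector,
            diseases[disease_ids[j]].description_vector,
        ),
    )
    matrices["hpo"] = _symmetric("hpo", disease_ids, hpo_fill)
    return matrices
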
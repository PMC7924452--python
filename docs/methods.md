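# Methods

This note records the model, the choices that were genuinely open, and
what the synthetic experiments do and do not establish.

## Synthetic knowledge bases

The generator (`kb_synth`) emulates the statistical structure that
similarity-fusion repurposing assumes: *similar drugs treat similar
diseases*. Drugs, diseases and proteins are assigned round-robin to
`n_clusters` latent clusters. Each cluster owns prototypes per
modality; members are noisy copies:

- **Fingerprints** — prototype bit-sets over F = 166 bits (MACCS-like
  length; small, fast, Tanimoto-meaningful), each bit on with
  probability 0.15; members flip every bit independently with
  probability `modality_noise`.
- **Side effects** — ~10 prototype terms from a 120-term vocabulary;
  each member term is swapped for a random one with probability
  `modality_noise`.
- **Targets** — 3 prototype proteins per cluster, same swap rule.
- **Protein sequences** — a per-cluster ancestor of length 120 over the
  20 standard residues, mutated per member position at rate
  `modality_noise`, so alignment similarity tracks cluster identity.
- **GO / phenotype annotations** — prototype term sets (depth ≥ 2)
  drawn from generated ontologies: random rooted trees (200 GO-like,
  150 HPO-like terms) with a guaranteed depth-≥4 backbone plus ~10%
  extra is-a edges pointing to lower-indexed terms, which makes common
  ancestors nontrivial while guaranteeing acyclicity by construction.
- **Description vectors** — ~20 prototype term counts over a 300-term
  vocabulary, term indices resampled at rate `modality_noise`.
- **Interaction network** — edge probability 0.3 within a cluster,
  0.01 between, so network closeness also tracks clusters.

Gold indications: each drug receives max(1, Poisson(2)) associations;
with probability `signal_strength` (ρ) the disease is drawn from the
drug's own cluster, otherwise uniformly. ρ = 0.9 and
`modality_noise` = 0.05 are the default study conditions; at ρ = 1,
noise = 0 every within-cluster similarity strictly dominates every
between-cluster one, which the property tests assert exhaustively.

Generation is a pure function of the config (a single NumPy
`default_rng` seed; all set iterations are sorted), so identical
configs give byte-identical on-disk bundles (JSON manifest + CSV/TSV +
FASTA — inspectable plain text).

What the generator does **not** emulate: heavy-tailed degree
distributions, missing modalities (records are generated complete;
readers of real tables may produce incomplete records, which the
similarity layer tolerates by scoring 0 off-diagonal with a warning),
correlated noise across modalities, and the literature/curation biases
of real gold standards. A high AUC on planted data therefore shows the
pipeline recovers the signal it assumes, not that the assumptions hold
in any real corpus.

## Similarity measures

The functional forms of the seven measures are this package's own
declared choices of field-standard formulations (the lineage
publications do not print formulas):

- Tanimoto/Jaccard for fingerprints and side effects; both-empty
  pairs score 0.
- Normalised Smith–Waterman for target sequences: BLOSUM62, gap open
  10, gap extend 0.5 (conventional defaults), score divided by the
  geometric mean of the self-alignment scores and clipped to [0, 1].
  Alignment scores come from Biopython's `PairwiseAligner`; the tests
  check them against an independent Gotoh dynamic program.
- Resnik-style semantic similarity: IC(t) = −ln(count(t)/count(root))
  in natural-log units with annotation counts propagated to all
  ancestors and pseudo-count 1 for unannotated terms; term-pair score
  is the most-informative-common-ancestor IC normalised by the corpus
  maximum; set score is the best-match average over both directions.
- Network closeness: exp(−b·d) on unweighted shortest paths, b = 1 by
  default, 0 across components, 1 for a shared target.
- Cosine for description vectors.

Drug-level aggregation over multiple targets is the **maximum** over
target pairs: it preserves the strongest evidence and the [0, 1] range,
and is directly checkable against enumeration oracles. All
protein-level quantities are computed once per protein pair and looked
up per drug pair.

## Fusion and evaluation

Features are weighted geometric means S_d^w · S_s^(1−w) aggregated
(max by default, mean available) over the known associations, with
w = 0.5 — the weights are not documented in the lineage, so w is
exposed as config rather than fixed. During cross-validation the known
set is the training-fold positives only; a training positive never
uses itself as evidence (`exclude_self`). This is the leakage guard
the tests instrument.

Negatives are sampled uniformly without replacement outside the gold
standard, 1:1 with positives by default, and disjoint between the
train and test sides of a fold. In the drug-wise regime test negatives
are drawn only among held-out-drug pairs and train negatives among
training-drug pairs, mirroring the "from the respective sets" reading
of the pair-wise construction; how the original evaluation drew
negatives in the drug-hidden scheme is not documented, so this is an
interpretation, flagged here.

The classifier is scikit-learn's L2 logistic regression (C = 1, lbfgs,
deterministic). Features already share the [0, 1] scale, so no
standardisation is applied by default. Classification threshold 0.5
for the thresholded metrics; ROC AUC and AUPR are threshold-free.
Fold seeds derive from `numpy.random.SeedSequence([seed, repetition,
fold])`, making a whole report a pure function of its seed.

The permutation null shuffles train and test labels within each fold
after feature construction; it should and does return AUC ≈ 0.5,
confirming that the signal test measures ranking skill rather than an
artifact of the pipeline.

**Study sizes.** The planted-signal study runs 120 drugs, 80 diseases,
100 proteins, 10 clusters, ρ = 0.9, noise = 0.05, over five generator
seeds with 10 repetitions of 10-fold CV — large enough for stable AUC
estimates (±0.02 across seeds) while a full run of study plus null
completes in well under two minutes on one CPU.

## Provenance model

Steps are lightweight pointers (`p-plan:Step`) ordered by
`pwo:hasFirstStep` and `dul:precedes` and decoupled from their
instructions (`p-plan:Plan`) via `dul:isDescribedBy`; instructions can
in turn be described by higher-level plans, giving abstraction levels.
Design choices where the published listings left room:

- Namespace bindings use the canonical URIs for p-plan, prov, dul,
  pwo, dcat, mls, opmw and edam; `dc:` is bound to DCMI *Terms* (the
  prefix is ambiguous in the wild); `bpmn:` and the workflow-instance
  namespace have no published URI and are minted under a configurable
  base defaulting to `https://w3id.org/fair/plex`.
- Timestamps are ISO-8601 with millisecond precision; metric values
  are stored as plain string literals in `dc:description` (six decimal
  places), matching the printed artifact pattern.
- Agent roles are emitted both as reified `prov:Association` nodes
  (`prov:agent`/`prov:hadRole`/`prov:hadPlan`) and as simple
  `dc:creator` properties — the dual approach of the model.
- Forks and conditionals are out of scope; precedence must be a DAG
  and emission fails on cycles.

`build_paper_fixture()` reproduces the published worked-example
listings (the DrugBank download step, execution 1546302862 with its
six evaluation artifacts, and main-protocol versions 0.1/0.2) triple
for triple, plus the minimal step typing needed to query all three as
one graph. One printed artifact name lacks the `Execution_` infix
(`ModelEvaluation_Precision_1546302862`); the fixture keeps it
verbatim.

## Competency questions

Each of the 13 questions is a standalone SPARQL 1.1 file; transitive
ordering uses `dul:precedes*` property paths. Workflow/version IRIs
are injected by `string.Template` after validating the IRI against a
character whitelist, so the files remain usable against external
stores. Rows are sorted lexicographically, making answers
deterministic. CQ2.4 is never demonstrated in the lineage; it is
answered via the association pattern attached to plan-to-plan
abstraction links, an interpretation. Version diffs classify
instruction plans as removed (in old only, not revised), changed
(linked by `prov:wasRevisionOf`), or added (in new only, not
revising); the three sets are disjoint by construction and validated.

## Numerical and degenerate-input conventions

- All similarity values are clipped to [0, 1] after computation;
  matrices keep an exact unit diagonal for entities with data.
- Empty term/target sets score 0 with a warning; an empty fusion
  candidate set scores 0; a zero description vector scores 0.
- Cross-validation requires both classes; single-class inputs raise.
- A permuted fold that degenerates to one class is skipped (it cannot
  be scored); this does not occur at the study sizes.
- Readers reject malformed rows with the line number, drop self-loop
  interactions with a warning, and deduplicate associations (set
  semantics).

## Known limitations

- The drug-wise negative-sampling scheme is an interpretation (above).
- The ontology generator produces trees-plus-shortcuts, not the dense
  multi-parent structure of the real Gene Ontology; IC distributions
  are correspondingly narrower.
- Real-corpus performance figures are outside what synthetic data can
  establish; the package's claims are about correctness (oracle
  equivalence, leakage guards, determinism, emit-then-query
  consistency) and signal recovery under its own generative model.
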
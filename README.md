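# fairpredict

Similarity-fusion drug repurposing with FAIR workflow provenance and
competency-question validation.

## What this package is for

Computational drug repositioning asks which approved drugs might treat
which diseases. A classical and much-replicated recipe ranks candidate
drug–disease pairs by how similar they are to *known* indications: if
drug *d* resembles a drug *d′* that is known to treat a disease *s′*
resembling *s*, then (*d*, *s*) is a plausible new indication.
`fairpredict` implements that recipe end to end on synthetic knowledge
bases with a planted cluster signal, so the whole statistical pipeline
can be exercised, validated against brute-force oracles and null
distributions, and — the second half of the package — described,
traced and versioned as FAIR machine-readable workflow provenance in
RDF, validated by SPARQL competency questions.

It is aimed at two audiences: method developers who want a compact,
fully testable reference implementation of similarity-fusion
repurposing, and workflow/provenance researchers who want a working
emitter and query suite for the unified P-PLAN/PROV/BPMN workflow
model.

## The model

**Similarities.** Five drug–drug measures and two disease–disease
measures, each a symmetric matrix with values in [0, 1]:

| measure | definition |
|---|---|
| `chemical` | Tanimoto/Jaccard on fingerprint bit-sets, \|A∩B\|/\|A∪B\| |
| `side_effect` | Jaccard on side-effect term sets |
| `target_seq` | Smith–Waterman score normalised as SW(x,y)/√(SW(x,x)·SW(y,y)), max over target pairs |
| `go` | Resnik best-match-average: per term pair IC(MICA)/max IC, IC(t) = −ln(count(t)/count(root)), max over target pairs |
| `ppi` | exp(−b·dist) for the shortest interaction-network path between targets, max over target pairs |
| `mesh` | cosine of medical-description term-count vectors |
| `hpo` | the same Resnik engine on phenotype term sets |

**Fusion.** For a candidate pair (*d*, *s*) and measure combination
(*i*, *j*), the feature is the strongest evidence over the known
associations *K*:

> x_ij(d, s) = max over (d′, s′) ∈ K \ {(d, s)} of
> S_i(d, d′)^w · S_j(s, s′)^(1−w),  w = 0.5 by default,

a weighted geometric mean. 5 × 2 measures give 10 features per pair.

**Classification and evaluation.** An L2-regularised logistic
regression is trained on gold positives plus uniformly sampled 1:1
negatives and scored by ROC AUC, AUPR, accuracy, precision, recall and
F-score under two 10-fold cross-validation regimes: *drug-wise* (10% of
drugs hidden with all their indications — cold start) and *pair-wise*
(10% of individual associations hidden). Per fold, only training-fold
positives serve as fusion evidence, so test pairs never leak into their
own features.

**Provenance.** Every workflow version is a `dul:Workflow`/
`p-plan:Plan` with steps ordered by `pwo:hasFirstStep`/`dul:precedes`,
typed `bpmn:ManualTask` or `bpmn:ScriptTask` plus an EDAM operation,
and decoupled from their instructions via `dul:isDescribedBy`.
Executions are `p-plan:Activity` nodes whose evaluation metrics become
`mls:ModelEvaluation` artifacts; versions link with `dc:hasVersion` and
`prov:wasRevisionOf`. Thirteen competency questions (manual steps,
abstraction levels, versioning) ship as standalone SPARQL files under
`src/fairpredict/queries/`.

## Worked example

```sh
fairpredict generate --seed 7 --out wk/kb --config cfg.json
# wrote KB (60 drugs, 40 diseases, 118 gold pairs) to wk/kb
fairpredict similarities --kb wk/kb --out wk/sim
# wrote 7 matrices to wk/sim
fairpredict crossval --kb wk/kb --matrices wk/sim \
    --strategy drug-wise --k 10 --repetitions 3 --seed 7 --out wk/cv
# accuracy: 0.864 +/- 0.067
# aupr: 0.906 +/- 0.091
# f_score: 0.860 +/- 0.072
# precision: 0.890 +/- 0.089
# recall: 0.842 +/- 0.101
# roc_auc: 0.906 +/- 0.078
```

with `cfg.json` containing
`{"generator": {"n_drugs": 60, "n_diseases": 40, "n_proteins": 50, "n_clusters": 6}}`.
The knowledge base plants 6 latent drug/disease clusters whose members
share fingerprints, side effects, targets and annotations; 90% of gold
indications stay on-cluster. The ROC AUC of 0.906 says the classifier
ranks held-out drugs' true indications above sampled non-indications
over 90% of the time — the planted signal is recovered well above the
0.5 chance level that a permuted-label run returns. `fairpredict
run-all` additionally emits the prospective/retrospective provenance
graphs, and `fairpredict cq` answers a competency question over any
Turtle file.

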
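"""Cross-validated evaluation of the similarity-fusion classifier.

Two 10-fold cross-validation regimes are supported:

``drug_wise``
    10% of drugs are hidden per fold, together with all their known
    indications.  Test positives are the hidden drugs' associations, so
    no drug appears on both sides of a fold (the harder, cold-start
    setting).

``pair_wise``
    10% of the individual gold associations are hidden per fold.

Negatives are drug--disease pairs sampled uniformly outside the gold
standard (1:1 with positives by default), disjoint between the train
and test sides of each fold.  Per fold, the known-association set used
as fusion evidence is restricted to the training positives, so test
pairs never leak into their own features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)

from .fusion import FEATURE_COLUMNS, FusionConfig, build_feature_table

__all__ = [
    "METRICS",
    "CVFold",
    "LogisticModel",
    "EvaluationReport",
    "split_drug_wise",
    "split_pair_wise",
    "sample_negatives",
    "train_logistic",
    "evaluate_predictions",
    "run_cross_validation",
]

METRICS = ("roc_auc", "aupr", "accuracy", "precision", "recall", "f_score")


@dataclass
class CVFold:
    strategy: str
    train_pos: set
    test_pos: set
    train_neg: set = field(default_factory=set)
    test_neg: set = field(default_factory=set)

    def check(self, gold: set) -> None:
        """Assert the structural fold invariants."""
        assert self.train_pos | self.test_pos <= gold
        assert not self.train_pos & self.test_pos
        if self.strategy == "drug_wise":
            train_drugs = {d for d, _ in self.train_pos}
            test_drugs = {d for d, _ in self.test_pos}
            assert not train_drugs & test_drugs, "drug leakage across the fold"
        negs = self.train_neg | self.test_neg
        assert not negs & gold, "negatives overlap the gold standard"
        assert not self.train_neg & self.test_neg


def split_drug_wise(gold: set, k: int, seed: int) -> list:
    """Partition the gold-standard drugs into k folds; a fold's test
    positives are all associations of its held-out drugs."""
    if k < 2:
        raise ValueError("k must be at least 2")
    if not gold:
        raise ValueError("empty gold standard")
    drugs = sorted({d for d, _ in gold})
    if len(drugs) < k:
        raise ValueError(f"only {len(drugs)} drugs for {k} folds")
    rng = np.random.default_rng(seed)
    order = [drugs[i] for i in rng.permutation(len(drugs))]
    chunks = [set(order[i::k]) for i in range(k)]
    folds = []
    for chunk in chunks:
        test = {(d, s) for d, s in gold if d in chunk}
        folds.append(CVFold(strategy="drug_wise", train_pos=gold - test, test_pos=test))
    return folds


def split_pair_wise(gold: set, k: int, seed: int) -> list:
    """Partition the gold associations themselves into k folds."""
    if k < 2:
        raise ValueError("k must be at least 2")
    if not gold:
        raise ValueError("empty gold standard")
    pairs = sorted(gold)
    if len(pairs) < k:
        raise ValueError(f"only {len(pairs)} associations for {k} folds")
    rng = np.random.default_rng(seed)
    order = [pairs[i] for i in rng.permutation(len(pairs))]
    folds = []
    for i in range(k):
        test = set(order[i::k])
        folds.append(CVFold(strategy="pair_wise", train_pos=gold - test, test_pos=test))
    return folds


def sample_negatives(drugs, diseases, forbidden: set, n: int, seed) -> set:
    """Uniformly sample n drug--disease pairs outside ``forbidden``,
    without replacement."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lattice = [
        (d, s) for d in sorted(set(drugs)) for s in sorted(set(diseases))
        if (d, s) not in forbidden
    ]
    if n > len(lattice):
        raise ValueError(f"requested {n} negatives but only {len(lattice)} pairs available")
    idx = rng.choice(len(lattice), size=n, replace=False)
    return {lattice[i] for i in idx}


@dataclass
class LogisticModel:
    """L2-regularized logistic regression over the 10 fused features."""

    coefficients: dict
    intercept: float
    regularization: str
    _estimator: LogisticRegression = field(repr=False, default=None)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return self._estimator.predict_proba(X[list(FEATURE_COLUMNS)].to_numpy())[:, 1]


def train_logistic(X: pd.DataFrame, reg: float = 1.0) -> LogisticModel:
    """Fit the classifier on a labelled feature table (deterministic)."""
    y = X["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    est = LogisticRegression(C=reg, solver="lbfgs", max_iter=1000)  # L2 by default
    est.fit(X[list(FEATURE_COLUMNS)].to_numpy(), y)
    coeffs = dict(zip(FEATURE_COLUMNS, est.coef_[0]))
    return LogisticModel(
        coefficients=coeffs,
        intercept=float(est.intercept_[0]),
        regularization=f"l2(C={reg})",
        _estimator=est,
    )


def evaluate_predictions(scores, labels, threshold: float = 0.5) -> dict:
    """Threshold-free ranking metrics plus thresholded classification
    metrics for one scored test set."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain both classes")
    preds = (scores >= threshold).astype(int)
    return {
        "roc_auc": float(roc_auc_score(labels, scores)),
        "aupr": float(average_precision_score(labels, scores)),
        "accuracy": float(accuracy_score(labels, preds)),
        "precision": float(precision_score(labels, preds, zero_division=0)),
        "recall": float(recall_score(labels, preds, zero_division=0)),
        "f_score": float(f1_score(labels, preds, zero_division=0)),
    }


@dataclass
class EvaluationReport:
    strategy: str
    seed: int
    frame: pd.DataFrame  # one row per (repetition, fold) with the 6 metrics

    @property
    def summary(self) -> dict:
        return {
            m: {"mean": float(self.frame[m].mean()), "std": float(self.frame[m].std(ddof=0))}
            for m in METRICS
        }

    def write(self, csv_path, json_path=None) -> None:
        self.frame.to_csv(csv_path, index=False)
        if json_path is not None:
            import json

            payload = {"strategy": self.strategy, "seed": self.seed, "summary": self.summary}
            with open(json_path, "w") as fh:
                json.dump(payload, fh, indent=1, sort_keys=True)


def run_cross_validation(
    kb,
    matrices: dict,
    strategy: str = "drug_wise",
    k: int = 10,
    repetitions: int = 10,
    neg_ratio: float = 1.0,
    seed: int = 0,
    fusion_cfg: FusionConfig | None = None,
    reg: float = 1.0,
    permute_labels: bool = False,
) -> EvaluationReport:
    """Repeated k-fold cross-validation of the full fuse-train-score loop.

    ``permute_labels`` shuffles the train and test labels within each
    fold after feature construction — the permutation null against
    which planted signal is judged.
    """
    if strategy not in ("drug_wise", "pair_wise"):
        raise ValueError(f"unknown strategy {strategy!r}")
    fusion_cfg = fusion_cfg or FusionConfig()
    split = split_drug_wise if strategy == "drug_wise" else split_pair_wise
    drug_ids = [d.drug_id for d in kb.drugs]
    disease_ids = [s.disease_id for s in kb.diseases]
    gold = set(kb.gold)

    rows = []
    for rep in range(repetitions):
        rep_seed = np.random.SeedSequence([seed, rep])
        fold_seed = int(rep_seed.generate_state(1)[0] % (2**31))
        folds = split(gold, k, fold_seed)
        for fi, fold in enumerate(folds):
            rng = np.random.default_rng(np.random.SeedSequence([seed, rep, fi]))
            if strategy == "drug_wise":
                test_drugs = {d for d, _ in fold.test_pos}
                train_drugs = sorted(set(drug_ids) - test_drugs)
                fold.train_neg = sample_negatives(
                    train_drugs, disease_ids, gold, round(neg_ratio * len(fold.train_pos)), rng
                )
                fold.test_neg = sample_negatives(
                    sorted(test_drugs), disease_ids, gold | fold.train_neg,
                    round(neg_ratio * len(fold.test_pos)), rng,
                )
            else:
                fold.train_neg = sample_negatives(
                    drug_ids, disease_ids, gold, round(neg_ratio * len(fold.train_pos)), rng
                )
                fold.test_neg = sample_negatives(
                    drug_ids, disease_ids, gold | fold.train_neg,
                    round(neg_ratio * len(fold.test_pos)), rng,
                )
            fold.check(gold)

            known = fold.train_pos
            train_pairs = [(d, s, 1) for d, s in sorted(fold.train_pos)] + [
                (d, s, 0) for d, s in sorted(fold.train_neg)
            ]
            test_pairs = [(d, s, 1) for d, s in sorted(fold.test_pos)] + [
                (d, s, 0) for d, s in sorted(fold.test_neg)
            ]
            X_train = build_feature_table(kb, matrices, train_pairs, known, fusion_cfg)
            X_test = build_feature_table(kb, matrices, test_pairs, known, fusion_cfg)
            if permute_labels:
                X_train["label"] = rng.permutation(X_train["label"].to_numpy())
                X_test["label"] = rng.permutation(X_test["label"].to_numpy())
                if X_train["label"].nunique() < 2 or X_test["label"].nunique() < 2:
                    continue  # degenerate permutation; cannot score

            model = train_logistic(X_train, reg=reg)
            scores = model.predict_proba(X_test)
            metrics = evaluate_predictions(scores, X_test["label"].to_numpy())
            rows.append({"repetition": rep, "fold": fi, **metrics})

    frame = pd.DataFrame(rows)
    return EvaluationReport(strategy=strategy, seed=seed, frame=frame)
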
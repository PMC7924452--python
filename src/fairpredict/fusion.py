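"""Similarity fusion: 10 features per drug--disease candidate pair.

For a candidate pair (d, s) and one drug measure S_i and one disease
measure S_j, the feature is an aggregate over the known associations
(d', s') of the weighted geometric mean  S_i(d, d')^w * S_j(s, s')^(1-w):
the strongest (or mean) evidence that a drug similar to d treats a
disease similar to s.  Five drug measures x two disease measures give
the 10-column feature table consumed by the logistic classifier.

With ``exclude_self`` the pair's own gold association never serves as
its evidence, which is the leakage guard used for training positives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .similarity import DRUG_MEASURES, DISEASE_MEASURES, SimilarityMatrix

__all__ = ["FusionConfig", "FEATURE_COLUMNS", "fuse_pair", "build_feature_table"]

#: column order: all disease measures nested under each drug measure
FEATURE_COLUMNS = tuple(f"{i}__{j}" for i in DRUG_MEASURES for j in DISEASE_MEASURES)


@dataclass(frozen=True)
class FusionConfig:
    weight: float = 0.5  # drug-side exponent w; disease side gets 1 - w
    aggregation: str = "max"
    exclude_self: bool = True

    def __post_init__(self):
        if not 0.0 < self.weight < 1.0:
            raise ValueError("weight must lie strictly between 0 and 1")
        if self.aggregation not in ("max", "mean"):
            raise ValueError("aggregation must be 'max' or 'mean'")


def fuse_pair(
    d: str,
    s: str,
    drug_sim: SimilarityMatrix,
    disease_sim: SimilarityMatrix,
    known,
    cfg: FusionConfig | None = None,
) -> float:
    """Fused similarity evidence for one pair under one measure combination.

    Aggregates ``S_i(d, d')^w * S_j(s, s')^(1-w)`` over the known
    associations (minus (d, s) itself under ``exclude_self``); an empty
    candidate set yields 0.
    """
    cfg = cfg or FusionConfig()
    candidates = sorted(set(known) - ({(d, s)} if cfg.exclude_self else set()))
    if not candidates:
        return 0.0
    w = cfg.weight
    sd = np.array([drug_sim.loc(d, dp) for dp, _ in candidates])
    ss = np.array([disease_sim.loc(s, sp) for _, sp in candidates])
    vals = sd**w * ss ** (1.0 - w)
    return float(vals.max() if cfg.aggregation == "max" else vals.mean())


def build_feature_table(
    kb,
    matrices: dict,
    pairs,
    known,
    cfg: FusionConfig | None = None,
) -> pd.DataFrame:
    """Fuse the 10 features for a list of (drug, disease[, label]) pairs.

    ``pairs`` is a sequence of (drug_id, disease_id) or
    (drug_id, disease_id, label) tuples; duplicates are rejected.
    Returns a DataFrame indexed by (drug_id, disease_id) with the 10
    feature columns of :data:`FEATURE_COLUMNS` and, when labels were
    given, a ``label`` column.  Fusion is vectorized over the known set.
    """
    cfg = cfg or FusionConfig()
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no pairs requested")
    has_labels = len(pairs[0]) == 3
    keys = [(p[0], p[1]) for p in pairs]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (drug, disease) pair requested")

    known = sorted(set(known))
    pair_drugs = [k[0] for k in keys]
    pair_diseases = [k[1] for k in keys]
    w = cfg.weight

    data = {}
    if known:
        known_drugs = [d for d, _ in known]
        known_diseases = [s for _, s in known]
        known_index = {p: i for i, p in enumerate(known)}
        # rows that must not see themselves as evidence
        self_mask = np.full((len(keys), len(known)), False)
        if cfg.exclude_self:
            for r, key in enumerate(keys):
                c = known_index.get(key)
                if c is not None:
                    self_mask[r, c] = True

    for di in DRUG_MEASURES:
        for dj in DISEASE_MEASURES:
            col = f"{di}__{dj}"
            if not known:
                data[col] = np.zeros(len(keys))
                continue
            Sd = matrices[di].values[
                np.ix_(matrices[di].indices(pair_drugs), matrices[di].indices(known_drugs))
            ]
            Ss = matrices[dj].values[
                np.ix_(
                    matrices[dj].indices(pair_diseases),
                    matrices[dj].indices(known_diseases),
                )
            ]
            fused = Sd**w * Ss ** (1.0 - w)
            if cfg.aggregation == "max":
                fused = np.where(self_mask, -np.inf, fused)
                col_vals = fused.max(axis=1)
                col_vals[np.isneginf(col_vals)] = 0.0
            else:
                fused = np.where(self_mask, np.nan, fused)
                with np.errstate(invalid="ignore"):
                    col_vals = np.nanmean(fused, axis=1)
                col_vals = np.nan_to_num(col_vals)
            data[col] = np.clip(col_vals, 0.0, 1.0)

    df = pd.DataFrame(data, index=pd.MultiIndex.from_tuples(keys, names=["drug_id", "disease_id"]))
    df = df[list(FEATURE_COLUMNS)]
    if has_labels:
        df["label"] = [int(p[2]) for p in pairs]
    return df
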
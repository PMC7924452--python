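"""Independent brute-force oracles used to validate the package.

Everything here is written from the mathematical definitions alone
(explicit dynamic programming, exhaustive enumeration over ancestor
sets, candidate pairs and lattice pairs) and deliberately shares no
code with the package implementation.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_score(s1: str, s2: str, gap_open: float = 10.0, gap_extend: float = 0.5) -> float:
    """Smith-Waterman local-alignment score, affine gaps, Gotoh DP.

    A gap of length L costs gap_open + gap_extend * (L - 1).
    """
    n, m = len(s1), len(s2)
    NEG = -1e18
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in s2 (vertical)
    F = np.full((n + 1, m + 1), NEG)  # gap in s1 (horizontal)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] - gap_open, E[i - 1][j] - gap_extend)
            F[i][j] = max(H[i][j - 1] - gap_open, F[i][j - 1] - gap_extend)
            sub = _BLOSUM62[s1[i - 1], s2[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def normalized_sw(s1: str, s2: str) -> float:
    cross = sw_score(s1, s2)
    if cross <= 0:
        return 0.0
    denom = (sw_score(s1, s1) * sw_score(s2, s2)) ** 0.5
    return min(1.0, cross / denom)


def ancestors(edges: dict, term: str) -> set:
    """Inclusive ancestor set by naive repeated expansion.

    ``edges`` maps child -> iterable of parents.
    """
    out = {term}
    while True:
        grown = set(out)
        for t in out:
            grown |= set(edges.get(t, ()))
        if grown == out:
            return out
        out = grown


def ic_counts(edges: dict, root: str, terms, annotations: dict) -> dict:
    """Information content by direct entity counting."""
    counts = {t: 0 for t in terms}
    for _, term_set in sorted(annotations.items()):
        reached = set()
        for t in term_set:
            reached |= ancestors(edges, t)
        for t in reached:
            counts[t] += 1
    root_count = counts[root] or 1
    return {
        t: max(0.0, -np.log((counts[t] or 1) / root_count)) for t in terms
    }


def resnik_bma(tA, tB, edges: dict, ic: dict) -> float:
    """Best-match-average Resnik similarity by exhaustive enumeration."""
    max_ic = max(ic.values())
    if max_ic <= 0:
        return 0.0

    def pair(a, b):
        common = ancestors(edges, a) & ancestors(edges, b)
        return max(ic[t] for t in common) / max_ic

    tA, tB = sorted(set(tA)), sorted(set(tB))
    row = np.mean([max(pair(a, b) for b in tB) for a in tA])
    col = np.mean([max(pair(a, b) for a in tA) for b in tB])
    return float((row + col) / 2)


def bfs_distance(edges, a: str, b: str):
    """Unweighted shortest-path length on an undirected edge list."""
    if a == b:
        return 0
    adj: dict[str, set] = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    frontier, seen, d = {a}, {a}, 0
    while frontier:
        d += 1
        nxt = set()
        for u in frontier:
            for v in adj.get(u, ()):
                if v == b:
                    return d
                if v not in seen:
                    seen.add(v)
                    nxt.add(v)
        frontier = nxt
    return None


def ppi_max_closeness(edges, pA, pB, decay=1.0) -> float:
    best = 0.0
    for a in sorted(set(pA)):
        for b in sorted(set(pB)):
            d = bfs_distance(edges, a, b)
            if d is not None:
                best = max(best, float(np.exp(-decay * d)))
    return best


def fuse(d, s, drug_sim: dict, disease_sim: dict, known, w=0.5,
         exclude_self=True, aggregation="max") -> float:
    """Weighted-geometric-mean fusion by explicit candidate enumeration.

    ``drug_sim`` and ``disease_sim`` map unordered id pairs (and
    identical-id pairs) to similarity values.
    """
    vals = []
    for dp, sp in sorted(known):
        if exclude_self and (dp, sp) == (d, s):
            continue
        sd = drug_sim[frozenset((d, dp))] if d != dp else drug_sim.get(frozenset((d,)), 1.0)
        ss = disease_sim[frozenset((s, sp))] if s != sp else disease_sim.get(frozenset((s,)), 1.0)
        vals.append(sd**w * ss ** (1 - w))
    if not vals:
        return 0.0
    return max(vals) if aggregation == "max" else float(np.mean(vals))


def is_topological(order, edges) -> bool:
    pos = {n: i for i, n in enumerate(order)}
    return all(pos[a] < pos[b] for a, b in edges if a in pos and b in pos)
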
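"""Independent brute-force oracles used to verify the fast implementations.

Everything here is deliberately naive (direct summation, exhaustive scans,
exact rational arithmetic) and shares no code with the package paths it
checks.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def ac_test_oracle(x: int, y: int, n1: float, n2: float) -> float:
    """Two-sided tag-count p-value by direct summation of the conditional
    distribution P(k | x) = (N2/N1)^k (x+k)!/(x! k! (1+N2/N1)^(x+k+1)),
    with the upper tail truncated once the mass is machine-negligible."""
    q = n2 / n1

    def logpmf(k: int) -> float:
        return (
            k * math.log(q)
            + math.lgamma(x + k + 1)
            - math.lgamma(x + 1)
            - math.lgamma(k + 1)
            - (x + k + 1) * math.log1p(q)
        )

    lower = sum(math.exp(logpmf(k)) for k in range(0, y + 1))
    upper = 0.0
    k = y
    # sum the upper tail until terms are negligible and past the mode
    cutoff = y + 50 + 10 * int(math.sqrt((x + y + 4) * max(q, 1.0))) + int(x * q)
    while True:
        term = math.exp(logpmf(k))
        upper += term
        k += 1
        if k > cutoff and term < 1e-30:
            break
    return min(1.0, 2.0 * min(lower, upper))


def hamming(a: str, b: str) -> int:
    return sum(ca != cb for ca, cb in zip(a, b))


def map_tags_oracle(
    clean: dict[str, int], db_entries: dict[str, list[tuple[str, int]]]
) -> tuple[dict[str, int], int, int, int]:
    """All-pairs Hamming scan mapper: exact tier first, then distance 1;
    unique-gene tags mapped, multi-gene excluded, no-hit unmapped."""
    gene_counts: dict[str, int] = {}
    n_mapped = n_ambig = n_unmapped = 0
    for tag, count in clean.items():
        exact = {g for t, hits in db_entries.items() if t == tag for g, _ in hits}
        if exact:
            genes = exact
        else:
            genes = {
                g
                for t, hits in db_entries.items()
                if hamming(t, tag) == 1
                for g, _ in hits
            }
        if len(genes) == 1:
            g = genes.pop()
            gene_counts[g] = gene_counts.get(g, 0) + count
            n_mapped += count
        elif genes:
            n_ambig += count
        else:
            n_unmapped += count
    return gene_counts, n_mapped, n_ambig, n_unmapped


def bh_oracle(pvals: list[float]) -> list[float]:
    """Second, independent coding of Benjamini–Hochberg: for each p_i,
    q_i = min over p_(j) >= p_i of m * p_(j) / rank_j, clipped at 1."""
    m = len(pvals)
    ranked = sorted(pvals)
    out = []
    for p in pvals:
        candidates = [
            m * pj / (j + 1) for j, pj in enumerate(ranked) if pj >= p
        ]
        out.append(min(1.0, min(candidates)))
    return out


def hypergeom_upper_oracle(k: int, n_total: int, big_k: int, n_study: int) -> Fraction:
    """Exact rational upper-tail hypergeometric P(X >= k)."""
    total = math.comb(n_total, n_study)
    acc = Fraction(0)
    for i in range(k, min(big_k, n_study) + 1):
        acc += Fraction(
            math.comb(big_k, i) * math.comb(n_total - big_k, n_study - i), total
        )
    return acc


def dag_closure_oracle(
    gene2terms: dict[str, set[str]], edges: list[tuple[str, str]]
) -> dict[str, set[str]]:
    """Transitive-ancestor closure by repeated DFS over the edge list."""
    parents: dict[str, set[str]] = {}
    for child, parent in edges:
        parents.setdefault(child, set()).add(parent)

    def ancestors(term: str) -> set[str]:
        seen: set[str] = set()
        stack = [term]
        while stack:
            t = stack.pop()
            for p in parents.get(t, ()):  # DFS over child -> parent edges
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
        return seen

    return {
        g: set(ts) | set().union(*(ancestors(t) for t in ts)) if ts else set()
        for g, ts in gene2terms.items()
    }


def average_linkage_oracle(x: np.ndarray, k: int) -> list[set[int]]:
    """Naive O(n^3) average-linkage agglomeration under correlation distance.

    Average linkage over the original pairwise distances (UPGMA on points);
    ties broken by the smallest member indices for determinism.
    """
    n = x.shape[0]

    def corr_dist(i: int, j: int) -> float:
        a, b = x[i] - x[i].mean(), x[j] - x[j].mean()
        denom = np.linalg.norm(a) * np.linalg.norm(b)
        return 1.0 - float(a @ b) / denom

    d = {(i, j): corr_dist(i, j) for i in range(n) for j in range(i + 1, n)}
    clusters: list[set[int]] = [{i} for i in range(n)]
    while len(clusters) > k:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                dist = float(
                    np.mean(
                        [
                            d[(min(i, j), max(i, j))]
                            for i in clusters[a]
                            for j in clusters[b]
                        ]
                    )
                )
                key = (dist, min(clusters[a]), min(clusters[b]))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        clusters[a] = clusters[a] | clusters[b]
        del clusters[b]
    return clusters
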
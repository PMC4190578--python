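"""Term and pathway overrepresentation with DAG propagation and rich factors.

Terms (GO-style) may carry a child → parent DAG; annotations are closed
under the true-path rule before testing. Each term with at least one study
gene and at least two background genes is tested with the one-sided
(upper-tail) hypergeometric distribution:

    p = P(X >= k),  X ~ Hypergeom(N, K, n)

for k study hits among n study genes against K annotated background genes
of N total. Benjamini–Hochberg correction runs across all tested terms in
one run, and each pathway additionally reports the rich factor k/K.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd
from scipy import stats as sps

from .diffexpr import bh_fdr

__all__ = [
    "propagate_annotations",
    "term_enrichment",
    "pathway_enrichment",
    "annotation_to_term_map",
]

RESULT_COLUMNS = ["term_id", "k", "n", "K", "N", "p", "q", "rich_factor", "enriched"]


def propagate_annotations(
    gene2terms: Mapping[str, set[str]],
    dag_edges: Sequence[tuple[str, str]],
) -> dict[str, set[str]]:
    """Close each gene's term set under ancestor traversal (true-path rule).

    ``dag_edges`` are (child, parent) pairs; a cycle raises with one cycle
    member named. Idempotent: terms only ever grow, and a closed map is
    returned unchanged.
    """
    graph = nx.DiGraph(dag_edges)  # child -> parent
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise ValueError(f"term hierarchy contains a cycle through {cycle[0][0]!r}")
    ancestors = {
        term: nx.descendants(graph, term) if term in graph else set()
        for term in {t for g in gene2terms.values() for t in g}
    }
    closed: dict[str, set[str]] = {}
    for gene, terms in gene2terms.items():
        full = set(terms)
        for t in terms:
            full |= ancestors.get(t, set())
        closed[gene] = full
    return closed


def annotation_to_term_map(gene2terms: Mapping[str, set[str]]) -> dict[str, set[str]]:
    """Invert gene → terms into term → genes."""
    term2genes: dict[str, set[str]] = {}
    for gene, terms in gene2terms.items():
        for t in terms:
            term2genes.setdefault(t, set()).add(gene)
    return term2genes


def term_enrichment(
    study: set[str],
    background: set[str],
    gene2terms: Mapping[str, set[str]],
    *,
    q_cutoff: float = 0.05,
    min_background_genes: int = 2,
) -> pd.DataFrame:
    """Upper-tail hypergeometric overrepresentation of terms in a study set.

    Terms are tested when they annotate >= 1 study gene and
    >= ``min_background_genes`` background genes; results are BH-corrected
    across tested terms, flagged ``enriched`` at q <= ``q_cutoff`` and
    sorted by (q, p, term_id). The ``rich_factor`` column is k/K.
    """
    if not study <= background:
        raise ValueError("study set must be a subset of the background")
    n_total = len(background)
    n_study = len(study)
    term2genes = annotation_to_term_map(gene2terms)
    rows = []
    for term in sorted(term2genes):
        bg_hits = term2genes[term] & background
        big_k = len(bg_hits)
        k = len(term2genes[term] & study)
        if big_k == 0:
            warnings.warn(f"term {term} annotates no background gene; skipped",
                          stacklevel=2)
            continue
        if k < 1 or big_k < min_background_genes:
            continue
        p = float(sps.hypergeom.sf(k - 1, n_total, big_k, n_study))
        rows.append(
            {
                "term_id": term,
                "k": k,
                "n": n_study,
                "K": big_k,
                "N": n_total,
                "p": min(p, 1.0),
                "rich_factor": k / big_k,
            }
        )
    if not rows:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    out = pd.DataFrame(rows)
    # sf can underflow to exactly 0 for extreme overlaps; keep p in (0, 1]
    out["p"] = out["p"].clip(lower=1e-300)
    out["q"] = bh_fdr(out["p"])
    out["enriched"] = out["q"] <= q_cutoff
    out = out.sort_values(["q", "p", "term_id"], kind="stable").reset_index(drop=True)
    return out[RESULT_COLUMNS]


def pathway_enrichment(
    study: set[str],
    background: set[str],
    pathways: Mapping[str, set[str]],
    *,
    q_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Pathway overrepresentation: same test, ranked by Q-value, with the
    rich factor (study hits / background pathway size) reported per pathway."""
    gene2paths: dict[str, set[str]] = {}
    for pid, members in pathways.items():
        if not members:
            warnings.warn(f"pathway {pid} is empty; skipped", stacklevel=2)
            continue
        for g in members:
            gene2paths.setdefault(g, set()).add(pid)
    return term_enrichment(
        study, background, gene2paths, q_cutoff=q_cutoff, min_background_genes=2
    )
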
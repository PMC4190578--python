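"""TPM quantification and exact two-library differential expression.

Expression is quantified as tags per million over unambiguously mapped
tags (so each library's TPM column sums to 10^6). Per-gene differences
between two libraries are tested with the Audic–Claverie conditional
test for tag counts: given a count x in a library of size N1, the count y
in a library of size N2 follows

    P(y | x) = (N2/N1)^y (x+y)! / (x! y! (1 + N2/N1)^(x+y+1)),

which is the negative binomial NB(r = x+1, p = N1/(N1+N2)) — the form used
here for numerically safe tail evaluation. The two-sided p doubles the
smaller tail. Genes are called differentially expressed at FDR <= 0.001
(Benjamini–Hochberg, per comparison) with |log2 ratio| >= 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .simulate import StudyDesign
from .tags import TagLibrary

__all__ = [
    "compute_tpm",
    "expression_matrix",
    "ac_test",
    "bh_fdr",
    "call_degs",
    "run_all_comparisons",
    "common_degs",
    "validation_correlation",
    "deg_sets",
]

DEFAULT_FDR = 1e-3
DEFAULT_LFC = 1.0


def compute_tpm(counts: Mapping[str, int], total: int) -> dict[str, float]:
    """Tags per million: count / total * 1e6."""
    if total < 1:
        raise ValueError("library total must be >= 1")
    scale = 1e6 / total
    return {g: c * scale for g, c in counts.items()}


def expression_matrix(
    libraries: Sequence[TagLibrary], genes: Sequence[str] | None = None
) -> pd.DataFrame:
    """Genes × libraries TPM table (zero for genes without mapped tags)."""
    if genes is None:
        pool: set[str] = set()
        for lib in libraries:
            pool.update(lib.mapped_unambiguous)
        genes = sorted(pool)
    data = {}
    for lib in libraries:
        total = sum(lib.mapped_unambiguous.values())
        if total == 0:
            data[lib.library_id] = pd.Series(0.0, index=genes)
            continue
        tpm = compute_tpm(lib.mapped_unambiguous, total)
        data[lib.library_id] = pd.Series(tpm).reindex(genes).fillna(0.0)
    return pd.DataFrame(data, index=genes)


def ac_test(x, y, n1, n2):
    """Two-sided Audic–Claverie p-value(s); vectorized over x and y.

    ``p = min(1, 2 * min(P(Y <= y | x), P(Y >= y | x)))`` with Y | x
    distributed NB(x+1, N1/(N1+N2)). Both tails include the observed y, so
    p is in (0, 1].
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if n1 < 1 or n2 < 1:
        raise ValueError("library totals must be >= 1")
    p_succ = n1 / (n1 + n2)
    lower = sps.nbinom.cdf(y, x + 1, p_succ)
    upper = sps.nbinom.sf(y - 1, x + 1, p_succ)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    # extreme count differences can underflow the tail to exactly 0;
    # keep the contract p in (0, 1]
    p = np.maximum(p, np.finfo(float).tiny)
    return float(p) if p.ndim == 0 else p


def bh_fdr(pvals: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, clipped at 1.

    ``q_(i) = min_{j >= i} m * p_(j) / j`` over the sorted p-values;
    monotone in p and order-preserving.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


@dataclass(frozen=True)
class ComparisonResult:
    """Per-gene record of one parent-vs-line library comparison."""

    gene_id: str
    x: int
    y: int
    n1: int
    n2: int
    tpm_parent: float
    tpm_line: float
    log2_ratio: float
    p: float
    q: float
    call: str  # up / down / ns


def call_degs(
    parent_lib: TagLibrary,
    line_lib: TagLibrary,
    *,
    fdr_threshold: float = DEFAULT_FDR,
    lfc_threshold: float = DEFAULT_LFC,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Test every gene observed in either library and call DEGs.

    Genes with x = y = 0 are excluded from testing and from the BH family.
    The log2 ratio is computed on TPM with a one-tag pseudo-TPM offset
    (1e6/N per library) added to both sides so zero counts stay finite; the
    p-value itself uses the raw counts. Calls require both q <= fdr and
    |log2 ratio| >= lfc.
    """
    n1 = sum(parent_lib.mapped_unambiguous.values())
    n2 = sum(line_lib.mapped_unambiguous.values())
    if n1 == 0 or n2 == 0:
        raise ValueError("both libraries must have mapped tags")
    if genes is None:
        genes = sorted(
            set(parent_lib.mapped_unambiguous) | set(line_lib.mapped_unambiguous)
        )
    x = np.array([parent_lib.mapped_unambiguous.get(g, 0) for g in genes])
    y = np.array([line_lib.mapped_unambiguous.get(g, 0) for g in genes])
    tested = (x + y) > 0
    genes = [g for g, t in zip(genes, tested) if t]
    x, y = x[tested], y[tested]

    tpm_parent = x * (1e6 / n1)
    tpm_line = y * (1e6 / n2)
    log2_ratio = np.log2((tpm_line + 1e6 / n2) / (tpm_parent + 1e6 / n1))
    p = ac_test(x, y, n1, n2)
    q = bh_fdr(p)
    call = np.full(len(genes), "ns", dtype=object)
    call[(q <= fdr_threshold) & (log2_ratio >= lfc_threshold)] = "up"
    call[(q <= fdr_threshold) & (log2_ratio <= -lfc_threshold)] = "down"
    return pd.DataFrame(
        {
            "gene_id": genes,
            "x": x,
            "y": y,
            "tpm_parent": tpm_parent,
            "tpm_line": tpm_line,
            "log2_ratio": log2_ratio,
            "p": p,
            "q": q,
            "call": call,
        }
    ).set_index("gene_id")


def run_all_comparisons(
    design: StudyDesign,
    libraries: Mapping[str, TagLibrary],
    *,
    fdr_threshold: float = DEFAULT_FDR,
    lfc_threshold: float = DEFAULT_LFC,
) -> dict[tuple[str, str], pd.DataFrame]:
    """One DEG table per (non-parent line, stage) versus the parent.

    A 6-line × 4-stage design yields the study's 20 comparisons. Raises if
    the parent library is missing at any required stage.
    """
    missing = [
        stage
        for stage in design.stages
        if design.library_id(design.parent, stage) not in libraries
    ]
    if missing:
        raise ValueError(f"parent library missing at stage(s): {missing}")
    results: dict[tuple[str, str], pd.DataFrame] = {}
    for line, stage in design.comparisons:
        parent_lib = libraries[design.library_id(design.parent, stage)]
        line_lib = libraries[design.library_id(line, stage)]
        results[(line, stage)] = call_degs(
            parent_lib,
            line_lib,
            fdr_threshold=fdr_threshold,
            lfc_threshold=lfc_threshold,
        )
    return results


def deg_sets(table: pd.DataFrame, direction: str | None = None) -> set[str]:
    """Gene ids called up/down (or either, when direction is None)."""
    if direction is None:
        mask = table["call"] != "ns"
    elif direction in ("up", "down"):
        mask = table["call"] == direction
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return set(table.index[mask])


def common_degs(
    deg_tables: Mapping[str, pd.DataFrame],
    mode: str = "intersection",
    *,
    line: str | None = None,
    strict: bool = False,
) -> set[str]:
    """Set algebra over per-line DEG calls at one stage.

    ``intersection``: genes called DE (either direction) in every line;
    ``up_in_all``: up in every line; ``down_only_in``: down in ``line`` and
    not down in any other line (with ``strict=True``, additionally up in
    every other line).
    """
    if len(deg_tables) < 2:
        raise ValueError("need at least two DEG tables")
    if mode == "intersection":
        sets = [deg_sets(t) for t in deg_tables.values()]
        return set.intersection(*sets)
    if mode == "up_in_all":
        sets = [deg_sets(t, "up") for t in deg_tables.values()]
        return set.intersection(*sets)
    if mode == "down_only_in":
        if line is None or line not in deg_tables:
            raise ValueError(f"unknown line {line!r} for down_only_in")
        target = deg_sets(deg_tables[line], "down")
        for other, table in deg_tables.items():
            if other == line:
                continue
            if strict:
                target &= deg_sets(table, "up")
            else:
                target -= deg_sets(table, "down")
        return target
    raise ValueError(f"unknown mode {mode!r}")


def validation_correlation(
    tpm_vector: Sequence[float],
    reference_vector: Sequence[float],
    *,
    log_transform: bool = True,
) -> float:
    """Squared Pearson correlation between platform measurements.

    Mirrors cross-platform expression validation (e.g. sequencing TPM vs
    qRT-PCR 2^-dCT relative quantities): values are log2(v+1)-transformed
    by default, then r^2 of the Pearson correlation is returned.
    """
    a = np.asarray(tpm_vector, dtype=float)
    b = np.asarray(reference_vector, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    if log_transform:
        if np.any(a < 0) or np.any(b < 0):
            raise ValueError("log transform requires non-negative values")
        a = np.log2(a + 1.0)
        b = np.log2(b + 1.0)
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        raise ValueError("zero variance: correlation undefined")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)
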
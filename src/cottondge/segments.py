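"""Mining DEGs inside introgressed donor chromosome segments.

Each chromosome segment introgression line carries one or more donor
intervals; genes whose loci overlap an interval (1-based, fully-closed
coordinates, any shared base, strand-agnostic) are the segment gene set.
Candidates are segment genes called differentially expressed in the
requested direction in at least one stage of that line's comparisons, and
can be handed to the enrichment module for functional characterization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .enrichment import term_enrichment

__all__ = [
    "SegmentDefinition",
    "genes_in_segment",
    "segment_deg_candidates",
    "segment_candidate_enrichment",
]


@dataclass(frozen=True)
class SegmentDefinition:
    """One introgressed donor interval carried by a line."""

    line_id: str
    chrom: str
    start: int  # 1-based, inclusive
    end: int  # 1-based, inclusive

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")


def genes_in_segment(segment: SegmentDefinition, loci: pd.DataFrame) -> set[str]:
    """Genes whose interval overlaps the segment by at least one base.

    ``loci`` columns: gene_id, chrom, start, end (1-based fully-closed);
    strand is ignored. Unknown chromosome raises.
    """
    if segment.chrom not in set(loci["chrom"]):
        raise ValueError(f"unknown chromosome {segment.chrom!r}")
    sub = loci[loci["chrom"] == segment.chrom]
    hit = (sub["start"] <= segment.end) & (sub["end"] >= segment.start)
    return set(sub.loc[hit, "gene_id"])


def segment_deg_candidates(
    segment_genes: set[str],
    deg_tables: Mapping[str, pd.DataFrame],
    direction: str = "up",
) -> pd.DataFrame:
    """Segment genes called ``direction`` in at least one stage.

    ``deg_tables`` maps stage label → ComparisonResult table for the
    segment's line. Returns a gene × stage boolean profile (True where the
    gene carries the requested call at that stage), empty when no segment
    gene is differential.
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    stages = list(deg_tables)
    profile: dict[str, list[bool]] = {}
    for gene in sorted(segment_genes):
        flags = [
            gene in table.index and table.loc[gene, "call"] == direction
            for table in deg_tables.values()
        ]
        if any(flags):
            profile[gene] = flags
    out = pd.DataFrame.from_dict(profile, orient="index", columns=stages)
    out.index.name = "gene_id"
    return out


def segment_candidate_enrichment(
    candidates: set[str],
    background: set[str],
    gene2terms: Mapping[str, set[str]],
    *,
    q_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Functional enrichment of segment candidate genes (delegates to the
    term-enrichment test); empty candidate sets return an empty table with
    a warning, and single-gene sets are flagged low-power."""
    if not candidates:
        warnings.warn("empty candidate set: no enrichment computed", stacklevel=2)
        return term_enrichment(set(), background, gene2terms, q_cutoff=q_cutoff)
    if len(candidates) == 1:
        warnings.warn(
            "single candidate gene: enrichment has minimal power", stacklevel=2
        )
    return term_enrichment(candidates, background, gene2terms, q_cutoff=q_cutoff)
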
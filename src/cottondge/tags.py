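"""CATG-anchored tag database, library cleaning, and 1-mismatch mapping.

The DGE chemistry counts 21-nt tags: an NlaIII CATG anchor plus the 17
downstream bases. Every CATG occurrence of every reference transcript with
at least 17 trailing bases contributes one database tag (sense strand;
antisense indexing available by flag). Library cleaning removes short
(<21 nt) tags and singletons; mapping matches clean tags exactly first and
then at Hamming distance 1, and excludes any tag hitting more than one
distinct gene within the winning tier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .simulate import ANCHOR, TAG_LENGTH, ReferenceTranscript

__all__ = [
    "TagRecord",
    "TagDatabase",
    "TagLibrary",
    "build_tag_database",
    "clean_tags",
    "map_tags",
    "summarize_library",
    "process_library",
]

_ACGT = set("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class TagRecord:
    """One database entry: tag sequence, source gene, anchor offset."""

    tag: str
    gene_id: str
    position: int  # 0-based offset of the CATG anchor within the transcript


@dataclass
class TagDatabase:
    """Tag → {(gene, position)} index with ambiguity and tagless bookkeeping."""

    entries: dict[str, list[tuple[str, int]]]
    ambiguous_tags: set[str]
    tagless_genes: set[str]
    genes: set[str]

    def __len__(self) -> int:
        return len(self.entries)

    def genes_for(self, tag: str) -> set[str]:
        return {g for g, _ in self.entries.get(tag, ())}


@dataclass
class TagLibrary:
    """One library's cleaned and mapped tag counts plus audit totals.

    Invariants: ``clean_total = raw_total - n_short_removed -
    n_singletons_removed`` and ``n_mapped + n_ambiguous_excluded +
    n_unmapped = clean_total``.
    """

    library_id: str
    raw_total: int
    clean: dict[str, int]
    clean_total: int
    mapped_unambiguous: dict[str, int]
    stats: dict[str, float] = field(default_factory=dict)


def build_tag_database(
    reference: Sequence[ReferenceTranscript], *, antisense: bool = False
) -> TagDatabase:
    """Index every CATG-anchored 21-nt tag of every transcript.

    Transcripts containing non-ACGT characters are skipped with a warning;
    genes contributing no tag (no anchor, or anchors too close to the 3'
    end) are listed in ``tagless_genes``.
    """
    if not reference:
        raise ValueError("empty reference")
    entries: dict[str, list[tuple[str, int]]] = {}
    genes: set[str] = set()
    tagless: set[str] = set()
    for rec in reference:
        genes.add(rec.gene_id)
        seq = rec.sequence.upper()
        if set(seq) - _ACGT:
            warnings.warn(
                f"skipping {rec.gene_id}: non-ACGT characters in sequence",
                stacklevel=2,
            )
            tagless.add(rec.gene_id)
            continue
        strands = [seq]
        if antisense:
            strands.append(seq.translate(_COMPLEMENT)[::-1])
        n_tags = 0
        for strand in strands:
            start = strand.find(ANCHOR)
            while start != -1:
                if start + TAG_LENGTH <= len(strand):
                    tag = strand[start : start + TAG_LENGTH]
                    entries.setdefault(tag, []).append((rec.gene_id, start))
                    n_tags += 1
                start = strand.find(ANCHOR, start + 1)
        if n_tags == 0:
            tagless.add(rec.gene_id)
    ambiguous = {
        tag for tag, hits in entries.items() if len({g for g, _ in hits}) >= 2
    }
    return TagDatabase(
        entries=entries, ambiguous_tags=ambiguous, tagless_genes=tagless, genes=genes
    )


def clean_tags(raw: Mapping[str, int]) -> tuple[dict[str, int], dict[str, int]]:
    """Remove short (<21 nt) tags, then singletons (library-wide count 1).

    Returns the surviving tag → count table and removal stats with
    count-level tallies (``n_short_removed`` sums the counts of short tags;
    each singleton contributes 1).
    """
    n_short = 0
    survivors: dict[str, int] = {}
    for tag, count in raw.items():
        if count < 1:
            raise ValueError(f"tag {tag!r} has non-positive count {count}")
        if len(tag) < TAG_LENGTH:
            n_short += count
        else:
            survivors[tag] = count
    n_singletons = sum(1 for c in survivors.values() if c == 1)
    clean = {t: c for t, c in survivors.items() if c > 1}
    stats = {
        "n_short_removed": n_short,
        "n_singletons_removed": n_singletons,
    }
    return clean, stats


def _hamming1_variants(tag: str) -> Iterable[str]:
    """All 63 sequences at Hamming distance exactly 1 from a 21-nt tag."""
    for i, base in enumerate(tag):
        for alt in "ACGT":
            if alt != base:
                yield f"{tag[:i]}{alt}{tag[i + 1:]}"


def map_tags(
    clean: Mapping[str, int], db: TagDatabase, *, mismatches: int = 1
) -> tuple[dict[str, int], dict[str, int]]:
    """Map clean tags to genes: exact tier first, then Hamming distance 1.

    Within the winning tier, a tag hitting exactly one distinct gene
    contributes its full count to that gene (positions within a gene are
    summed); a tag hitting two or more genes is excluded as ambiguous. A
    tag that is ambiguous at distance 0 stays excluded even if some
    distance-1 interpretation would be unique.
    """
    if mismatches not in (0, 1):
        raise ValueError("mismatches must be 0 or 1")
    gene_counts: dict[str, int] = {}
    n_mapped = 0
    n_ambiguous = 0
    n_unmapped = 0
    for tag, count in clean.items():
        if len(tag) != TAG_LENGTH:
            raise ValueError(
                f"clean tag {tag!r} is not {TAG_LENGTH} nt; cleaning contract violated"
            )
        hit_genes = db.genes_for(tag)
        if not hit_genes and mismatches == 1:
            hit_genes = set()
            for variant in _hamming1_variants(tag):
                hit_genes |= db.genes_for(variant)
                if len(hit_genes) > 1:
                    break
        if len(hit_genes) == 1:
            gene = next(iter(hit_genes))
            gene_counts[gene] = gene_counts.get(gene, 0) + count
            n_mapped += count
        elif len(hit_genes) > 1:
            n_ambiguous += count
        else:
            n_unmapped += count
    tallies = {
        "n_mapped": n_mapped,
        "n_ambiguous_excluded": n_ambiguous,
        "n_unmapped": n_unmapped,
    }
    return gene_counts, tallies


def summarize_library(lib: TagLibrary, db: TagDatabase) -> dict[str, float]:
    """Per-library mapping statistics (fractions in [0, 1])."""
    if lib.clean_total == 0:
        warnings.warn(
            f"library {lib.library_id}: zero clean tags, reporting zero rates",
            stacklevel=2,
        )
        pct_mapped = 0.0
        pct_genes = 0.0
    else:
        pct_mapped = lib.stats.get("n_mapped", 0) / lib.clean_total
        pct_genes = (
            sum(1 for c in lib.mapped_unambiguous.values() if c > 0) / len(db.genes)
            if db.genes
            else 0.0
        )
    stats = dict(lib.stats)
    stats["pct_unambiguous_mapped"] = pct_mapped
    stats["pct_genes_hit"] = pct_genes
    lib.stats = stats
    return stats


def process_library(
    library_id: str,
    raw: Mapping[str, int],
    db: TagDatabase,
    *,
    mismatches: int = 1,
) -> TagLibrary:
    """Clean, map and summarize one raw tag library."""
    raw_total = sum(raw.values())
    clean, clean_stats = clean_tags(raw)
    clean_total = sum(clean.values())
    assert (
        clean_total
        == raw_total
        - clean_stats["n_short_removed"]
        - clean_stats["n_singletons_removed"]
    )
    gene_counts, tallies = map_tags(clean, db, mismatches=mismatches)
    lib = TagLibrary(
        library_id=library_id,
        raw_total=raw_total,
        clean=clean,
        clean_total=clean_total,
        mapped_unambiguous=gene_counts,
        stats={**clean_stats, **tallies},
    )
    summarize_library(lib, db)
    return lib
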
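"""Synthetic DGE tag-profiling data with known ground truth.

Emulates the statistical structure of an NlaIII-anchored digital gene
expression experiment on a chromosome segment introgression line (CSIL)
panel: a reference transcript set, a line × stage library design with one
recurrent parent, heavy-tailed true expression with planted fold changes,
and raw 21-nt tag libraries with per-base sequencing error, short-tag and
singleton contamination.

Every operation is deterministic for a fixed seed; per-library random
streams are derived from a single master seed and the library identifier,
so libraries can be regenerated independently and in any order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ReferenceTranscript",
    "StudyDesign",
    "GroundTruth",
    "DEFAULT_LINES",
    "DEFAULT_STAGES",
    "DEFAULT_PARENT",
    "generate_reference",
    "generate_design",
    "simulate_true_expression",
    "simulate_tag_library",
    "generate_annotations",
    "generate_loci_and_segments",
    "write_reference_fasta",
    "write_tag_library",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
ANCHOR = "CATG"
TAG_LENGTH = 21

# The study panel: five introgression lines plus the recurrent parent TM-1,
# sampled at four fiber-elongation stages (days post-anthesis).
DEFAULT_LINES = (
    "TM-1",
    "CSIL-35431",
    "CSIL-31134",
    "CSIL-31068",
    "CSIL-31044",
    "CSIL-35368",
)
DEFAULT_STAGES = ("05DPA", "10DPA", "15DPA", "20DPA")
DEFAULT_PARENT = "TM-1"


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


class DesignError(ValueError):
    """Invalid study design (e.g. duplicated line × stage library)."""


class SimulationError(RuntimeError):
    """Simulation cannot proceed (e.g. no taggable genes)."""


@dataclass(frozen=True)
class ReferenceTranscript:
    """One reference gene model: identifier plus sense-strand sequence."""

    gene_id: str
    sequence: str

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.sequence)


@dataclass(frozen=True)
class StudyDesign:
    """Line × stage library layout with a designated recurrent parent.

    ``libraries`` holds one ``(library_id, line, stage)`` triple per
    line × stage combination; the parent line must be present at every
    stage so that every non-parent library has a same-stage baseline.
    """

    libraries: tuple[tuple[str, str, str], ...]
    lines: tuple[str, ...]
    stages: tuple[str, ...]
    parent: str

    @property
    def library_ids(self) -> list[str]:
        return [lib_id for lib_id, _, _ in self.libraries]

    @property
    def n_libraries(self) -> int:
        return len(self.libraries)

    @property
    def comparisons(self) -> list[tuple[str, str]]:
        """All (line, stage) pairs compared against the parent."""
        return [
            (line, stage)
            for line in self.lines
            if line != self.parent
            for stage in self.stages
        ]

    @property
    def n_comparisons(self) -> int:
        return len(self.comparisons)

    def library_id(self, line: str, stage: str) -> str:
        for lib_id, ln, st in self.libraries:
            if ln == line and st == stage:
                return lib_id
        raise DesignError(f"no library for line={line!r} stage={stage!r}")


@dataclass
class GroundTruth:
    """Planted truth: relative abundances and per-library log2 fold changes.

    ``abundance`` is a genes × libraries table whose columns each sum to 1;
    ``de_log2fc`` has the same shape and holds the planted log2 fold change
    of each gene versus the recurrent parent at the same stage (0 for
    non-DE genes and for every parent library).
    """

    abundance: pd.DataFrame
    de_log2fc: pd.DataFrame

    def de_genes(self, library_id: str) -> list[str]:
        col = self.de_log2fc[library_id]
        return list(col.index[col != 0.0])


def _library_rng(master_seed: int, library_id: str) -> np.random.Generator:
    """Deterministic per-library stream keyed on (master seed, library id)."""
    return np.random.default_rng(
        [int(master_seed) % (2**31), zlib.crc32(library_id.encode())]
    )


def generate_reference(
    n_genes: int,
    length_range: tuple[int, int] = (300, 2000),
    *,
    no_catg_fraction: float = 0.02,
    paralog_fraction: float = 0.30,
    paralog_divergence: float = 0.01,
    seed: int = 0,
) -> list[ReferenceTranscript]:
    """Generate a reference transcript set with i.i.d. nucleotides.

    A ``no_catg_fraction`` Bernoulli subset of genes is guaranteed to
    contain no CATG anchor (they exercise tagless-gene handling); every
    other gene is guaranteed at least one anchor. A ``paralog_fraction``
    subset of the remaining genes is generated as a low-divergence copy of
    another gene, which plants genuinely ambiguous tags — the mechanism
    behind the roughly-half unambiguous mapping rate typical of DGE
    libraries built on a diploid reference for a polyploid-derived sample.
    """
    if n_genes < 1:
        raise ConfigurationError("n_genes must be >= 1")
    lo, hi = length_range
    if not (TAG_LENGTH <= lo <= hi <= 10000):
        raise ConfigurationError(
            f"length range must lie within [{TAG_LENGTH}, 10000], got {length_range}"
        )
    if not 0.0 <= no_catg_fraction <= 1.0:
        raise ConfigurationError("no_catg_fraction must be in [0, 1]")
    if not 0.0 <= paralog_fraction < 1.0:
        raise ConfigurationError("paralog_fraction must be in [0, 1)")

    rng = np.random.default_rng(seed)
    width = max(5, len(str(n_genes)))
    lengths = rng.integers(lo, hi + 1, size=n_genes)
    tagless = rng.random(n_genes) < no_catg_fraction
    is_paralog = (rng.random(n_genes) < paralog_fraction) & ~tagless
    is_paralog[0] = False  # first gene always a fresh draw

    sequences: list[np.ndarray] = []
    for i in range(n_genes):
        if is_paralog[i]:
            src = int(rng.integers(0, i))
            seq = sequences[src].copy()
            mut = rng.random(seq.size) < paralog_divergence
            if mut.any():
                shift = rng.integers(1, 4, size=int(mut.sum()))
                idx = np.searchsorted(_BASES, seq[mut])
                seq[mut] = _BASES[(idx + shift) % 4]
        else:
            seq = _BASES[rng.integers(0, 4, size=int(lengths[i]))]
        if tagless[i]:
            seq = _strip_anchor(seq, rng)
        else:
            seq = _ensure_anchor(seq, rng)
        sequences.append(seq)

    return [
        ReferenceTranscript(f"G{i + 1:0{width}d}", seq.tobytes().decode())
        for i, seq in enumerate(sequences)
    ]


def _strip_anchor(seq: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Mutate until the sequence contains no CATG occurrence."""
    anchor = np.frombuffer(ANCHOR.encode(), dtype=np.uint8)
    seq = seq.copy()
    while True:
        hits = _find_anchor(seq, anchor)
        if hits.size == 0:
            return seq
        for pos in hits:
            old = seq[pos + 3]
            choices = _BASES[_BASES != old]
            seq[pos + 3] = choices[rng.integers(0, 3)]


def _ensure_anchor(seq: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Guarantee at least one CATG with a full 21-nt tag after it."""
    anchor = np.frombuffer(ANCHOR.encode(), dtype=np.uint8)
    hits = _find_anchor(seq, anchor)
    hits = hits[hits + TAG_LENGTH <= seq.size]
    if hits.size:
        return seq
    seq = seq.copy()
    pos = int(rng.integers(0, seq.size - TAG_LENGTH + 1))
    seq[pos : pos + 4] = anchor
    return seq


def _find_anchor(seq: np.ndarray, anchor: np.ndarray) -> np.ndarray:
    if seq.size < 4:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(seq, 4)
    return np.nonzero((windows == anchor).all(axis=1))[0]


def generate_design(
    line_ids: Sequence[str] = DEFAULT_LINES,
    stages: Sequence[str] = DEFAULT_STAGES,
    parent: str = DEFAULT_PARENT,
) -> StudyDesign:
    """One library per line × stage; parent-vs-line comparisons implied."""
    if parent not in line_ids:
        raise DesignError(f"parent {parent!r} not among line_ids")
    seen: set[tuple[str, str]] = set()
    libraries = []
    for line in line_ids:
        for stage in stages:
            if (line, stage) in seen:
                raise DesignError(f"duplicate library for ({line}, {stage})")
            seen.add((line, stage))
            libraries.append((f"{line}_{stage}", line, stage))
    return StudyDesign(
        libraries=tuple(libraries),
        lines=tuple(dict.fromkeys(line_ids)),
        stages=tuple(stages),
        parent=parent,
    )


def simulate_true_expression(
    reference: Sequence[ReferenceTranscript],
    design: StudyDesign,
    *,
    de_fraction: float = 0.10,
    shared_de_fraction: float = 0.5,
    log2fc_magnitude: float = 2.0,
    meanlog: float = 0.0,
    sdlog: float = 1.5,
    seed: int = 0,
) -> GroundTruth:
    """Draw shared log-normal baselines and plant DE genes per line × stage.

    Baseline relative abundances are log-normal (heavy-tailed, as tag-count
    distributions are) and shared across libraries. For each non-parent
    line × stage a ``de_fraction`` subset of genes has its abundance
    multiplied by ``2**(±log2fc_magnitude)`` (random sign, balanced in
    expectation so renormalization stays mild); columns are renormalized to
    sum to 1 and the planted log2 fold changes recorded.

    A ``shared_de_fraction`` of each library's DE picks comes from a
    per-stage pool common to every non-parent line (with a common sign),
    emulating stage-driven responses shared across introgression lines —
    the structure behind the study's common-DEG sets; the remainder is
    private to the line.
    """
    if not 0.0 <= de_fraction <= 1.0:
        raise ConfigurationError("de_fraction must be in [0, 1]")
    if not 0.0 <= shared_de_fraction <= 1.0:
        raise ConfigurationError("shared_de_fraction must be in [0, 1]")
    if log2fc_magnitude < 0:
        raise ConfigurationError("log2fc_magnitude must be >= 0")

    rng = np.random.default_rng(seed)
    genes = [t.gene_id for t in reference]
    n = len(genes)
    baseline = rng.lognormal(mean=meanlog, sigma=sdlog, size=n)
    baseline /= baseline.sum()

    lib_ids = design.library_ids
    abundance = pd.DataFrame(
        np.tile(baseline[:, None], (1, len(lib_ids))), index=genes, columns=lib_ids
    )
    lfc = pd.DataFrame(0.0, index=genes, columns=lib_ids)

    n_de = int(round(de_fraction * n))
    n_shared = int(round(shared_de_fraction * n_de))
    shared_pool: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for stage in design.stages:
        idx = rng.choice(n, size=n_shared, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_shared)
        shared_pool[stage] = (idx, signs)

    for line, stage in design.comparisons:
        lib = design.library_id(line, stage)
        shared_idx, shared_signs = shared_pool[stage]
        remaining = np.setdiff1d(np.arange(n), shared_idx, assume_unique=False)
        private_idx = rng.choice(remaining, size=n_de - n_shared, replace=False)
        de_idx = np.concatenate([shared_idx, private_idx])
        signs = np.concatenate(
            [shared_signs, rng.choice([-1.0, 1.0], size=n_de - n_shared)]
        )
        planted = signs * log2fc_magnitude
        col = abundance[lib].to_numpy()
        col[de_idx] *= 2.0**planted
        abundance[lib] = col
        lfc.iloc[de_idx, lfc.columns.get_loc(lib)] = planted

    abundance = abundance / abundance.sum(axis=0)
    return GroundTruth(abundance=abundance, de_log2fc=lfc)


def _gene_tags(sequence: str) -> list[str]:
    """All CATG-anchored 21-nt tags of a transcript, 5'→3' order."""
    seq = np.frombuffer(sequence.encode(), dtype=np.uint8)
    anchor = np.frombuffer(ANCHOR.encode(), dtype=np.uint8)
    hits = _find_anchor(seq, anchor)
    hits = hits[hits + TAG_LENGTH <= seq.size]
    return [sequence[p : p + TAG_LENGTH] for p in hits]


def simulate_tag_library(
    reference: Sequence[ReferenceTranscript],
    truth: GroundTruth,
    library_id: str,
    *,
    depth: int = 100_000,
    error_rate: float = 0.01,
    short_frac: float = 0.01,
    singleton_boost: float = 0.005,
    three_prime_weight: float = 0.8,
    seed: int = 0,
) -> dict[str, int]:
    """Draw ``depth`` raw tags for one library; returns a tag → count table.

    Genes are drawn by true abundance (restricted to taggable genes), the
    tag position within a gene by a geometric 3' bias (``three_prime_weight``
    on the 3'-most anchor), each base is substituted independently with
    ``error_rate``, a ``short_frac`` of tags is truncated below 21 nt, and a
    ``singleton_boost`` fraction is emitted as unique junk tags. Counts sum
    to ``depth`` exactly.
    """
    if depth < 1:
        raise ConfigurationError("depth must be >= 1")
    if not 0.0 <= error_rate <= 0.1:
        raise ConfigurationError("error_rate must be in [0, 0.1]")
    if not 0.0 <= short_frac < 1.0 or not 0.0 <= singleton_boost < 1.0:
        raise ConfigurationError("junk fractions must be in [0, 1)")
    if not 0.0 < three_prime_weight <= 1.0:
        raise ConfigurationError("three_prime_weight must be in (0, 1]")

    rng = _library_rng(seed, library_id)

    tags_per_gene = {t.gene_id: _gene_tags(t.sequence) for t in reference}
    taggable = [g for g, tags in tags_per_gene.items() if tags]
    if not taggable:
        raise SimulationError("reference contains no taggable genes")

    abund = truth.abundance[library_id].reindex(taggable).to_numpy()
    total = abund.sum()
    if total <= 0:
        raise SimulationError("zero total abundance over taggable genes")
    probs = abund / total

    gene_counts = rng.multinomial(depth, probs)

    # Expand drawn tags into a depth × 21 byte matrix (deterministic order).
    rows: list[np.ndarray] = []
    repeats: list[int] = []
    w = three_prime_weight
    for g, cnt in zip(taggable, gene_counts):
        if cnt == 0:
            continue
        tags = tags_per_gene[g]
        k = len(tags)
        if k == 1:
            pos_counts = np.array([cnt])
        else:
            # geometric weights from the 3'-most anchor inward
            weights = w * (1.0 - w) ** np.arange(k, dtype=float)
            if w < 1.0:
                weights = weights / weights.sum()
            else:
                weights = np.zeros(k)
                weights[0] = 1.0
            pos_counts = rng.multinomial(cnt, weights)
        for tag, pc in zip(reversed(tags), pos_counts):
            if pc:
                rows.append(np.frombuffer(tag.encode(), dtype=np.uint8))
                repeats.append(int(pc))

    mat = np.repeat(np.vstack(rows), repeats, axis=0)

    if error_rate > 0.0:
        flip = rng.random(mat.shape) < error_rate
        if flip.any():
            shift = rng.integers(1, 4, size=int(flip.sum()))
            idx = np.searchsorted(_BASES, mat[flip])
            mat[flip] = _BASES[(idx + shift) % 4]

    n_junk = int(round(singleton_boost * depth))
    n_short = int(round(short_frac * depth))
    n_junk = min(n_junk, depth)
    n_short = min(n_short, depth - n_junk)

    counts: dict[str, int] = {}

    def _add(tag: str, c: int) -> None:
        counts[tag] = counts.get(tag, 0) + c

    # unique junk tags (stress the singleton filter); replacement keeps
    # the total at exactly `depth`
    for _ in range(n_junk):
        junk = _BASES[rng.integers(0, 4, size=TAG_LENGTH)].tobytes().decode()
        _add(junk, 1)

    # truncated (short) tags
    short_lens = rng.integers(12, TAG_LENGTH, size=n_short)
    for i, ln in enumerate(short_lens):
        _add(mat[n_junk + i, : int(ln)].tobytes().decode(), 1)

    body = mat[n_junk + n_short :]
    if body.size:
        uniq, cnts = np.unique(body, axis=0, return_counts=True)
        for row, c in zip(uniq, cnts):
            _add(row.tobytes().decode(), int(c))

    assert sum(counts.values()) == depth
    return counts


def generate_annotations(
    genes: Sequence[str],
    *,
    n_terms: int = 40,
    n_pathways: int = 15,
    mean_terms_per_gene: float = 2.0,
    seed: int = 0,
) -> tuple[dict[str, set[str]], list[tuple[str, str]], dict[str, set[str]]]:
    """Synthetic gene → term map, a small term DAG, and a pathway map.

    Terms form a forest-like DAG (each term has 0–2 parents among earlier
    terms); genes receive a Poisson number of leaf-ish terms. Pathways are
    disjoint-ish gene blocks of varying size. Purely artifact plumbing for
    self-contained runs; real annotations are consumed as input TSVs.
    """
    rng = np.random.default_rng(seed)
    terms = [f"T{i:04d}" for i in range(n_terms)]
    edges: list[tuple[str, str]] = []
    for i, t in enumerate(terms):
        if i == 0:
            continue
        n_par = int(rng.integers(0, min(3, i + 1)))
        for p in rng.choice(i, size=n_par, replace=False):
            edges.append((t, terms[int(p)]))

    gene2terms: dict[str, set[str]] = {}
    for g in genes:
        k = min(n_terms, rng.poisson(mean_terms_per_gene))
        if k:
            chosen = rng.choice(n_terms, size=k, replace=False)
            gene2terms[g] = {terms[int(c)] for c in chosen}

    pathways: dict[str, set[str]] = {}
    gene_arr = np.array(genes)
    for j in range(n_pathways):
        size = int(rng.integers(5, max(6, len(genes) // n_pathways + 5)))
        members = rng.choice(len(gene_arr), size=min(size, len(gene_arr)), replace=False)
        pathways[f"P{j:03d}"] = {str(gene_arr[int(m)]) for m in members}
    return gene2terms, edges, pathways


def generate_loci_and_segments(
    genes: Sequence[str],
    design: StudyDesign,
    *,
    n_chromosomes: int = 13,
    gene_span: int = 2000,
    gene_gap: int = 8000,
    segment_genes: int = 40,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lay genes along chromosomes and define one introgressed segment per line.

    Returns (loci, segments): loci with 1-based fully-closed coordinates
    (gene_id, chrom, start, end, strand); segments with one interval per
    non-parent line (line_id, chrom, start, end) covering ``segment_genes``
    consecutive genes.
    """
    rng = np.random.default_rng(seed)
    chroms = [f"Chr{c + 1:02d}" for c in range(n_chromosomes)]
    per_chrom = int(np.ceil(len(genes) / n_chromosomes))
    rows = []
    for i, g in enumerate(genes):
        c = i // per_chrom
        j = i % per_chrom
        start = 1 + j * (gene_span + gene_gap)
        rows.append(
            {
                "gene_id": g,
                "chrom": chroms[c],
                "start": start,
                "end": start + gene_span - 1,
                "strand": "+" if rng.random() < 0.5 else "-",
            }
        )
    loci = pd.DataFrame(rows)

    seg_rows = []
    non_parent = [ln for ln in design.lines if ln != design.parent]
    for k, line in enumerate(non_parent):
        chrom = chroms[k % n_chromosomes]
        sub = loci[loci["chrom"] == chrom].reset_index(drop=True)
        n_seg = min(segment_genes, len(sub))
        start_idx = int(rng.integers(0, max(1, len(sub) - n_seg + 1)))
        block = sub.iloc[start_idx : start_idx + n_seg]
        seg_rows.append(
            {
                "line_id": line,
                "chrom": chrom,
                "start": int(block["start"].min()),
                "end": int(block["end"].max()),
            }
        )
    segments = pd.DataFrame(seg_rows)
    return loci, segments


def write_reference_fasta(reference: Sequence[ReferenceTranscript], path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(t.sequence), id=t.gene_id, description="")
        for t in reference
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def write_tag_library(counts: Mapping[str, int], path) -> None:
    """2-column TSV ``tag<TAB>count`` sorted by tag (byte-stable)."""
    with open(path, "w") as fh:
        for tag in sorted(counts):
            fh.write(f"{tag}\t{counts[tag]}\n")
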
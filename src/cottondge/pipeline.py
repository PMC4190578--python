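"""End-to-end orchestration: simulate → tag pipeline → DE → clustering →
enrichment → segment mining, as one reproducible, manifest-stamped run.

A run is driven by a :class:`RunConfig` (plain dataclass, loadable from
YAML). One master seed is fanned out deterministically per stage and per
library, so a rerun with an identical config is byte-identical. Outputs
are plain TSV/JSON under the run directory::

    reference.fasta           design.tsv            truth/
    tags/<lib>.tags.tsv       tag_db.tsv
    counts/<lib>.counts.tsv   counts/<lib>.stats.tsv
    tpm_matrix.tsv            comparisons/<line>_<stage>.tsv
    deg_summary.tsv           clustering/   enrichment/   segments/
    manifest.json
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import clustering, diffexpr, enrichment, segments, simulate, tags

__all__ = ["RunConfig", "validate_config", "run_pipeline", "load_config"]

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Parameters of one pipeline run (defaults mirror the desk-scale study
    layout: 6 lines × 4 stages, 2,000 genes, 10^5 tags per library)."""

    # design
    lines: tuple[str, ...] = simulate.DEFAULT_LINES
    stages: tuple[str, ...] = simulate.DEFAULT_STAGES
    parent: str = simulate.DEFAULT_PARENT
    # simulation
    n_genes: int = 2000
    length_range: tuple[int, int] = (300, 2000)
    no_catg_fraction: float = 0.02
    paralog_fraction: float = 0.30
    paralog_divergence: float = 0.01
    depth: int = 100_000
    error_rate: float = 0.01
    short_frac: float = 0.01
    singleton_boost: float = 0.005
    de_fraction: float = 0.10
    log2fc_magnitude: float = 2.0
    # thresholds
    fdr: float = 1e-3
    lfc: float = 1.0
    enrich_q: float = 0.05
    expressed_fraction: float = 0.5
    # clustering
    sota_clusters: int = 5
    deg_groups: int = 6
    # segments
    segment_genes: int = 40
    # reproducibility
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for key in ("lines", "stages", "length_range"):
            d[key] = list(d[key])
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("lines", "stages", "length_range"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def validate_config(config: RunConfig) -> list[str]:
    """All violations found (empty list means the config is valid)."""
    problems: list[str] = []
    if config.parent not in config.lines:
        problems.append(f"parent {config.parent!r} not among lines")
    if len(set(config.lines)) != len(config.lines):
        problems.append("duplicate line identifiers")
    if len(set(config.stages)) != len(config.stages):
        problems.append("duplicate stage labels")
    if config.n_genes < 1:
        problems.append("n_genes must be >= 1")
    lo, hi = config.length_range
    if not (simulate.TAG_LENGTH <= lo <= hi <= 10000):
        problems.append(f"length_range {config.length_range} outside [21, 10000]")
    if config.depth < 1:
        problems.append("depth must be >= 1")
    if not 0.0 <= config.error_rate <= 0.1:
        problems.append("error_rate must be in [0, 0.1]")
    if not 0.0 <= config.de_fraction <= 1.0:
        problems.append("de_fraction must be in [0, 1]")
    for name in ("fdr", "enrich_q"):
        v = getattr(config, name)
        if not 0.0 < v <= 1.0:
            problems.append(f"{name} must be in (0, 1]")
    if config.lfc < 0:
        problems.append("lfc must be >= 0")
    if not 0.0 <= config.expressed_fraction < 1.0:
        problems.append("expressed_fraction must be in [0, 1)")
    if config.sota_clusters < 1 or config.deg_groups < 1:
        problems.append("cluster counts must be >= 1")
    if config.seed < 0:
        problems.append("seed must be non-negative")
    return problems


def _write_tsv(df: pd.DataFrame, path: Path, *, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index=index)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict[str, Any]:
    """Execute every stage in dependency order; returns the run manifest."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = Path(outdir)
    for sub in ("truth", "tags", "counts", "comparisons", "clustering",
                "enrichment", "segments"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    # --- stage: simulate -------------------------------------------------
    reference = simulate.generate_reference(
        config.n_genes,
        config.length_range,
        no_catg_fraction=config.no_catg_fraction,
        paralog_fraction=config.paralog_fraction,
        paralog_divergence=config.paralog_divergence,
        seed=config.seed,
    )
    simulate.write_reference_fasta(reference, out / "reference.fasta")
    design = simulate.generate_design(config.lines, config.stages, config.parent)
    pd.DataFrame(design.libraries, columns=["library_id", "line", "stage"]).to_csv(
        out / "design.tsv", sep="\t", index=False
    )
    truth = simulate.simulate_true_expression(
        reference,
        design,
        de_fraction=config.de_fraction,
        log2fc_magnitude=config.log2fc_magnitude,
        seed=config.seed + 1,
    )
    _write_tsv(truth.abundance, out / "truth" / "abundance.tsv")
    _write_tsv(truth.de_log2fc, out / "truth" / "de_log2fc.tsv")

    raw_libraries: dict[str, dict[str, int]] = {}
    for lib_id in design.library_ids:
        raw = simulate.simulate_tag_library(
            reference,
            truth,
            lib_id,
            depth=config.depth,
            error_rate=config.error_rate,
            short_frac=config.short_frac,
            singleton_boost=config.singleton_boost,
            seed=config.seed,
        )
        raw_libraries[lib_id] = raw
        simulate.write_tag_library(raw, out / "tags" / f"{lib_id}.tags.tsv")

    # --- stage: tag database + clean/map ---------------------------------
    db = tags.build_tag_database(reference)
    db_rows = [
        {"tag": tag, "gene_id": g, "position": pos}
        for tag in sorted(db.entries)
        for g, pos in sorted(db.entries[tag])
    ]
    pd.DataFrame(db_rows).to_csv(out / "tag_db.tsv", sep="\t", index=False)

    libraries: dict[str, tags.TagLibrary] = {}
    stats_rows = []
    for lib_id in design.library_ids:
        lib = tags.process_library(lib_id, raw_libraries[lib_id], db)
        libraries[lib_id] = lib
        counts = pd.Series(lib.mapped_unambiguous, name="count").sort_index()
        counts.index.name = "gene_id"
        counts.to_csv(out / "counts" / f"{lib_id}.counts.tsv", sep="\t")
        stats = {"library_id": lib_id, "raw_total": lib.raw_total,
                 "clean_total": lib.clean_total, **lib.stats}
        stats_rows.append(stats)
        pd.DataFrame([stats]).to_csv(
            out / "counts" / f"{lib_id}.stats.tsv", sep="\t", index=False,
            float_format=_FLOAT_FMT,
        )
    pd.DataFrame(stats_rows).to_csv(
        out / "library_stats.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )

    # --- stage: quantify + compare ----------------------------------------
    tpm = diffexpr.expression_matrix(list(libraries.values()))
    _write_tsv(tpm, out / "tpm_matrix.tsv")

    comparisons = diffexpr.run_all_comparisons(
        design, libraries, fdr_threshold=config.fdr, lfc_threshold=config.lfc
    )
    summary_rows = []
    for (line, stage), table in comparisons.items():
        _write_tsv(table, out / "comparisons" / f"{line}_{stage}.tsv")
        summary_rows.append(
            {
                "line": line,
                "stage": stage,
                "n_up": int((table["call"] == "up").sum()),
                "n_down": int((table["call"] == "down").sum()),
                "n_tested": len(table),
            }
        )
    deg_summary = pd.DataFrame(summary_rows)
    deg_summary.to_csv(out / "deg_summary.tsv", sep="\t", index=False)

    # --- stage: clustering -------------------------------------------------
    profiles = clustering.filter_expressed(tpm, config.expressed_fraction)
    pcc = clustering.pcc_matrix(profiles)
    _write_tsv(pcc, out / "clustering" / "pcc_matrix.tsv")
    sota = clustering.sota_cluster(
        profiles,
        clustering.SotaParams(max_clusters=config.sota_clusters, seed=config.seed),
    )
    sota.assignments.rename_axis("gene_id").to_csv(
        out / "clustering" / "sota_assignments.tsv", sep="\t"
    )
    _write_tsv(sota.centroids.rename_axis("cluster"),
               out / "clustering" / "sota_centroids.tsv")

    all_degs = sorted(
        set().union(*(diffexpr.deg_sets(t) for t in comparisons.values()))
    )
    deg_in_profiles = [g for g in all_degs if g in profiles.index]
    if len(deg_in_profiles) >= config.deg_groups:
        groups = clustering.hierarchical_cluster(
            profiles.loc[deg_in_profiles], config.deg_groups
        )
        groups.rename_axis("gene_id").to_csv(
            out / "clustering" / "deg_groups.tsv", sep="\t"
        )

    # --- stage: enrichment --------------------------------------------------
    gene_ids = [t.gene_id for t in reference]
    gene2terms, dag_edges, pathways = simulate.generate_annotations(
        gene_ids, seed=config.seed + 2
    )
    gene2terms = enrichment.propagate_annotations(gene2terms, dag_edges)
    background = set(tpm.index[(tpm > 0).any(axis=1)])

    common_by_stage = {}
    for stage in design.stages:
        per_line = {
            line: comparisons[(line, stage)]
            for line in design.lines
            if line != design.parent
        }
        common = diffexpr.common_degs(per_line, "intersection")
        common_by_stage[stage] = common
        study = common & background
        if study:
            table = enrichment.term_enrichment(
                study, background, gene2terms, q_cutoff=config.enrich_q
            )
            _write_tsv(table, out / "enrichment" / f"go_common_{stage}.tsv",
                       index=False)
    study_all = set(all_degs) & background
    if study_all:
        pw = enrichment.pathway_enrichment(
            study_all, background, pathways, q_cutoff=config.enrich_q
        )
        _write_tsv(pw, out / "enrichment" / "pathways_all_degs.tsv", index=False)

    # --- stage: segments ------------------------------------------------------
    loci, seg_table = simulate.generate_loci_and_segments(
        gene_ids, design, segment_genes=config.segment_genes,
        seed=config.seed + 3,
    )
    loci.to_csv(out / "segments" / "gene_loci.tsv", sep="\t", index=False)
    seg_table.to_csv(out / "segments" / "segments.tsv", sep="\t", index=False)
    for _, row in seg_table.iterrows():
        seg = segments.SegmentDefinition(
            row["line_id"], row["chrom"], int(row["start"]), int(row["end"])
        )
        seg_genes = segments.genes_in_segment(seg, loci)
        per_stage = {
            stage: comparisons[(seg.line_id, stage)] for stage in design.stages
        }
        cand = segments.segment_deg_candidates(seg_genes, per_stage, "up")
        cand.to_csv(out / "segments" / f"{seg.line_id}.candidates.tsv", sep="\t")

    # --- manifest ---------------------------------------------------------------
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_libraries": design.n_libraries,
        "n_comparisons": design.n_comparisons,
        "n_genes": config.n_genes,
        "common_degs_per_stage": {
            stage: len(genes) for stage, genes in common_by_stage.items()
        },
        "outputs": sorted(
            str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()
            and p.name != "manifest.json"
        ),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
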
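"""Generate the synthetic study: reference, design, truth, raw tag libraries.

Emulates the study layout — five introgression lines plus the recurrent
parent TM-1, four fiber-elongation stages, one DGE library each — at desk
scale (2,000 genes, 10^5 raw tags/library; the real study used 37,505
genes and 7.0–8.7 M tags/library). Also writes the synthetic annotation
maps, gene loci and introgressed-segment definitions used downstream.

Usage: python analysis/01_simulate.py [--seed 1] [--n-genes 2000]
       [--depth 100000] [--outdir results/run]
"""

import argparse
from pathlib import Path

import pandas as pd

from cottondge import simulate as sim


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-genes", type=int, default=2000)
    ap.add_argument("--depth", type=int, default=100_000)
    ap.add_argument("--outdir", default="results/run")
    args = ap.parse_args()

    out = Path(args.outdir)
    (out / "tags").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)

    reference = sim.generate_reference(args.n_genes, seed=args.seed)
    sim.write_reference_fasta(reference, out / "reference.fasta")
    n_tagless = sum(1 for t in reference if "CATG" not in t.sequence)
    print(f"reference: {len(reference)} genes, {n_tagless} without a CATG anchor")

    design = sim.generate_design()
    pd.DataFrame(design.libraries, columns=["library_id", "line", "stage"]).to_csv(
        out / "design.tsv", sep="\t", index=False
    )
    print(f"design: {design.n_libraries} libraries "
          f"({len(design.lines)} lines x {len(design.stages)} stages), "
          f"{design.n_comparisons} parent-vs-line comparisons implied")

    truth = sim.simulate_true_expression(reference, design, seed=args.seed + 1)
    truth.abundance.to_csv(out / "truth" / "abundance.tsv", sep="\t",
                           float_format="%.10g")
    truth.de_log2fc.to_csv(out / "truth" / "de_log2fc.tsv", sep="\t",
                           float_format="%.10g")
    n_de = int((truth.de_log2fc != 0).any(axis=1).sum())
    print(f"truth: {n_de} genes carry a planted fold change in >=1 library")

    for lib_id in design.library_ids:
        raw = sim.simulate_tag_library(
            reference, truth, lib_id, depth=args.depth, seed=args.seed
        )
        sim.write_tag_library(raw, out / "tags" / f"{lib_id}.tags.tsv")
    print(f"tags: {design.n_libraries} libraries x {args.depth} raw tags")

    gene_ids = [t.gene_id for t in reference]
    gene2terms, dag_edges, pathways = sim.generate_annotations(
        gene_ids, seed=args.seed + 2
    )
    pd.DataFrame(
        [(g, t) for g, ts in sorted(gene2terms.items()) for t in sorted(ts)],
        columns=["gene_id", "term_id"],
    ).to_csv(out / "gene2term.tsv", sep="\t", index=False)
    pd.DataFrame(dag_edges, columns=["child", "parent"]).to_csv(
        out / "term_dag.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [(p, g) for p, gs in sorted(pathways.items()) for g in sorted(gs)],
        columns=["pathway_id", "gene_id"],
    ).to_csv(out / "pathways.tsv", sep="\t", index=False)

    loci, segments = sim.generate_loci_and_segments(
        gene_ids, design, seed=args.seed + 3
    )
    loci.to_csv(out / "gene_loci.tsv", sep="\t", index=False)
    segments.to_csv(out / "segments.tsv", sep="\t", index=False)
    print(f"annotations: {len(gene2terms)} annotated genes, "
          f"{len(pathways)} pathways; {len(segments)} introgressed segments")


if __name__ == "__main__":
    main()
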
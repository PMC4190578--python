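"""Mine upregulated DEGs inside each line's introgressed chromosome segment.

For every introgression line, genes overlapping its donor segment are
intersected with that line's upregulated DEG calls across stages; the
candidate sets are then functionally characterized by term enrichment
against the expressed background.

Usage: python analysis/06_segment_mining.py [--rundir results/run]
"""

import argparse
from pathlib import Path

import pandas as pd

from cottondge import segments as sg

import importlib.util as _ilu

_spec = _ilu.spec_from_file_location(
    "enrich_driver", Path(__file__).parent / "05_enrichment.py"
)
_enrich_driver = _ilu.module_from_spec(_spec)
_spec.loader.exec_module(_enrich_driver)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--rundir", default="results/run")
    args = ap.parse_args()
    run = Path(args.rundir)
    (run / "segments").mkdir(exist_ok=True)

    loci = pd.read_csv(run / "gene_loci.tsv", sep="\t")
    seg_table = pd.read_csv(run / "segments.tsv", sep="\t")
    gene2terms, _ = _enrich_driver._load_annotations(run)
    tpm = pd.read_csv(run / "tpm_matrix.tsv", sep="\t", index_col=0)
    background = set(tpm.index[(tpm > 0).any(axis=1)])

    design = pd.read_csv(run / "design.tsv", sep="\t")
    stages = list(dict.fromkeys(design["stage"]))

    for row in seg_table.itertuples():
        seg = sg.SegmentDefinition(row.line_id, row.chrom,
                                   int(row.start), int(row.end))
        seg_genes = sg.genes_in_segment(seg, loci)
        deg_tables = {
            stage: pd.read_csv(
                run / "comparisons" / f"{seg.line_id}_{stage}.tsv",
                sep="\t", index_col=0,
            )
            for stage in stages
        }
        cand = sg.segment_deg_candidates(seg_genes, deg_tables, "up")
        cand.to_csv(run / "segments" / f"{seg.line_id}.candidates.tsv", sep="\t")
        msg = (f"{seg.line_id}: {len(seg_genes)} genes in segment "
               f"{seg.chrom}:{seg.start}-{seg.end}, "
               f"{len(cand)} upregulated candidates")
        if len(cand) >= 2:
            enr = sg.segment_candidate_enrichment(
                set(cand.index), background, gene2terms
            )
            enr.to_csv(run / "segments" / f"{seg.line_id}.enrichment.tsv",
                       sep="\t", index=False, float_format="%.10g")
            if not enr.empty:
                msg += (f"; top term {enr.loc[0, 'term_id']} "
                        f"(q={enr.loc[0, 'q']:.3g})")
        print(msg)


if __name__ == "__main__":
    main()
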
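"""Build the CATG tag database, clean every raw library and map to genes.

Reports the library-level statistics the tag-profiling literature tracks:
raw/clean totals, unambiguous mapping rate (about half of clean tags, as
in real DGE data where paralogous tags are excluded), and the fraction of
reference genes hit.

Usage: python analysis/02_map_tags.py [--rundir results/run]
"""

import argparse
from pathlib import Path

import pandas as pd

from cottondge import io as cio
from cottondge.tags import build_tag_database, process_library


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--rundir", default="results/run")
    args = ap.parse_args()
    run = Path(args.rundir)
    (run / "counts").mkdir(exist_ok=True)

    reference = cio.read_reference_fasta(run / "reference.fasta")
    db = build_tag_database(reference)
    print(f"tag database: {len(db.entries)} distinct tags, "
          f"{len(db.ambiguous_tags)} ambiguous (multi-gene), "
          f"{len(db.tagless_genes)} tagless genes")

    rows = []
    for tag_file in sorted((run / "tags").glob("*.tags.tsv")):
        lib_id = tag_file.name.removesuffix(".tags.tsv")
        lib = process_library(lib_id, cio.read_tag_library(tag_file), db)
        counts = pd.Series(lib.mapped_unambiguous, name="count").sort_index()
        counts.index.name = "gene_id"
        counts.to_csv(run / "counts" / f"{lib_id}.counts.tsv", sep="\t")
        rows.append({"library_id": lib_id, "raw_total": lib.raw_total,
                     "clean_total": lib.clean_total, **lib.stats})
    stats = pd.DataFrame(rows)
    stats.to_csv(run / "library_stats.tsv", sep="\t", index=False,
                 float_format="%.10g")
    print(f"mapped {len(rows)} libraries: "
          f"unambiguous mapping {100 * stats.pct_unambiguous_mapped.mean():.1f}% "
          f"of clean tags (range {100 * stats.pct_unambiguous_mapped.min():.1f}-"
          f"{100 * stats.pct_unambiguous_mapped.max():.1f}%), "
          f"{100 * stats.pct_genes_hit.mean():.1f}% of genes hit")


if __name__ == "__main__":
    main()
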
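"""TPM quantification and the 20 parent-vs-line exact-test comparisons.

Each introgression line is compared with TM-1 at the same stage using the
Audic–Claverie test; DEGs are genes with BH FDR <= 0.001 and
|log2 ratio| >= 1. Also derives the common DEGs shared by all lines at
each stage and the DEGs down only in the shorter-fiber line.

Usage: python analysis/03_differential_expression.py [--rundir results/run]
"""

import argparse
from pathlib import Path

import pandas as pd

from cottondge import diffexpr as de
from cottondge import io as cio
from cottondge import simulate as sim
from cottondge.tags import TagLibrary


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--rundir", default="results/run")
    ap.add_argument("--fdr", type=float, default=1e-3)
    ap.add_argument("--lfc", type=float, default=1.0)
    args = ap.parse_args()
    run = Path(args.rundir)
    (run / "comparisons").mkdir(exist_ok=True)

    design_df = cio.read_design(run / "design.tsv")
    lines = list(dict.fromkeys(design_df["line"]))
    stages = list(dict.fromkeys(design_df["stage"]))
    design = sim.generate_design(lines, stages, sim.DEFAULT_PARENT)

    libraries = {}
    for lib_id in design.library_ids:
        counts = cio.read_gene_counts(run / "counts" / f"{lib_id}.counts.tsv")
        total = sum(counts.values())
        libraries[lib_id] = TagLibrary(lib_id, total, {}, total, counts)

    tpm = de.expression_matrix(list(libraries.values()))
    tpm.to_csv(run / "tpm_matrix.tsv", sep="\t", float_format="%.10g")

    comparisons = de.run_all_comparisons(
        design, libraries, fdr_threshold=args.fdr, lfc_threshold=args.lfc
    )
    summary = []
    for (line, stage), table in comparisons.items():
        table.to_csv(run / "comparisons" / f"{line}_{stage}.tsv", sep="\t",
                     float_format="%.10g")
        summary.append({"line": line, "stage": stage,
                        "n_up": int((table["call"] == "up").sum()),
                        "n_down": int((table["call"] == "down").sum()),
                        "n_tested": len(table)})
    summary = pd.DataFrame(summary)
    summary.to_csv(run / "deg_summary.tsv", sep="\t", index=False)
    total_deg = int((summary.n_up + summary.n_down).sum())
    print(f"{len(comparisons)} comparisons; DEGs per comparison "
          f"{(summary.n_up + summary.n_down).min()}-"
          f"{(summary.n_up + summary.n_down).max()} "
          f"({total_deg} calls in total)")

    common_rows = []
    for stage in design.stages:
        per_line = {ln: comparisons[(ln, stage)]
                    for ln in design.lines if ln != design.parent}
        common = de.common_degs(per_line, "intersection")
        down_only = de.common_degs(per_line, "down_only_in", line="CSIL-35368")
        common_rows.append({"stage": stage, "n_common": len(common),
                            "n_down_only_35368": len(down_only),
                            "common_genes": ",".join(sorted(common))})
    common_df = pd.DataFrame(common_rows)
    common_df.to_csv(run / "common_degs.tsv", sep="\t", index=False)
    print("common DEGs per stage:",
          dict(zip(common_df.stage, common_df.n_common)))


if __name__ == "__main__":
    main()
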
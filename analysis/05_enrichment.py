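"""Functional term and pathway enrichment of the DEG sets.

Annotations are closed under the term DAG (true-path rule), the background
is all genes expressed in the libraries, and each stage's common DEG set
plus the pooled DEG set are tested with the upper-tail hypergeometric test
(BH-corrected, q <= 0.05). Pathways additionally report the rich factor
(study hits / background pathway size).

Usage: python analysis/05_enrichment.py [--rundir results/run]
"""

import argparse
from pathlib import Path

import pandas as pd

from cottondge import enrichment as en


def _load_annotations(run: Path):
    g2t_df = pd.read_csv(run / "gene2term.tsv", sep="\t")
    gene2terms: dict[str, set[str]] = {}
    for row in g2t_df.itertuples():
        gene2terms.setdefault(row.gene_id, set()).add(row.term_id)
    dag = [tuple(r) for r in
           pd.read_csv(run / "term_dag.tsv", sep="\t").to_numpy()]
    pw_df = pd.read_csv(run / "pathways.tsv", sep="\t")
    pathways: dict[str, set[str]] = {}
    for row in pw_df.itertuples():
        pathways.setdefault(row.pathway_id, set()).add(row.gene_id)
    return en.propagate_annotations(gene2terms, dag), pathways


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--rundir", default="results/run")
    ap.add_argument("--qcut", type=float, default=0.05)
    args = ap.parse_args()
    run = Path(args.rundir)
    (run / "enrichment").mkdir(exist_ok=True)

    gene2terms, pathways = _load_annotations(run)
    tpm = pd.read_csv(run / "tpm_matrix.tsv", sep="\t", index_col=0)
    background = set(tpm.index[(tpm > 0).any(axis=1)])
    print(f"background: {len(background)} expressed genes")

    common = pd.read_csv(run / "common_degs.tsv", sep="\t")
    all_degs: set[str] = set()
    for path in (run / "comparisons").glob("*.tsv"):
        table = pd.read_csv(path, sep="\t", index_col=0)
        all_degs |= set(table.index[table["call"] != "ns"])

    for row in common.itertuples():
        genes = set(str(row.common_genes).split(",")) if row.n_common else set()
        study = genes & background
        if not study:
            print(f"{row.stage}: no common DEGs to test")
            continue
        table = en.term_enrichment(study, background, gene2terms,
                                   q_cutoff=args.qcut)
        table.to_csv(run / "enrichment" / f"go_common_{row.stage}.tsv",
                     sep="\t", index=False, float_format="%.10g")
        n_enr = int(table["enriched"].sum())
        print(f"{row.stage}: {len(study)} common DEGs, "
              f"{n_enr} enriched terms of {len(table)} tested")

    study_all = all_degs & background
    pw_table = en.pathway_enrichment(study_all, background, pathways,
                                     q_cutoff=args.qcut)
    pw_table.to_csv(run / "enrichment" / "pathways_all_degs.tsv", sep="\t",
                    index=False, float_format="%.10g")
    if not pw_table.empty:
        top = pw_table.iloc[0]
        print(f"pathways: top {top.term_id} "
              f"(k={top.k}/K={top.K}, rich factor {top.rich_factor:.2f}, "
              f"q={top.q:.3g}) among {len(pw_table)} tested")


if __name__ == "__main__":
    main()
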
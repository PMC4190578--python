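"""Library correlation and expression clustering.

Genes expressed in more than half of the 24 libraries feed the
library-level Pearson correlation matrix and SOTA clustering of
log2-transformed TPM profiles; DEG profiles are additionally cut into six
expression groups by average-linkage hierarchical clustering (the G1–G6
style grouping).

Usage: python analysis/04_clustering.py [--rundir results/run]
"""

import argparse
from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd

from cottondge import clustering as cl


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--rundir", default="results/run")
    ap.add_argument("--sota-clusters", type=int, default=5)
    ap.add_argument("--deg-groups", type=int, default=6)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    run = Path(args.rundir)
    (run / "clustering").mkdir(exist_ok=True)

    tpm = pd.read_csv(run / "tpm_matrix.tsv", sep="\t", index_col=0)
    profiles = cl.filter_expressed(tpm, 0.5)
    print(f"{len(profiles)} of {len(tpm)} genes expressed in more than half "
          f"of the {tpm.shape[1]} libraries")

    pcc = cl.pcc_matrix(profiles)
    pcc.to_csv(run / "clustering" / "pcc_matrix.tsv", sep="\t",
               float_format="%.10g")
    off_diag = pcc.to_numpy()[~np.eye(len(pcc), dtype=bool)]
    print(f"library PCC range {off_diag.min():.3f}-{off_diag.max():.3f}")

    sota = cl.sota_cluster(
        profiles,
        cl.SotaParams(max_clusters=args.sota_clusters, seed=args.seed),
    )
    sota.assignments.rename_axis("gene_id").to_csv(
        run / "clustering" / "sota_assignments.tsv", sep="\t"
    )
    sota.centroids.rename_axis("cluster").to_csv(
        run / "clustering" / "sota_centroids.tsv", sep="\t", float_format="%.10g"
    )
    sizes = Counter(sota.assignments)
    print(f"SOTA: {sota.n_clusters} clusters, sizes "
          f"{sorted(sizes.values(), reverse=True)}; "
          f"resource per cycle {[round(r, 4) for r in sota.resource_history]}")

    degs = set()
    for path in (run / "comparisons").glob("*.tsv"):
        table = pd.read_csv(path, sep="\t", index_col=0)
        degs |= set(table.index[table["call"] != "ns"])
    deg_profiles = profiles.loc[sorted(degs & set(profiles.index))]
    if len(deg_profiles) >= args.deg_groups:
        groups = cl.hierarchical_cluster(deg_profiles, args.deg_groups)
        groups.rename_axis("gene_id").to_csv(
            run / "clustering" / "deg_groups.tsv", sep="\t"
        )
        print(f"DEG groups (G1-G{args.deg_groups}): sizes "
              f"{sorted(Counter(groups).values(), reverse=True)}")
    else:
        print(f"only {len(deg_profiles)} well-expressed DEGs; "
              f"skipping the {args.deg_groups}-group cut")


if __name__ == "__main__":
    main()
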
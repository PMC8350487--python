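"""Node-wise GLM of weighted degree on divergent thinking with Monte-Carlo
cluster correction, then projection to regional means.

For each flavor (local / distributed) the per-node DT slope, t statistic
and p-value are written together with the surviving clusters; the t map is
summarized into region means for the transcriptome screen.

Usage: python analysis/03_wd_dt_association.py [--outdir results] [--iters 10000]
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from connectogene import SyntheticSpec, cluster_correct, fit_glm, parcel_mean
from connectogene.connectivity_core import read_matrix_tsv


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--iters", type=int, default=10_000)
    args = ap.parse_args()
    out = args.outdir

    spec = SyntheticSpec.from_yaml(out / "spec.yaml")
    pheno = pd.read_csv(out / "pheno.csv")
    base = read_matrix_tsv(out / "base_network.tsv")
    labels = pd.read_csv(out / "node_labels.tsv", sep="\t")["region_id"].to_numpy()
    effect = set(pd.read_csv(out / "effect_nodes.csv")["node"].tolist())
    adjacency = (base.r > 0).astype(int)

    for flavor in ("local", "distributed"):
        wd = pd.read_csv(out / f"wd_{flavor}.tsv", sep="\t", index_col=0)
        amap = fit_glm(wd, pheno)
        amap = cluster_correct(
            amap, adjacency, pheno, n_iter=args.iters, seed=spec.seed + 1
        )
        table = pd.DataFrame(
            {"node": amap.node_ids, "beta": amap.beta, "t": amap.t_stat, "p": amap.p}
        )
        table.to_csv(out / f"assoc_{flavor}.tsv", sep="\t", index=False)
        regional = parcel_mean(amap.t_stat, labels)
        regional.as_series().rename_axis("region_id").to_csv(
            out / f"regional_t_{flavor}.tsv", sep="\t"
        )
        print(f"-- {flavor} connectivity vs DT --")
        print(f"   cluster extent threshold: {amap.cluster_extent_threshold} nodes")
        for c, s in zip(amap.significant_clusters, amap.cluster_signs):
            overlap = len(c & effect)
            print(
                f"   cluster (sign {s:+d}): {len(c)} nodes, {overlap} on planted effect nodes, "
                f"mean beta {amap.beta[sorted(c)].mean():+.2f}"
            )
        if not amap.significant_clusters:
            print("   no cluster survives correction")
    print(f"wrote assoc_*.tsv and regional_t_*.tsv to {out}/")


if __name__ == "__main__":
    main()
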
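"""Simulate the study cohort: modular connectivity backbone, resting time
series with a planted negative WD-DT effect, phenotypes, and node-to-region
labels.  Writes the study spec and the small cohort-level tables; later
stages regenerate the (deterministic) time series from the spec rather than
storing them.

Usage: python analysis/01_simulate_cohort.py [--seed 7] [--outdir results]
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from connectogene import SyntheticSpec, generate_cohort
from connectogene.connectivity_core import write_matrix_tsv


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)

    spec = SyntheticSpec(seed=args.seed)
    series, pheno, base, effect = generate_cohort(spec)

    spec.to_yaml(out / "spec.yaml")
    pheno.to_csv(out / "pheno.csv", index=False)
    write_matrix_tsv(base, out / "base_network.tsv")
    labels = pd.DataFrame(
        {
            "node_id": [f"n{j}" for j in range(spec.n_nodes)],
            "region_id": np.arange(spec.n_nodes) % spec.n_regions + 1,
        }
    )
    labels.to_csv(out / "node_labels.tsv", sep="\t", index=False)
    pd.Series(effect, name="node").to_csv(out / "effect_nodes.csv", index=False)

    member = spec.membership()
    print(f"cohort: {spec.n_subjects} subjects x {spec.n_timepoints} timepoints x {spec.n_nodes} nodes")
    print(f"modules: {spec.n_modules} (sizes {np.bincount(member).tolist()})")
    print(f"planted effect: size {spec.effect_size} on {len(effect)} nodes of module 0")
    print(f"wrote spec, phenotypes, base network and labels to {out}/")


if __name__ == "__main__":
    main()
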
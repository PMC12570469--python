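#!/usr/bin/env python
"""Richness, rarefaction, richness contrasts, and Bray-Curtis/NMDS/PERMANOVA.

Reads the occurrence and TPM matrices from results/community/ and writes
the diversity tables under results/diversity/.
"""
import argparse
from pathlib import Path

import pandas as pd

from virotu import diversity, io


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--in-dir", type=Path, default=Path("results"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/diversity"))
    args = ap.parse_args()
    out = io.ensure_dir(args.out_dir)

    occ = io.read_occurrence(args.in_dir / "community" / "occurrence.csv")
    tpm = io.read_abundance(args.in_dir / "community" / "abundance_tpm.csv")
    design = io.read_design(args.in_dir / "simulated" / "design.csv")

    rich = diversity.richness(occ, design)
    rich.to_csv(out / "richness.csv", index=False)
    cell_means = rich.groupby(["phenotype", "compartment"])["richness"].mean()
    print("mean richness per cell:")
    print(cell_means.round(1).to_string())

    curve = diversity.rarefaction(occ, n_permutations=100, seed=args.seed)
    curve.to_frame().to_csv(out / "rarefaction.csv", index=False)
    print(f"rarefaction: {curve.mean_richness[-1]:.0f} vOTUs at {curve.k[-1]} samples "
          f"(mean over {curve.n_permutations} orderings)")

    mw = diversity.pairwise_mann_whitney(rich)
    mw.to_csv(out / "mann_whitney.csv", index=False)
    sig = mw[mw["p_value"] < 0.05]
    print(f"{len(sig)}/{len(mw)} pairwise richness contrasts significant at 0.05")

    bc = diversity.bray_curtis(tpm)
    io.write_matrix(out / "bray_curtis.csv", bc)
    res = diversity.nmds(bc, k=2, seed=args.seed)
    io.write_matrix(out / "nmds_coordinates.csv", res.coordinates)
    print(f"NMDS stress: {res.stress:.3f} (converged: {res.converged})")

    labels = design.set_index("sample_id")
    rows = []
    for factor in ("phenotype", "compartment"):
        pr = diversity.permanova(bc, labels[factor], n_permutations=999, seed=args.seed)
        rows.append({"factor": factor, "pseudo_F": pr.pseudo_f, "R2": pr.r_squared,
                     "p_value": pr.p_value})
        print(f"PERMANOVA {factor}: F={pr.pseudo_f:.2f} R2={pr.r_squared:.3f} "
              f"p={pr.p_value:.4g}")
    pd.DataFrame(rows).to_csv(out / "permanova.csv", index=False)


if __name__ == "__main__":
    main()
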
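#!/usr/bin/env python
"""Generate the synthetic study inputs: 24-sample design, coverage, annotations.

Writes the full set of pipeline inputs (and the generator's ground-truth
occupancy, for later validation) under results/simulated/.
"""
import argparse
from pathlib import Path

import pandas as pd

from virotu import io, simulate


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results/simulated"))
    args = ap.parse_args()
    out = io.ensure_dir(args.out_dir)

    design = simulate.generate_design(n_replicates=4, seed=args.seed)
    params = simulate.SimulationParams(seed=args.seed)
    cov, truth = simulate.generate_coverage(design, params)
    io.write_design(out / "design.csv", design)
    io.write_coverage(out / "coverage.csv", cov)
    io.write_occurrence(out / "truth_occupancy.csv", truth)

    genes = simulate.generate_gene_tables(n_contigs=60, seed=args.seed)
    genes.to_csv(out / "genes.csv", index=False)

    orders = [
        ("Pseudomonadota", "Chromatiales"),
        ("Thermodesulfobacteriota", "Desulfobacterales"),
        ("Pseudomonadota", "Burkholderiales"),
        ("Actinomycetota", "Mycobacteriales"),
        ("Bacillota", "Bacillales"),
    ]
    hosts = simulate.generate_host_table(list(truth.index), orders, p_assigned=0.083,
                                         seed=args.seed)
    hosts.to_csv(out / "hosts.csv", index=False)
    pd.DataFrame(
        {
            "order": ["Chromatiales", "Desulfobacterales", "Burkholderiales"],
            "function": ["sulfur-oxidizing", "sulfate-reducing", "iron-oxidizing"],
        }
    ).to_csv(out / "functions.csv", index=False)

    n_occ = int(truth.to_numpy().sum())
    print(f"simulated {params.n_votus} vOTUs x {len(design)} samples "
          f"({n_occ} true occurrences, {len(hosts)} host assignments) -> {out}")


if __name__ == "__main__":
    main()
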
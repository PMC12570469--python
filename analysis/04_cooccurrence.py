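#!/usr/bin/env python
"""Sharing classes of multi-sample vOTUs vs the richness-conserving null.

Classifies every vOTU found in two or more samples by the phenotypes and
compartments it spans, compares observed class counts to the
randomization null (each sample redrawn at its observed richness from
the full catalog), and reports the chi-square goodness-of-fit tests.
Writes tables under results/cooccurrence/.
"""
import argparse
from pathlib import Path

import pandas as pd

from virotu import cooccurrence, io


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-replicates", type=int, default=1000)
    ap.add_argument("--in-dir", type=Path, default=Path("results"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/cooccurrence"))
    args = ap.parse_args()
    out = io.ensure_dir(args.out_dir)

    occ = io.read_occurrence(args.in_dir / "community" / "occurrence.csv")
    design = io.read_design(args.in_dir / "simulated" / "design.csv")

    multi = cooccurrence.multi_sample_filter(occ)
    print(f"{len(multi)} of {len(occ)} vOTUs occur in >= 2 samples "
          f"({100 * (len(occ) - len(multi)) / len(occ):.0f}% singletons)")

    rows = []
    for classification in cooccurrence.CLASSIFICATIONS:
        res = cooccurrence.null_model(
            occ, design, classification,
            n_replicates=args.n_replicates, seed=args.seed,
        )
        table = pd.DataFrame(
            {
                "class": res.observed.index,
                "observed": res.observed.to_numpy(),
                "expected": res.expected_counts.round(2).to_numpy(),
            }
        )
        table.to_csv(out / f"sharing_{classification}.csv", index=False)
        rows.append({"classification": classification, "chi2": res.chi2,
                     "df": res.df, "p_value": res.p_value})
        print(f"\n{classification} sharing (observed vs null expectation, "
              f"chi2={res.chi2:.1f}, p={res.p_value:.3g}):")
        print(table.to_string(index=False))
    pd.DataFrame(rows).to_csv(out / "tests.csv", index=False)


if __name__ == "__main__":
    main()
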
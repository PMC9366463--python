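#!/usr/bin/env python
"""Balanced 16-taxon tip-swap schemes: graded incongruence, per-branch bias.

Each scheme mixes 50% species-topology loci with 50% copies of a single
alternative topology in which 2, 4, 6 or 8 terminals are reciprocally
swapped across the two halves of the tree.  Deeper branches subtend clades
whose *proportion* of swapped terminals grows with the swap size, and their
time estimates are increasingly underestimated.

Writes results/swap_per_branch.tsv (per-branch percent errors by scheme).
"""

import argparse
from pathlib import Path

import pandas as pd

from discordate.experiments import ExperimentConfig, run_experiment

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--n-loci", type=int, default=400)
    parser.add_argument("--seq-length", type=int, default=800)
    parser.add_argument("--seed", type=int, default=2)
    args = parser.parse_args()
    RESULTS.mkdir(exist_ok=True)

    frames = []
    for k in (2, 4, 6, 8):
        scheme = f"balanced16_swap{k}"
        out = run_experiment(
            ExperimentConfig(
                scheme=scheme,
                methods=("concat",),
                fractions=(0.5,),
                n_loci=args.n_loci,
                seq_length=args.seq_length,
                seed=args.seed,
            )
        )
        pb = out["per_branch"].assign(scheme=scheme)
        frames.append(
            pb[["scheme", "clade", "branch_class", "true_t", "estimate",
                "percent_error", "percent_incongruent"]]
        )
        print(f"{scheme}: done")
    table = pd.concat(frames, ignore_index=True).round(3)
    table.to_csv(RESULTS / "swap_per_branch.tsv", sep="\t", index=False)

    # the two deepest (root-adjacent) branches, by scheme
    deep = table[table["clade"].str.count(",") == 7]
    print("\nDeep-branch (8-taxon clade) time error by swap size (percent):")
    print(
        deep.groupby("scheme")["percent_error"].mean().round(1).to_string()
    )
    print(
        "\nLarger swaps change a larger share of each half's terminals, and "
        "the deep branches' times are underestimated more strongly."
    )


if __name__ == "__main__":
    main()
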
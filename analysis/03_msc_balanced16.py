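#!/usr/bin/env python
"""Balanced 16-taxon multispecies-coalescent experiment, replicated.

Simulates gene trees under the coalescent (Ne = 0.12, every species branch
0.2 time units; ~87% of gene trees congruent per internal branch), then
estimates branch times three ways per replicate: all loci concatenated,
only fully congruent loci concatenated, and the congruent-branch
(equivalent-branch averaging) method.  Also bins per-branch errors of the
concatenated analysis by per-branch incongruence (5% bins).

Writes:
    results/msc16_summary.tsv     - class means by method and replicate
    results/msc16_class_means.tsv - replicate-averaged class means
    results/msc16_curve.tsv       - error vs incongruence bin
"""

import argparse
from pathlib import Path

from discordate.experiments import ExperimentConfig, run_experiment

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--replicates", type=int, default=4,
                        help="replicated experiments (50 in the full design)")
    parser.add_argument("--n-loci", type=int, default=400)
    parser.add_argument("--seq-length", type=int, default=800)
    parser.add_argument("--seed", type=int, default=3)
    args = parser.parse_args()
    RESULTS.mkdir(exist_ok=True)

    config = ExperimentConfig(
        scheme="balanced16",
        methods=("concat", "congruent_loci", "congruent_branches"),
        thresholds=(0,),
        n_loci=args.n_loci,
        seq_length=args.seq_length,
        n_replicates=args.replicates,
        seed=args.seed,
    )
    out = run_experiment(config, out_dir=RESULTS / "msc16")
    summary = out["summary"]
    summary.to_csv(RESULTS / "msc16_summary.tsv", sep="\t", index=False)

    means = (
        summary.groupby(["method", "parameter", "branch_class"])
        ["mean_percent_error"].mean().round(2).reset_index()
    )
    means.to_csv(RESULTS / "msc16_class_means.tsv", sep="\t", index=False)
    print("Replicate-averaged percent errors:")
    print(means.to_string(index=False))

    curve = out["curve"].round(2)
    curve.to_csv(RESULTS / "msc16_curve.tsv", sep="\t", index=False)
    print("\nConcatenation error vs per-branch incongruence (5% bins):")
    print(curve.to_string(index=False))
    print(
        "\nTerminal branches (0% incongruence bin) are overestimated — gene "
        "divergences predate species divergences under the coalescent — "
        "while higher-incongruence branches are increasingly underestimated."
    )


if __name__ == "__main__":
    main()
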
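#!/usr/bin/env python
"""Four-taxon multispecies-coalescent design: method comparison.

All species branches last 0.2 time units (root 0.4), Ne = 0.12, so ~12.6%
of gene trees lack each internal clade and every gene divergence predates
its species divergence.  Compares concatenation, congruent-locus filtering
and congruent-branch averaging under the free-rate strict clock with the
root fixed to the true species root age.

Writes results/msc4_methods.tsv.
"""

import argparse
from pathlib import Path

from discordate.experiments import ExperimentConfig, run_experiment

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--replicates", type=int, default=3)
    parser.add_argument("--n-loci", type=int, default=400)
    parser.add_argument("--seq-length", type=int, default=800)
    parser.add_argument("--seed", type=int, default=4)
    args = parser.parse_args()
    RESULTS.mkdir(exist_ok=True)

    config = ExperimentConfig(
        scheme="four_taxon_msc",
        methods=("concat", "congruent_loci", "congruent_branches"),
        thresholds=(0,),
        n_loci=args.n_loci,
        seq_length=args.seq_length,
        n_replicates=args.replicates,
        seed=args.seed,
    )
    out = run_experiment(config)
    summary = out["summary"]
    means = (
        summary[summary["parameter"] == "t"]
        .groupby(["method", "branch_class"])["mean_percent_error"]
        .mean().round(2).unstack()
    )
    means.to_csv(RESULTS / "msc4_methods.tsv", sep="\t")
    print("Replicate-averaged percent errors (t):")
    print(means.to_string())
    print(
        "\nEven after keeping only topologically congruent loci, coalescent "
        "time inflation (gene divergences older than species divergences) "
        "leaves internal branches underestimated; full removal would require "
        "modeling the coalescent itself, which is outside this package."
    )


if __name__ == "__main__":
    main()
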
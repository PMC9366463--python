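"""Replicated experiment driver and percentage-error summaries.

An experiment is: simulate gene trees and alignments for a named scheme,
apply one or more estimation strategies, and summarize signed percentage
errors ``100 * (estimate - truth) / truth`` per branch, per branch class
(internal vs terminal), and — for chronogram-producing methods — per node
age, with nodes classed by whether they subtend internal or only terminal
branches.  Multispecies-coalescent schemes are replicated (fresh gene trees
and sequences per replicate); fixed schemes follow the single-run design.

Everything is deterministic under the master seed: replicate and locus seeds
are spawned from a :class:`numpy.random.SeedSequence`, so reruns produce
bit-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .congruence import branch_incongruence
from .estimators import (
    BranchEstimateTable,
    run_concatenated,
    run_congruent_branches,
    run_congruent_loci,
)
from .inference import ClockConfig, UCLNPrior
from .simulate import (
    FixedSchemeConfig,
    GeneTreeSet,
    MSCConfig,
    SeqSimConfig,
    build_canonical_trees,
    simulate_dataset,
    simulate_fixed_scheme,
    simulate_msc,
)
from .trees import TimeTree

__all__ = [
    "ExperimentConfig",
    "default_clock",
    "percent_error",
    "branch_percent_errors",
    "node_age_errors",
    "incongruence_error_curve",
    "run_experiment",
]

#: schemes whose gene trees come from the multispecies coalescent
MSC_SCHEMES = ("balanced16", "imbalanced16", "four_taxon_msc")
#: MSC schemes are dated with a free clock rate: their gene trees are older
#: than the species-tree root used as the calibration, so fixing the rate to
#: the simulation's true value would add a misspecification bias unrelated to
#: topological incongruence.  Fixed schemes keep the true rate (their gene
#: trees carry the species tree's exact node ages).
FREE_RATE_SCHEMES = MSC_SCHEMES


def default_clock(scheme: str, species_tree: TimeTree, rate: float) -> ClockConfig:
    """The clock configuration each simulation design is analyzed under."""
    if scheme in FREE_RATE_SCHEMES:
        return ClockConfig(mode="strict_free_rate", root_age=species_tree.root_age)
    return ClockConfig(
        mode="strict_fixed_rate", root_age=species_tree.root_age, rate=rate
    )


# ---------------------------------------------------------------------------
# error summaries
# ---------------------------------------------------------------------------


def branch_percent_errors(result: BranchEstimateTable) -> pd.DataFrame:
    """Per-branch signed percentage errors for a method's estimate table."""
    truth_col = {"t": "true_t", "n": "true_n", "r": "true_r"}[result.param]
    df = result.table.copy()
    truth = df[truth_col].to_numpy(dtype=float)
    if np.any(truth == 0):
        raise ZeroDivisionError("zero true value: percentage error undefined")
    df["percent_error"] = 100.0 * (df["estimate"] - truth) / truth
    if result.param == "n" and "merged_root_pair" in df:
        # the merged pair is one identifiable quantity; keep a single row
        merged = df["merged_root_pair"]
        df = pd.concat([df[~merged], df[merged].iloc[:1]], ignore_index=True)
    return df


def node_age_errors(fitted_tree: TimeTree, true_tree: TimeTree) -> pd.DataFrame:
    """Signed percentage errors of internal node ages (root excluded: fixed).

    Nodes are classed ``node_subtending_internal`` when at least one child
    branch is internal, else ``node_subtending_terminal``; for trees whose
    tips sit at age 0 the latter class's error equals the terminal-branch
    duration error.
    """
    rows = []
    for true_node in true_tree.postorder():
        if true_node.is_leaf or true_node.parent is None:
            continue
        est_node = fitted_tree.node(true_node.id)
        cls = (
            "node_subtending_internal"
            if any(not c.is_leaf for c in true_node.children)
            else "node_subtending_terminal"
        )
        rows.append(
            {
                "node_id": true_node.id,
                "node_class": cls,
                "true_age": true_node.age,
                "estimate": est_node.age,
                "percent_error": 100.0
                * (est_node.age - true_node.age)
                / true_node.age,
            }
        )
    return pd.DataFrame(rows)


def percent_error(
    result: BranchEstimateTable, true_tree: TimeTree | None = None
) -> pd.DataFrame:
    """Class-mean percentage errors (unweighted over branches).

    Returns one row per class; when the method produced a chronogram and
    ``true_tree`` is given, node-age classes are appended.
    """
    per_branch = branch_percent_errors(result)
    rows = []
    for cls, grp in per_branch.groupby("branch_class"):
        rows.append(
            {
                "parameter": result.param,
                "branch_class": cls,
                "mean_percent_error": grp["percent_error"].mean(),
                "n_branches": len(grp),
            }
        )
    if result.fitted_tree is not None and true_tree is not None:
        nodes = node_age_errors(result.fitted_tree, true_tree)
        for cls, grp in nodes.groupby("node_class"):
            rows.append(
                {
                    "parameter": "node_age",
                    "branch_class": cls,
                    "mean_percent_error": grp["percent_error"].mean(),
                    "n_branches": len(grp),
                }
            )
    out = pd.DataFrame(rows)
    out.insert(0, "method", result.method)
    return out


def incongruence_error_curve(
    per_branch: pd.DataFrame, bin_width: float = 5.0
) -> pd.DataFrame:
    """Mean percentage error binned by per-branch gene-tree incongruence.

    ``per_branch`` needs ``percent_incongruent`` and ``percent_error``
    columns (possibly pooled across replicates).  Zero-incongruence branches
    (all terminals) land in the first bin.
    """
    df = per_branch.dropna(subset=["percent_error"]).copy()
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    df["bin"] = pd.cut(
        df["percent_incongruent"], bins=edges, right=False, include_lowest=True
    )
    out = (
        df.groupby("bin", observed=True)
        .agg(
            mean_percent_error=("percent_error", "mean"),
            n_branches=("percent_error", "size"),
        )
        .reset_index()
    )
    out["bin_low"] = out["bin"].map(lambda b: b.left).astype(float)
    out["bin_high"] = out["bin"].map(lambda b: b.right).astype(float)
    return out.drop(columns="bin")


# ---------------------------------------------------------------------------
# experiment driver
# ---------------------------------------------------------------------------


@dataclass
class ExperimentConfig:
    """What to simulate and which strategies to run.

    ``fractions`` applies to fixed schemes only (proportion of loci given the
    alternative topology); MSC schemes replicate instead (``n_replicates``).
    """

    scheme: str
    methods: tuple = ("concat",)
    fractions: tuple = (0.5,)
    thresholds: tuple = (0,)
    param: str = "t"
    n_loci: int = 400
    seq_length: int = 800
    rate: float = 0.05
    ne: float = 0.12
    n_replicates: int = 1
    seed: int = 0
    ucln: UCLNPrior | None = None

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        known = {"concat", "congruent_loci", "congruent_branches"}
        unknown = set(self.methods) - known
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}")

    @property
    def design(self) -> str:
        return "msc" if self.scheme in MSC_SCHEMES else "fixed"


def _simulate_replicate(config: ExperimentConfig, fraction, seeds):
    species, alt = build_canonical_trees(config.scheme)
    tree_seed, seq_seed = seeds
    if config.design == "msc":
        genes = simulate_msc(
            MSCConfig(species, Ne=config.ne, n_loci=config.n_loci, seed=tree_seed)
        )
    else:
        genes = simulate_fixed_scheme(
            FixedSchemeConfig(
                species, alt, fraction_incongruent=fraction,
                n_loci=config.n_loci, seed=tree_seed,
            )
        )
    alignments = simulate_dataset(
        genes, SeqSimConfig(config.seq_length, config.rate, seed=seq_seed)
    )
    return species, genes, alignments


def _run_methods(config, species, genes, alignments, clock):
    results = []
    for method in config.methods:
        if method == "concat":
            results.append(
                run_concatenated(
                    genes, alignments, species, clock,
                    param=config.param, prior=config.ucln, sim_rate=config.rate,
                )
            )
        elif method == "congruent_loci":
            for thr in config.thresholds:
                results.append(
                    run_congruent_loci(
                        genes, alignments, species, clock, max_incongruent=thr,
                        param=config.param, prior=config.ucln, sim_rate=config.rate,
                    )
                )
        elif method == "congruent_branches":
            results.append(
                run_congruent_branches(
                    genes, alignments, species, clock,
                    param=config.param, prior=config.ucln, sim_rate=config.rate,
                )
            )
    return results


def run_experiment(config: ExperimentConfig, out_dir=None) -> dict:
    """Simulate -> estimate -> summarize, replicated and seed-deterministic.

    Returns ``{"per_branch": ..., "summary": ..., "curve": ..., "manifest": ...}``;
    when ``out_dir`` is given the tables are also written as TSV plus a JSON
    manifest of the configuration.
    """
    master = np.random.SeedSequence(config.seed)
    fractions = list(config.fractions) if config.design == "fixed" else [None]
    rep_seeds = master.spawn(config.n_replicates * len(fractions) * 2)

    per_branch_rows, summary_rows = [], []
    seed_idx = 0
    for rep in range(config.n_replicates):
        for fraction in fractions:
            seeds = rep_seeds[seed_idx : seed_idx + 2]
            seed_idx += 2
            species, genes, alignments = _simulate_replicate(
                config, fraction, seeds
            )
            clock = default_clock(config.scheme, species, config.rate)
            incong = {
                r.branch_id: r.percent_incongruent
                for r in branch_incongruence(species, genes)
            }
            for result in _run_methods(config, species, genes, alignments, clock):
                pb = branch_percent_errors(result)
                pb.insert(0, "replicate", rep)
                pb.insert(1, "fraction_incongruent", fraction)
                pb["percent_incongruent"] = pb["branch_id"].map(incong)
                per_branch_rows.append(pb)

                sm = percent_error(result, true_tree=species)
                sm.insert(0, "replicate", rep)
                sm.insert(1, "fraction_incongruent", fraction)
                summary_rows.append(sm)

    per_branch = pd.concat(per_branch_rows, ignore_index=True)
    summary = pd.concat(summary_rows, ignore_index=True)
    curve = None
    if config.design == "msc":
        concat_rows = per_branch[per_branch["method"] == "concat"]
        if len(concat_rows):
            curve = incongruence_error_curve(concat_rows)

    manifest = dataclasses.asdict(config)
    manifest["design"] = config.design
    if manifest.get("ucln") is not None:
        manifest["ucln"] = dataclasses.asdict(config.ucln)

    out = {"per_branch": per_branch, "summary": summary, "curve": curve,
           "manifest": manifest}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        per_branch.drop(columns=[], inplace=False).to_csv(
            out_dir / "per_branch.tsv", sep="\t", index=False
        )
        summary.to_csv(out_dir / "summary.tsv", sep="\t", index=False)
        if curve is not None:
            curve.to_csv(out_dir / "curve.tsv", sep="\t", index=False)
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return out
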
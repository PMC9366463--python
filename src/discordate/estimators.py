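"""The three species-tree estimation strategies.

Given a set of loci (gene trees + alignments) and the known species tree:

* :func:`run_concatenated` — join all loci into one alignment and estimate
  the target parameter on the fixed species-tree topology.  This is the
  strategy whose bias under gene-tree discordance the experiments quantify.
* :func:`run_congruent_loci` — first discard loci whose gene trees have more
  than a threshold number of topologically incongruent branches, then
  concatenate the rest ("gene shopping" at the locus level).
* :func:`run_congruent_branches` — date every gene tree individually (root
  fixed to the species-tree root age), then estimate each species branch as
  the arithmetic mean duration over the gene-tree branches *equivalent* to it
  (same descendant and ancestral clades).  No single chronogram is assembled
  from these means: different branches borrow from different gene trees, so
  the implied tip times need not align to the present, and no confidence
  intervals are produced.

Gene-tree topologies are the true simulated ones throughout; gene-tree
estimation error is outside this package's scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import GAP, Alignment
from .congruence import build_equivalence_map, filter_gene_trees
from .inference import (
    ClockConfig,
    MCMCConfig,
    UCLNPrior,
    estimate_n_unrooted,
    estimate_r_fixed_times,
    estimate_t_strict_clock,
    mcmc_t_strict_clock,
)
from .simulate import GeneTreeSet
from .trees import TimeTree

__all__ = [
    "BranchEstimateTable",
    "concatenate",
    "run_concatenated",
    "run_congruent_loci",
    "run_congruent_branches",
]


@dataclass
class BranchEstimateTable:
    """Per-branch estimates for one method, as a tidy DataFrame.

    Columns: ``branch_id``, ``clade``, ``branch_class`` (internal/terminal),
    ``true_t``, ``true_n``, ``estimate``, ``n_used`` (gene trees averaged,
    congruent-branch method only), ``merged_root_pair`` (n estimation only),
    ``method``, ``param``.
    """

    table: pd.DataFrame
    method: str
    param: str
    fitted_tree: TimeTree | None = None
    rate_hat: float | None = None
    info: dict = field(default_factory=dict)

    def estimates(self) -> dict[int, float]:
        return dict(zip(self.table["branch_id"], self.table["estimate"]))


def _branch_frame(species_tree: TimeTree, sim_rate: float) -> pd.DataFrame:
    rows = []
    for n in species_tree.postorder():
        if n.parent is None:
            continue
        rows.append(
            {
                "branch_id": n.id,
                "clade": ",".join(sorted(species_tree.clade_of(n))),
                "branch_class": "terminal" if n.is_leaf else "internal",
                "true_t": n.branch_t,
                "true_n": sim_rate * n.branch_t,
            }
        )
    return pd.DataFrame(rows).sort_values("branch_id", ignore_index=True)


def concatenate(alignments: list[Alignment]) -> Alignment:
    """Join loci column-wise over the union of taxa; missing taxa are padded
    with gaps and per-locus boundaries are recorded."""
    if not alignments:
        raise ValueError("nothing to concatenate")
    taxa: list[str] = []
    for a in alignments:
        for t in a.taxa:
            if t not in taxa:
                taxa.append(t)
    total = sum(a.n_sites for a in alignments)
    data = np.full((len(taxa), total), GAP, dtype=np.uint8)
    boundaries = []
    col = 0
    for a in alignments:
        idx = [taxa.index(t) for t in a.taxa]
        data[idx, col : col + a.n_sites] = a.data
        col += a.n_sites
        boundaries.append(col)
    return Alignment(taxa, data, boundaries=boundaries)


def _fit_concatenated(
    concat: Alignment,
    species_tree: TimeTree,
    clock: ClockConfig,
    param: str,
    prior: UCLNPrior | None,
    sim_rate: float,
    seed,
    method: str,
) -> BranchEstimateTable:
    frame = _branch_frame(species_tree, sim_rate)
    if param == "t":
        fit = estimate_t_strict_clock(concat, species_tree, clock, seed=seed)
        durations = fit.branch_durations()
        frame["estimate"] = frame["branch_id"].map(durations)
        return BranchEstimateTable(
            frame.assign(method=method, param="t"),
            method=method,
            param="t",
            fitted_tree=fit.tree,
            rate_hat=fit.rate,
            info={"loglik": fit.loglik},
        )
    if param == "n":
        nfit = estimate_n_unrooted(concat, species_tree)
        frame["estimate"] = frame["branch_id"].map(nfit.estimates)
        frame["merged_root_pair"] = frame["branch_id"].isin(nfit.root_pair)
        # truth for the merged pair is the identifiable sum
        pair_truth = frame.loc[frame["merged_root_pair"], "true_n"].sum()
        frame.loc[frame["merged_root_pair"], "true_n"] = pair_truth
        return BranchEstimateTable(
            frame.assign(method=method, param="n"),
            method=method,
            param="n",
            info={"loglik": nfit.loglik, "root_pair": nfit.root_pair},
        )
    if param == "r":
        if prior is None:
            raise ValueError("r estimation requires a UCLNPrior")
        rfit = estimate_r_fixed_times(concat, species_tree, prior)
        frame["estimate"] = frame["branch_id"].map(rfit.rates)
        frame["true_r"] = sim_rate
        return BranchEstimateTable(
            frame.assign(method=method, param="r"),
            method=method,
            param="r",
            info={"log_posterior": rfit.log_posterior},
        )
    raise ValueError(f"unknown parameter {param!r}")


def run_concatenated(
    genes: GeneTreeSet,
    alignments: list[Alignment],
    species_tree: TimeTree,
    clock: ClockConfig,
    param: str = "t",
    prior: UCLNPrior | None = None,
    sim_rate: float = 0.05,
    seed=None,
) -> BranchEstimateTable:
    """All loci concatenated, parameter estimated on the species topology."""
    if len(genes) != len(alignments):
        raise ValueError("genes and alignments must be parallel")
    concat = concatenate(alignments)
    out = _fit_concatenated(
        concat, species_tree, clock, param, prior, sim_rate, seed, "concat"
    )
    out.info["n_loci_used"] = len(alignments)
    return out


def run_congruent_loci(
    genes: GeneTreeSet,
    alignments: list[Alignment],
    species_tree: TimeTree,
    clock: ClockConfig,
    max_incongruent: int = 0,
    param: str = "t",
    prior: UCLNPrior | None = None,
    sim_rate: float = 0.05,
    seed=None,
) -> BranchEstimateTable:
    """Concatenate only loci whose gene trees pass the incongruence threshold."""
    filtered = filter_gene_trees(genes, species_tree, max_incongruent)
    kept = filtered.provenance["kept_indices"]
    if not kept:
        raise ValueError("no locus passes the congruence filter")
    concat = concatenate([alignments[i] for i in kept])
    out = _fit_concatenated(
        concat,
        species_tree,
        clock,
        param,
        prior,
        sim_rate,
        seed,
        f"congruent_loci<={max_incongruent}",
    )
    out.info.update(
        {
            "n_loci_used": len(kept),
            "max_incongruent": max_incongruent,
            "retained_fraction": filtered.provenance["retained_fraction"],
        }
    )
    return out


def run_congruent_branches(
    genes: GeneTreeSet,
    alignments: list[Alignment],
    species_tree: TimeTree,
    clock: ClockConfig,
    param: str = "t",
    prior: UCLNPrior | None = None,
    sim_rate: float = 0.05,
    seed=None,
    dating: str = "posterior_mean",
) -> BranchEstimateTable:
    """Mean per-branch estimate over gene trees possessing an equivalent branch.

    Each gene tree is analyzed individually; for ``t`` it is dated with its
    root fixed to the species-tree root age, by default via short MCMC
    chains whose posterior-mean ages reproduce Bayesian per-locus dating
    (the conditioned-Yule tree prior matters at single-locus alignment
    sizes; ``dating="ml"`` switches to pure maximum likelihood).  A species
    branch with zero equivalent branches gets a missing value and a warning,
    never a fallback.  For ``n``, equivalent branches adjacent to the gene
    tree's root are skipped: only their pairwise sum is identifiable.
    """
    if len(genes) != len(alignments):
        raise ValueError("genes and alignments must be parallel")
    if dating not in ("posterior_mean", "ml"):
        raise ValueError(f"unknown dating mode {dating!r}")
    base_seed = 0 if seed is None else int(seed)

    per_gene_values: list[dict[int, float]] = []
    for locus, (gene_tree, aln) in enumerate(zip(genes, alignments)):
        if param == "t":
            if dating == "posterior_mean":
                post = mcmc_t_strict_clock(
                    aln, gene_tree, clock,
                    MCMCConfig(seed=base_seed * 100003 + locus),
                )
                per_gene_values.append(post.branch_durations())
                continue
            # ML path: per-locus datings are numerous and averaged; a coarser
            # Brent tolerance (vs the concatenated fits) moves class means
            # < 0.01 percentage points
            fit = estimate_t_strict_clock(
                aln, gene_tree, clock, seed=seed, age_xatol_frac=1e-4
            )
            per_gene_values.append(fit.branch_durations())
        elif param == "n":
            nfit = estimate_n_unrooted(aln, gene_tree)
            vals = dict(nfit.estimates)
            for v in nfit.root_pair:  # unidentifiable individually
                vals.pop(v, None)
            per_gene_values.append(vals)
        elif param == "r":
            if prior is None:
                raise ValueError("r estimation requires a UCLNPrior")
            rfit = estimate_r_fixed_times(aln, gene_tree, prior)
            per_gene_values.append(dict(rfit.rates))
        else:
            raise ValueError(f"unknown parameter {param!r}")

    emap = build_equivalence_map(species_tree, genes)
    frame = _branch_frame(species_tree, sim_rate)
    estimates, n_used = {}, {}
    for branch_id, pairs in emap.matches.items():
        vals = [
            per_gene_values[gi][node_id]
            for gi, node_id in pairs
            if node_id in per_gene_values[gi]
        ]
        n_used[branch_id] = len(vals)
        estimates[branch_id] = float(np.mean(vals)) if vals else np.nan
        if not vals:
            warnings.warn(
                f"species branch {branch_id} has no usable equivalent branch; "
                "estimate left missing",
                stacklevel=2,
            )
    frame["estimate"] = frame["branch_id"].map(estimates)
    frame["n_used"] = frame["branch_id"].map(n_used)
    return BranchEstimateTable(
        frame.assign(method="congruent_branches", param=param),
        method="congruent_branches",
        param=param,
        info={"n_missing_branches": len(emap.missing)},
    )
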
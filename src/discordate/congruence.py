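"""Topology comparison between a species tree and gene trees.

Two notions of agreement are used, both rooted and clade-based:

* **congruence (per branch)** — a gene tree is congruent for a species-tree
  branch when it contains a branch with the same descendant clade.  Terminal
  branches are trivially congruent (a sampled tip is always a clade), so
  incongruence is a property of internal branches only.
* **equivalence (per branch, strictly stronger)** — a gene-tree branch is
  *equivalent* to a species-tree branch when the clades under both its
  descendant node *and* its ancestral node match the species tree's.  This is
  the matching rule used by the congruent-branch estimator: an equivalent
  branch spans the same two speciation events, so its duration estimates the
  species branch's duration.

Incomplete taxon sampling is handled by intersecting species-tree clades with
the gene tree's taxon set before comparison; a branch whose restricted
descendant clade is empty or equal to its restricted ancestral clade is
untestable in that gene tree and excluded from denominators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .simulate import GeneTreeSet
from .trees import CladePair, TimeTree, clade_pairs

__all__ = [
    "BranchCongruenceReport",
    "EquivalenceMap",
    "branch_incongruence",
    "count_incongruent_branches",
    "filter_gene_trees",
    "is_equivalent_branch",
    "build_equivalence_map",
]

logger = logging.getLogger(__name__)


@dataclass
class BranchCongruenceReport:
    branch_id: int
    descendant_clade: frozenset
    percent_incongruent: float
    n_gene_trees_considered: int

    @property
    def is_terminal(self) -> bool:
        return len(self.descendant_clade) == 1


@dataclass
class EquivalenceMap:
    """For each species branch, the (gene index, gene branch id) pairs of
    equivalent gene-tree branches; branches with no equivalent are listed in
    ``missing``."""

    matches: dict[int, list[tuple[int, int]]]
    missing: list[int] = field(default_factory=list)

    def n_equivalent(self, branch_id: int) -> int:
        return len(self.matches[branch_id])


def _restrict(pair: CladePair, gene_taxa: frozenset):
    """Restricted (descendant, ancestral) clades, or None when untestable."""
    d, a = pair.restricted(gene_taxa)
    if not d or d == a:
        return None
    return d, a


def branch_incongruence(
    species_tree: TimeTree, genes: GeneTreeSet
) -> list[BranchCongruenceReport]:
    """Percent of gene trees lacking each species-tree branch's clade.

    Gene trees that do not sample enough taxa to test a clade are excluded
    from that branch's denominator.
    """
    if len(genes) == 0:
        raise ValueError("empty gene-tree set")
    pairs = clade_pairs(species_tree)
    gene_info = [(frozenset(g.clades().values()), g.taxa) for g in genes]

    reports = []
    for branch_id, pair in pairs.items():
        considered = 0
        absent = 0
        for clades, taxa in gene_info:
            restricted = _restrict(pair, taxa)
            if restricted is None:
                continue
            d, _ = restricted
            considered += 1
            if len(d) > 1 and d not in clades:
                absent += 1
        pct = 100.0 * absent / considered if considered else float("nan")
        reports.append(
            BranchCongruenceReport(
                branch_id=branch_id,
                descendant_clade=pair.descendant,
                percent_incongruent=pct,
                n_gene_trees_considered=considered,
            )
        )
    return reports


def count_incongruent_branches(species_tree: TimeTree, gene_tree: TimeTree) -> int:
    """Number of internal species-tree branches whose (taxon-restricted)
    descendant clade is absent from the gene tree."""
    gene_clades = frozenset(gene_tree.clades().values())
    gene_taxa = gene_tree.taxa
    count = 0
    for branch_id, pair in clade_pairs(species_tree).items():
        if len(pair.descendant) < 2:
            continue
        restricted = _restrict(pair, gene_taxa)
        if restricted is None:
            continue
        d, _ = restricted
        if len(d) > 1 and d not in gene_clades:
            count += 1
    return count


def filter_gene_trees(
    genes: GeneTreeSet, species_tree: TimeTree, max_incongruent: int
) -> GeneTreeSet:
    """Retain gene trees with at most ``max_incongruent`` incongruent branches.

    Order is preserved; provenance records the retained indices and fraction
    so locus-level data (alignments) can be subset in step.
    """
    if max_incongruent < 0:
        raise ValueError("max_incongruent must be >= 0")
    kept = [
        i
        for i, g in enumerate(genes)
        if count_incongruent_branches(species_tree, g) <= max_incongruent
    ]
    if not kept:
        logger.warning(
            "filter_gene_trees: no gene tree passes threshold %d", max_incongruent
        )
    provenance = dict(genes.provenance)
    provenance.update(
        {
            "filter_max_incongruent": max_incongruent,
            "kept_indices": kept,
            "retained_fraction": len(kept) / len(genes) if len(genes) else 0.0,
        }
    )
    return GeneTreeSet([genes[i] for i in kept], provenance=provenance)


def is_equivalent_branch(
    species_branch: CladePair, gene_tree: TimeTree, gene_branch: int
) -> bool:
    """Does the gene-tree branch span the same two clades as the species branch?

    True iff, after restricting the species clades to the gene tree's sampled
    taxa, the gene branch's descendant clade equals the restricted descendant
    clade *and* its ancestral node's clade equals the restricted ancestral
    clade.  For a species branch attached to the root the ancestral clade is
    the full taxon set, so the gene branch must hang off the gene tree's root.
    The relation is directional: species branch -> gene branch.
    """
    restricted = _restrict(species_branch, gene_tree.taxa)
    if restricted is None:
        return False
    d, a = restricted
    node = gene_tree.node(gene_branch)
    if node.parent is None:
        return False
    return gene_tree.clade_of(node) == d and gene_tree.clade_of(node.parent) == a


def build_equivalence_map(
    species_tree: TimeTree, genes: GeneTreeSet
) -> EquivalenceMap:
    """Find, per species branch, every gene tree's equivalent branch (if any).

    In a bifurcating gene tree at most one branch can match; in the polytomous
    case the candidate with the smallest ancestral clade would be taken (and
    logged).
    """
    pairs = clade_pairs(species_tree)
    matches: dict[int, list[tuple[int, int]]] = {b: [] for b in pairs}

    gene_maps = []
    for g in genes:
        clade_to_node: dict[frozenset, int] = {}
        for node_id, clade in g.clades().items():
            if clade in clade_to_node:  # polytomy duplicates: keep smaller ancestor
                logger.info("duplicate clade in gene tree; keeping first match")
                continue
            clade_to_node[clade] = node_id
        gene_maps.append((g, clade_to_node))

    for branch_id, pair in pairs.items():
        for gi, (g, clade_to_node) in enumerate(gene_maps):
            restricted = _restrict(pair, g.taxa)
            if restricted is None:
                continue
            d, a = restricted
            node_id = clade_to_node.get(d)
            if node_id is None:
                continue
            parent = g.node(node_id).parent
            if parent is not None and g.clade_of(parent) == a:
                matches[branch_id].append((gi, node_id))

    missing = [b for b, m in matches.items() if not m]
    for b in missing:
        logger.warning(
            "species branch %d (clade %s) has no equivalent branch in any gene tree",
            b,
            sorted(pairs[b].descendant),
        )
    return EquivalenceMap(matches=matches, missing=missing)
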
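"""Synthetic data: gene-tree simulators and Jukes-Cantor sequence simulation.

Three simulation designs generate gene trees for a known species tree:

* **fixed schemes** — every gene tree is a verbatim copy of either the species
  tree or a single alternative topology with identical node ages; the fraction
  of alternative trees is the experimental dial.  This isolates *topological*
  incongruence: gene-tree divergence times never differ from the species tree.
* **multispecies coalescent (MSC)** — gene lineages coalesce within species
  branches at rate k(k-1)/(2*Ne) (time measured in the species tree's units),
  producing both topological incongruence (incomplete lineage sorting) and
  gene divergences that predate species divergences.
* **sequence simulation** — 800 bp per locus by default, evolved along the
  gene tree under Jukes-Cantor at a strict clock rate of 0.05
  substitutions/site/time.

Study-condition defaults (400 loci, Ne = 0.12, r = 0.05, L = 800, the
canonical four- and 16-taxon trees with all-0.2 branch durations) live here;
every test input and experiment draws from this module.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment
from .trees import Node, TimeTree

__all__ = [
    "GeneTreeSet",
    "FixedSchemeConfig",
    "MSCConfig",
    "SeqSimConfig",
    "CANONICAL_SCHEMES",
    "build_canonical_trees",
    "simulate_fixed_scheme",
    "simulate_msc",
    "simulate_jc_alignment",
    "simulate_dataset",
]


@dataclass
class GeneTreeSet:
    """A collection of gene trees plus provenance about how they were made."""

    trees: list[TimeTree]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i) -> TimeTree:
        return self.trees[i]

    def to_newick(self) -> str:
        return "".join(t.to_newick() + "\n" for t in self.trees)

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick())


# ---------------------------------------------------------------------------
# canonical species / alternative trees
# ---------------------------------------------------------------------------

CANONICAL_SCHEMES = (
    "four_taxon",
    "four_taxon_msc",
    "balanced16",
    "balanced16_swap2",
    "balanced16_swap4",
    "balanced16_swap6",
    "balanced16_swap8",
    "imbalanced16",
)


def _cherry(a: str, b: str, age: float) -> Node:
    return Node(age=age, children=[Node(label=a), Node(label=b)])


def _four_taxon(internal_age: float, root_age: float, order=("A", "B", "C", "D")) -> TimeTree:
    a, b, c, d = order
    return TimeTree(
        Node(
            age=root_age,
            children=[_cherry(a, b, internal_age), _cherry(c, d, internal_age)],
        )
    )


def _balanced16(edge: float = 0.2) -> TimeTree:
    tips = list(string.ascii_uppercase[:16])

    def build(labels, depth):
        if len(labels) == 1:
            return Node(label=labels[0])
        half = len(labels) // 2
        return Node(
            age=depth * edge,
            children=[build(labels[:half], depth - 1), build(labels[half:], depth - 1)],
        )

    return TimeTree(build(tips, 4))


def _imbalanced16(edge: float = 0.2) -> TimeTree:
    """Caterpillar: cherry (A,B) at age 0.2, each later tip joining one step
    deeper, up to the root at 3.0."""
    tips = list(string.ascii_uppercase[:16])
    node = _cherry(tips[0], tips[1], edge)
    for k, label in enumerate(tips[2:], start=2):
        node = Node(age=k * edge, children=[node, Node(label=label)])
    return TimeTree(node)


def _swap_map(k: int) -> dict:
    """Reciprocal tip swap across the two halves of the balanced tree:
    A<->I, B<->J, ... for k/2 pairs."""
    left = string.ascii_uppercase[: k // 2]
    right = string.ascii_uppercase[8 : 8 + k // 2]
    m = {}
    for a, b in zip(left, right):
        m[a], m[b] = b, a
    return m


def build_canonical_trees(name: str) -> tuple[TimeTree, TimeTree | None]:
    """Species tree and, for fixed schemes, its alternative gene-tree topology.

    * ``four_taxon`` — ((A,B),(C,D)), internal nodes at 0.5, root at 1.0; the
      alternative tree groups (A,C) and (B,D) at identical ages.
    * ``four_taxon_msc`` — same topology with every branch duration 0.2
      (root age 0.4); used by the MSC design, so no alternative tree.
    * ``balanced16`` / ``balanced16_swapK`` — perfectly balanced 16-taxon tree,
      every branch duration 0.2 (root 0.8); the alternative tree reciprocally
      swaps K terminals across the two halves (A<->I, B<->J, ...).
    * ``imbalanced16`` — 16-taxon caterpillar, internal branches 0.2, terminal
      durations increasing from 0.2 to 3.0 toward the root.
    """
    if name == "four_taxon":
        return _four_taxon(0.5, 1.0), _four_taxon(0.5, 1.0, order=("A", "C", "B", "D"))
    if name == "four_taxon_msc":
        return _four_taxon(0.2, 0.4), None
    if name == "balanced16":
        return _balanced16(), None
    if name.startswith("balanced16_swap"):
        k = int(name.removeprefix("balanced16_swap"))
        if k not in (2, 4, 6, 8):
            raise ValueError(f"unknown scheme {name!r}")
        species = _balanced16()
        return species, species.relabel(_swap_map(k))
    if name == "imbalanced16":
        return _imbalanced16(), None
    raise ValueError(f"unknown scheme {name!r}; known: {CANONICAL_SCHEMES}")


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


@dataclass
class FixedSchemeConfig:
    species_tree: TimeTree
    incongruent_tree: TimeTree
    fraction_incongruent: float
    n_loci: int = 400
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.fraction_incongruent <= 1.0:
            raise ValueError("fraction_incongruent must be in [0, 1]")
        if self.n_loci < 1:
            raise ValueError("n_loci must be positive")
        if self.species_tree.taxa != self.incongruent_tree.taxa:
            raise ValueError("species and incongruent trees must share tip sets")


@dataclass
class MSCConfig:
    species_tree: TimeTree
    Ne: float = 0.12
    n_loci: int = 400
    seed: int | None = None

    def __post_init__(self):
        if self.Ne <= 0:
            raise ValueError("Ne must be positive")
        if self.n_loci < 1:
            raise ValueError("n_loci must be positive")


@dataclass
class SeqSimConfig:
    seq_length: int = 800
    rate: float = 0.05
    seed: int | None = None

    def __post_init__(self):
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")
        if self.rate <= 0:
            raise ValueError("rate must be positive")


# ---------------------------------------------------------------------------
# gene-tree simulators
# ---------------------------------------------------------------------------


def simulate_fixed_scheme(config: FixedSchemeConfig) -> GeneTreeSet:
    """Gene trees as exact copies of the species or alternative topology.

    Exactly ``round(fraction * n_loci)`` trees take the alternative topology;
    all node ages are identical to the species tree's.  Tree order is shuffled
    under the seed so locus index carries no information.
    """
    rng = np.random.default_rng(config.seed)
    n_inc = int(round(config.fraction_incongruent * config.n_loci))
    flags = np.zeros(config.n_loci, dtype=bool)
    flags[:n_inc] = True
    rng.shuffle(flags)
    trees = [
        (config.incongruent_tree if f else config.species_tree).copy() for f in flags
    ]
    return GeneTreeSet(
        trees,
        provenance={
            "design": "fixed",
            "fraction_incongruent": config.fraction_incongruent,
            "n_loci": config.n_loci,
            "seed": config.seed,
            "is_incongruent": flags.tolist(),
        },
    )


def _msc_one_tree(species: TimeTree, Ne: float, rng: np.random.Generator) -> TimeTree:
    """One gene tree from the multispecies coalescent.

    Species branches are processed tips-to-root; within a branch the k extant
    gene lineages coalesce with exponential waiting times at rate
    k(k-1)/(2*Ne); lineages still separate at the branch's top are handed to
    the parent population, and everything remaining coalesces above the root.
    Every coalescence therefore happens at or above the species-tree age of the
    MRCA population it occurs in.
    """
    pools: dict[int, list[Node]] = {}
    for sp in species.postorder():
        if sp.is_leaf:
            pool = [Node(label=sp.label, age=sp.age)]
        else:
            pool = []
            for c in sp.children:
                pool.extend(pools.pop(c.id))
        t = sp.age
        t_end = sp.parent.age if sp.parent is not None else np.inf
        while len(pool) > 1:
            k = len(pool)
            t_next = t + rng.exponential(2.0 * Ne / (k * (k - 1)))
            if t_next >= t_end:
                break
            t = t_next
            i, j = rng.choice(k, size=2, replace=False)
            merged = Node(age=t, children=[pool[i], pool[j]])
            pool = [x for idx, x in enumerate(pool) if idx not in (i, j)]
            pool.append(merged)
        pools[sp.id] = pool
    (root,) = pools[species.root.id]
    return TimeTree(root)


def simulate_msc(config: MSCConfig) -> GeneTreeSet:
    """Gene trees under the multispecies coalescent, one sample per species."""
    rng = np.random.default_rng(config.seed)
    trees = [
        _msc_one_tree(config.species_tree, config.Ne, rng)
        for _ in range(config.n_loci)
    ]
    return GeneTreeSet(
        trees,
        provenance={
            "design": "msc",
            "Ne": config.Ne,
            "n_loci": config.n_loci,
            "seed": config.seed,
        },
    )


# ---------------------------------------------------------------------------
# sequence simulation
# ---------------------------------------------------------------------------


def simulate_jc_alignment(tree: TimeTree, config: SeqSimConfig) -> Alignment:
    """Evolve sequences along ``tree`` under Jukes-Cantor.

    The root sequence is uniform over {A,C,G,T}; along a branch of duration t
    each site stays put with probability 1/4 + (3/4) exp(-(4/3) r t) and
    otherwise moves to one of the three other bases uniformly, which is
    exactly the JC transition kernel.  Sites are independent.
    """
    rng = np.random.default_rng(config.seed)
    L = config.seq_length
    seqs: dict[int, np.ndarray] = {tree.root.id: rng.integers(0, 4, L, dtype=np.uint8)}
    taxa, rows = [], []
    for node in tree.preorder():
        if node.parent is not None:
            n_subs = config.rate * node.branch_t
            p_same = 0.25 + 0.75 * np.exp(-4.0 / 3.0 * n_subs)
            seq = seqs[node.parent.id].copy()
            hit = rng.random(L) >= p_same
            k = int(hit.sum())
            if k:
                # uniform over the three non-current bases
                seq[hit] = (seq[hit] + rng.integers(1, 4, k, dtype=np.uint8)) % 4
            seqs[node.id] = seq
        if node.is_leaf:
            taxa.append(node.label)
            rows.append(seqs[node.id])
    order = np.argsort(taxa, kind="stable")
    return Alignment([taxa[i] for i in order], np.vstack([rows[i] for i in order]))


def simulate_dataset(
    genes: GeneTreeSet, seq_config: SeqSimConfig
) -> list[Alignment]:
    """One alignment per gene tree, with per-locus seeds spawned from the
    config seed so the dataset is reproducible as a whole."""
    ss = seq_config.seed
    if not isinstance(ss, np.random.SeedSequence):
        ss = np.random.SeedSequence(ss)
    seeds = ss.spawn(len(genes))
    out = []
    for tree, ss in zip(genes, seeds):
        cfg = SeqSimConfig(seq_config.seq_length, seq_config.rate, seed=ss)
        out.append(simulate_jc_alignment(tree, cfg))
    return out
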
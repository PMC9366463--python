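import numpy as np
import pytest

from discordate.simulate import (
    FixedSchemeConfig,
    SeqSimConfig,
    build_canonical_trees,
    simulate_dataset,
    simulate_fixed_scheme,
)
from discordate.trees import Node, TimeTree


def random_clock_tree(n_tips: int, rng: np.random.Generator) -> TimeTree:
    """Random ultrametric tree by sequential pairwise joins at increasing ages."""
    pool = [Node(label=f"t{i}") for i in range(n_tips)]
    age = 0.0
    while len(pool) > 1:
        age += rng.exponential(0.3) + 1e-3
        i, j = rng.choice(len(pool), size=2, replace=False)
        merged = Node(age=age, children=[pool[i], pool[j]])
        pool = [x for k, x in enumerate(pool) if k not in (i, j)] + [merged]
    return TimeTree(pool[0])


@pytest.fixture(scope="session")
def four_taxon():
    species, alt = build_canonical_trees("four_taxon")
    return species, alt


@pytest.fixture(scope="session")
def small_clean_dataset():
    """Forty fully congruent four-taxon loci of 800 bp (truth recoverable)."""
    species, alt = build_canonical_trees("four_taxon")
    genes = simulate_fixed_scheme(
        FixedSchemeConfig(species, alt, fraction_incongruent=0.0, n_loci=40, seed=101)
    )
    alignments = simulate_dataset(genes, SeqSimConfig(800, 0.05, seed=102))
    return species, genes, alignments
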
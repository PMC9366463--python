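"""Rooted time trees: the shared data model for every other module.

A :class:`TimeTree` is a rooted tree whose nodes carry *ages* (time before
present; tips of an ultrametric tree sit at age 0).  The duration of the
branch above a node is ``parent.age - node.age`` (written ``t``).  Branches
may optionally carry a substitution rate ``r`` and an expected number of
substitutions per site ``n = r * t``; the identity ``t = n / r`` is what
makes times and rates jointly non-identifiable from sequence data alone.

Branch identity across trees is clade-based: a branch is named by the set of
tip labels descended from it, which is how topological congruence between a
species tree and its gene trees is defined throughout the package.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import dendropy

__all__ = [
    "Node",
    "TimeTree",
    "CladePair",
    "TreeError",
    "read_newick",
    "write_newick",
    "descendant_clades",
    "clade_pairs",
    "restrict_to_taxa",
]

#: absolute tolerance for ultrametricity / age-ordering checks; accumulation
#: error over the short paths handled here (<= 16 edges) stays well below this
AGE_TOL = 1e-9


class TreeError(ValueError):
    """Malformed tree or invalid tree operation."""


class Node:
    """A tree node with an age and optional per-branch rate/substitution count.

    ``rate`` and ``n_subs`` describe the branch *above* this node (undefined
    for the root).
    """

    __slots__ = ("label", "age", "parent", "children", "id", "rate", "n_subs")

    def __init__(self, label=None, age=0.0, children=None):
        self.label = label
        self.age = float(age)
        self.parent = None
        self.children = []
        self.id = None
        self.rate = None
        self.n_subs = None
        if children:
            for c in children:
                self.add_child(c)

    def add_child(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def branch_t(self) -> float:
        """Duration of the branch above this node (nan for the root)."""
        if self.parent is None:
            return float("nan")
        return self.parent.age - self.age

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Node({self.label or self.id}, age={self.age:g})"


class TimeTree:
    """A rooted tree with node ages; nodes are indexed in postorder (root last)."""

    def __init__(self, root: Node, validate: bool = True):
        self.root = root
        self._postorder: list[Node] = []
        self._clades: dict[int, frozenset] | None = None
        self._index()
        if validate:
            self.validate()

    # -- structure ---------------------------------------------------------

    def _index(self) -> None:
        self._postorder = []
        self._clades = None
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                node.id = len(self._postorder)
                self._postorder.append(node)
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def postorder(self) -> list[Node]:
        return list(self._postorder)

    def preorder(self) -> list[Node]:
        return list(reversed(self._postorder))

    @property
    def nodes(self) -> list[Node]:
        return list(self._postorder)

    def node(self, node_id: int) -> Node:
        return self._postorder[node_id]

    def tips(self) -> list[Node]:
        return [n for n in self._postorder if n.is_leaf]

    @property
    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    @property
    def taxa(self) -> frozenset:
        return frozenset(self.tip_labels)

    @property
    def n_tips(self) -> int:
        return sum(1 for n in self._postorder if n.is_leaf)

    @property
    def root_age(self) -> float:
        return self.root.age

    def validate(self) -> None:
        labels = self.tip_labels
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {dup}")
        if any(l is None for l in labels):
            raise TreeError("unlabeled tip")
        for n in self._postorder:
            if n.parent is not None and n.age >= n.parent.age + 1e-12:
                raise TreeError(
                    f"node age {n.age} not strictly below parent age {n.parent.age}"
                )

    def is_ultrametric(self, tol: float = AGE_TOL) -> bool:
        return all(abs(t.age) <= tol for t in self.tips())

    def is_bifurcating(self) -> bool:
        return all(len(n.children) == 2 for n in self._postorder if not n.is_leaf)

    # -- clades ------------------------------------------------------------

    def clades(self) -> dict[int, frozenset]:
        """Descendant tip-label set for every non-root branch, keyed by node id."""
        if self._clades is None:
            sets: dict[int, frozenset] = {}
            full: dict[int, frozenset] = {}
            for n in self._postorder:
                if n.is_leaf:
                    s = frozenset((n.label,))
                else:
                    s = frozenset().union(*(full[c.id] for c in n.children))
                full[n.id] = s
                if n.parent is not None:
                    sets[n.id] = s
            self._clades = sets
            self._full_clades = full
        return dict(self._clades)

    def clade_of(self, node: Node | int) -> frozenset:
        """Tip-label set of the subtree rooted at ``node`` (root included)."""
        self.clades()
        node_id = node if isinstance(node, int) else node.id
        return self._full_clades[node_id]

    # -- editing / copying ---------------------------------------------------

    def copy(self) -> "TimeTree":
        def rec(n: Node) -> Node:
            m = Node(label=n.label, age=n.age)
            m.rate = n.rate
            m.n_subs = n.n_subs
            for c in n.children:
                m.add_child(rec(c))
            return m

        return TimeTree(rec(self.root), validate=False)

    def relabel(self, mapping: dict) -> "TimeTree":
        """Return a copy with tip labels replaced via ``mapping`` (others kept)."""
        out = self.copy()
        for t in out.tips():
            t.label = mapping.get(t.label, t.label)
        out._clades = None
        return out

    # -- I/O -----------------------------------------------------------------

    def to_newick(self, include_root_length: bool = False) -> str:
        return write_newick(self, include_root_length=include_root_length)

    def __repr__(self):  # pragma: no cover
        return f"TimeTree({self.n_tips} tips, root_age={self.root_age:g})"


@dataclass(frozen=True)
class CladePair:
    """Identifies a species-tree branch by the clades at its two ends.

    ``descendant`` is the tip set below the branch's lower (descendant) node;
    ``ancestral`` is the tip set below its upper (ancestral) node.  For a
    branch attached to the root, ``ancestral`` is the full taxon set.
    """

    descendant: frozenset
    ancestral: frozenset

    def __post_init__(self):
        if not self.descendant:
            raise TreeError("descendant clade must be non-empty")
        if not self.descendant < self.ancestral:
            raise TreeError("descendant must be a proper subset of ancestral")

    def restricted(self, taxa: frozenset) -> "tuple[frozenset, frozenset]":
        """Both clades intersected with a sampled taxon set (may be degenerate)."""
        return self.descendant & taxa, self.ancestral & taxa


def _quote_label(label: str) -> str:
    if any(ch in label for ch in " \t(),:;'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: TimeTree, include_root_length: bool = False) -> str:
    """Serialize a :class:`TimeTree`; branch lengths are durations (t)."""

    def rec(n: Node) -> str:
        if n.is_leaf:
            core = _quote_label(n.label)
        else:
            core = "(" + ",".join(rec(c) for c in n.children) + ")"
        if n.parent is not None:
            core += f":{n.branch_t:.12g}"
        elif include_root_length:
            core += ":0"
        return core

    return rec(tree.root) + ";"


def read_newick(text: str) -> TimeTree:
    """Parse a newick string with branch lengths into a :class:`TimeTree`.

    Node ages are computed by depth accumulation from the root: a node's age
    is the maximum tip depth minus its own depth, so ultrametric inputs get
    tips at age 0.  Missing branch lengths are treated as 0 (dendropy's
    convention for the root edge); malformed input raises dendropy's parse
    error, which carries the offending position.
    """
    dtree = dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )

    depths: dict = {}
    max_depth = 0.0
    for dn in dtree.preorder_node_iter():
        edge = dn.edge.length or 0.0
        parent = dn.parent_node
        depths[dn] = (depths[parent] if parent is not None else 0.0) + (
            edge if parent is not None else 0.0
        )
        if dn.is_leaf():
            max_depth = max(max_depth, depths[dn])

    def rec(dn) -> Node:
        label = dn.taxon.label if dn.taxon is not None else dn.label
        node = Node(label=label, age=max_depth - depths[dn])
        for child in dn.child_nodes():
            node.add_child(rec(child))
        return node

    return TimeTree(rec(dtree.seed_node))


def read_newick_list(text: str) -> list[TimeTree]:
    """Parse one tree per line (blank lines ignored)."""
    return [read_newick(line) for line in io.StringIO(text) if line.strip()]


def descendant_clades(tree: TimeTree) -> dict[int, frozenset]:
    """Map each non-root branch (keyed by its descendant node id) to its clade.

    Terminal branches map to singletons; a fully bifurcating rooted tree
    yields exactly ``2 * n_tips - 2`` entries.
    """
    return tree.clades()


def clade_pairs(tree: TimeTree) -> dict[int, CladePair]:
    """Descendant/ancestral clade pair for every non-root branch."""
    tree.clades()
    out = {}
    for n in tree.postorder():
        if n.parent is None:
            continue
        out[n.id] = CladePair(
            descendant=tree.clade_of(n), ancestral=tree.clade_of(n.parent)
        )
    return out


def restrict_to_taxa(tree: TimeTree, taxa) -> TimeTree:
    """Induced subtree on ``taxa``: unary nodes suppressed, ages unchanged."""
    taxa = frozenset(taxa)
    if not taxa & tree.taxa:
        raise TreeError("no tree tip is in the requested taxon set")

    def rec(n: Node) -> Node | None:
        if n.is_leaf:
            if n.label in taxa:
                return Node(label=n.label, age=n.age)
            return None
        kept = [m for m in (rec(c) for c in n.children) if m is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        return Node(age=n.age, children=kept)

    root = rec(tree.root)
    assert root is not None
    return TimeTree(root)
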
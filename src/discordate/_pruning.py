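"""Felsenstein pruning for the Jukes-Cantor model.

The inner loops are JIT-compiled with numba because the optimizers upstream
(coordinate search over node ages / branch lengths) evaluate the likelihood
thousands of times on small (pattern x 4) arrays, where Python/numpy call
overhead would dominate.

The JC transition kernel has the rank-one-plus-identity form
``P(n) @ v = e * v + (1/4)(1 - e) * sum(v)`` with ``e = exp(-4n/3)``, which is
what the kernels exploit instead of forming 4x4 matrices.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .alignment import GAP, Alignment
from .trees import TimeTree


@njit(cache=True)
def _update_nodes(cond, nvec, child0, child1, order):
    """Recompute conditional likelihoods at the internal nodes in ``order``
    (must be consistent with postorder among themselves)."""
    P = cond.shape[1]
    for idx in range(order.shape[0]):
        v = order[idx]
        c0 = child0[v]
        c1 = child1[v]
        e0 = np.exp(-4.0 / 3.0 * nvec[c0])
        e1 = np.exp(-4.0 / 3.0 * nvec[c1])
        q0 = 0.25 * (1.0 - e0)
        q1 = 0.25 * (1.0 - e1)
        for p in range(P):
            s0 = cond[c0, p, 0] + cond[c0, p, 1] + cond[c0, p, 2] + cond[c0, p, 3]
            s1 = cond[c1, p, 0] + cond[c1, p, 1] + cond[c1, p, 2] + cond[c1, p, 3]
            for s in range(4):
                cond[v, p, s] = (e0 * cond[c0, p, s] + q0 * s0) * (
                    e1 * cond[c1, p, s] + q1 * s1
                )


@njit(cache=True)
def _root_loglik(root_cond, weights):
    total = 0.0
    P = root_cond.shape[0]
    for p in range(P):
        site = 0.25 * (
            root_cond[p, 0] + root_cond[p, 1] + root_cond[p, 2] + root_cond[p, 3]
        )
        total += weights[p] * np.log(site)
    return total


class JCPruner:
    """Pruning likelihood on a fixed bifurcating topology.

    Branch lengths are expected substitutions per site, stored per node (the
    branch above that node), indexed by the tree's postorder node ids.  The
    class supports full recomputation and cheap single-branch / single-age
    updates that only touch the ancestor path.
    """

    def __init__(self, tree: TimeTree, alignment: Alignment):
        if not tree.is_bifurcating():
            raise ValueError("pruning requires a bifurcating tree")
        missing = tree.taxa - set(alignment.taxa)
        if missing:
            raise ValueError(f"alignment lacks taxa {sorted(missing)}")

        self.tree = tree
        nodes = tree.postorder()
        self.n_nodes = len(nodes)
        self.root_id = tree.root.id
        self.child0 = np.full(self.n_nodes, -1, dtype=np.int64)
        self.child1 = np.full(self.n_nodes, -1, dtype=np.int64)
        self.parent = np.full(self.n_nodes, -1, dtype=np.int64)
        internal = []
        for n in nodes:
            if not n.is_leaf:
                self.child0[n.id] = n.children[0].id
                self.child1[n.id] = n.children[1].id
                internal.append(n.id)
            if n.parent is not None:
                self.parent[n.id] = n.parent.id
        self.internal_postorder = np.array(internal, dtype=np.int64)

        patterns, counts = alignment.site_patterns()
        self.weights = np.ascontiguousarray(counts)
        self.n_patterns = patterns.shape[1]
        self.cond = np.zeros((self.n_nodes, self.n_patterns, 4))
        row_of = {t: i for i, t in enumerate(alignment.taxa)}
        for n in nodes:
            if n.is_leaf:
                states = patterns[row_of[n.label]]
                tip = self.cond[n.id]
                gap = states == GAP
                tip[gap, :] = 1.0
                tip[np.arange(self.n_patterns)[~gap], states[~gap]] = 1.0

        self.nvec = np.zeros(self.n_nodes)
        self._ancestor_paths = {}
        for n in nodes:
            if n.is_leaf:
                continue
            path = []
            cur = n.id
            while cur != -1:
                if self.child0[cur] != -1:
                    path.append(cur)
                cur = self.parent[cur]
            self._ancestor_paths[n.id] = np.array(path, dtype=np.int64)
        for n in nodes:
            if n.is_leaf:
                self._ancestor_paths[n.id] = self._ancestor_paths[n.parent.id]

    # -- evaluation ----------------------------------------------------------

    def set_all(self, nvec: np.ndarray) -> float:
        if np.any(nvec[np.arange(self.n_nodes) != self.root_id] < 0):
            raise ValueError("branch lengths must be non-negative")
        self.nvec[:] = nvec
        _update_nodes(self.cond, self.nvec, self.child0, self.child1,
                      self.internal_postorder)
        return self.loglik()

    def recompute_all(self) -> float:
        _update_nodes(self.cond, self.nvec, self.child0, self.child1,
                      self.internal_postorder)
        return self.loglik()

    def set_branch(self, node_id: int, n: float) -> float:
        """Set the branch above ``node_id`` and update only its ancestors."""
        self.nvec[node_id] = n
        _update_nodes(self.cond, self.nvec, self.child0, self.child1,
                      self._ancestor_paths[node_id])
        return self.loglik()

    def update_from(self, node_id: int) -> float:
        """Recompute the ancestor path of ``node_id`` after external nvec edits."""
        _update_nodes(self.cond, self.nvec, self.child0, self.child1,
                      self._ancestor_paths[node_id])
        return self.loglik()

    def loglik(self) -> float:
        return float(_root_loglik(self.cond[self.root_id], self.weights))


def jc_log_likelihood(
    tree: TimeTree,
    alignment: Alignment,
    branch_n: dict | None = None,
    rate: float | None = None,
) -> float:
    """Exact JC log-likelihood of ``alignment`` on ``tree``.

    Branch lengths (expected substitutions/site) come from, in order of
    precedence: the ``branch_n`` mapping (node id -> n), ``rate`` times the
    branch durations, or per-node ``n_subs`` attributes.
    """
    pruner = JCPruner(tree, alignment)
    nvec = np.zeros(pruner.n_nodes)
    for node in tree.postorder():
        if node.parent is None:
            continue
        if branch_n is not None:
            nvec[node.id] = branch_n[node.id]
        elif rate is not None:
            nvec[node.id] = rate * node.branch_t
        elif node.n_subs is not None:
            nvec[node.id] = node.n_subs
        else:
            raise ValueError(f"no branch length for node {node.id}")
    return pruner.set_all(nvec)
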
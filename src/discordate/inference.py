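"""Likelihood-based estimation of substitutions (n), times (t) and rates (r).

All estimators share the Jukes-Cantor pruning likelihood and a fixed, known
topology; they differ in what is free:

* :func:`estimate_n_unrooted` — maximum-likelihood branch lengths in expected
  substitutions per site.  Under a reversible model the root position carries
  no information, so the two root-adjacent branches are identifiable only
  through their sum and are reported jointly.
* :func:`estimate_t_strict_clock` — node ages of an ultrametric tree under a
  strict clock, with the root age fixed (the only absolute-time calibration).
  The rate is either fixed or profiled within box constraints.
* :func:`estimate_r_fixed_times` — maximum-a-posteriori per-branch rates with
  all node ages fixed to their true values, under independent lognormal
  branch-rate priors (an uncorrelated-lognormal relaxed clock with the times
  held fixed).

Point estimates (ML/MAP) stand in for posterior means: at the alignment sizes
used here (hundreds of loci x 800 bp) the posterior is data-dominated and the
weak tree priors move point summaries by far less than the Monte-Carlo noise
the experiments measure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from ._pruning import JCPruner, jc_log_likelihood
from .alignment import Alignment
from .trees import TimeTree

__all__ = [
    "UCLNPrior",
    "ClockConfig",
    "ClockFit",
    "ClockPosterior",
    "MCMCConfig",
    "UnrootedNFit",
    "RateFit",
    "jc_log_likelihood",
    "estimate_n_unrooted",
    "estimate_t_strict_clock",
    "estimate_r_fixed_times",
    "mcmc_t_strict_clock",
]

#: stop coordinate sweeps once a full sweep improves log-likelihood less than this
LOGLIK_TOL = 1e-8
#: Brent bracket for branch lengths (expected substitutions/site)
N_BOUNDS = (0.0, 10.0)


@dataclass(frozen=True)
class UCLNPrior:
    """Lognormal branch-rate prior parameterized by its *real-scale* mean and
    variance (``v = 0`` collapses to a strict clock at rate ``m``)."""

    m: float
    v: float

    def __post_init__(self):
        if self.m <= 0:
            raise ValueError("m must be positive")
        if self.v < 0:
            raise ValueError("v must be non-negative")

    @property
    def sigma2(self) -> float:
        return math.log1p(self.v / self.m**2)

    @property
    def mu(self) -> float:
        return math.log(self.m) - self.sigma2 / 2.0

    def logpdf(self, r: float) -> float:
        if self.v == 0:
            raise ValueError("degenerate prior (v = 0) has no density")
        s2 = self.sigma2
        lr = math.log(r)
        return -lr - 0.5 * math.log(2 * math.pi * s2) - (lr - self.mu) ** 2 / (2 * s2)


@dataclass(frozen=True)
class ClockConfig:
    """Strict-clock settings for time estimation.

    ``strict_fixed_rate`` uses the supplied ``rate``; ``strict_free_rate``
    profiles the rate inside ``rate_bounds`` (a uniform-prior box).
    """

    mode: str
    root_age: float
    rate: float | None = None
    rate_bounds: tuple[float, float] = (1e-6, 1.0)

    def __post_init__(self):
        if self.mode not in ("strict_fixed_rate", "strict_free_rate"):
            raise ValueError(f"unknown clock mode {self.mode!r}")
        if self.root_age <= 0:
            raise ValueError("root_age must be positive")
        if self.mode == "strict_fixed_rate":
            if self.rate is None or self.rate <= 0:
                raise ValueError("strict_fixed_rate requires a positive rate")
        if self.rate_bounds[0] <= 0 or self.rate_bounds[0] >= self.rate_bounds[1]:
            raise ValueError("invalid rate bounds")


@dataclass
class ClockFit:
    """Result of strict-clock dating: an ultrametric tree with estimated ages."""

    tree: TimeTree
    rate: float
    loglik: float
    n_sweeps: int

    def age(self, node_id: int) -> float:
        return self.tree.node(node_id).age

    def branch_durations(self) -> dict[int, float]:
        return {
            n.id: n.branch_t for n in self.tree.postorder() if n.parent is not None
        }


@dataclass
class UnrootedNFit:
    """ML branch lengths; the two root-adjacent branches carry their sum."""

    estimates: dict[int, float]
    root_pair: tuple[int, int]
    loglik: float


@dataclass
class RateFit:
    rates: dict[int, float]
    log_posterior: float


# ---------------------------------------------------------------------------
# branch lengths (n)
# ---------------------------------------------------------------------------


def estimate_n_unrooted(
    alignment: Alignment,
    topology: TimeTree,
    tol: float = LOGLIK_TOL,
    max_sweeps: int = 60,
    polish: bool = True,
) -> UnrootedNFit:
    """ML branch lengths (expected substitutions/site) on a fixed topology.

    The rooted input is treated as unrooted: one root-adjacent branch absorbs
    the (identifiable) sum of the pair, and both are reported with that sum.
    Optimization is coordinate-wise Brent followed by an L-BFGS-B polish.
    """
    pruner = JCPruner(topology, alignment)
    c0, c1 = (c.id for c in topology.root.children)
    free = [
        n.id for n in topology.postorder() if n.parent is not None and n.id != c1
    ]
    nvec = np.zeros(pruner.n_nodes)
    nvec[free] = 0.02
    best = pruner.set_all(nvec)

    for sweep in range(max_sweeps):
        for v in free:
            res = minimize_scalar(
                lambda x: -pruner.set_branch(v, x),
                bounds=N_BOUNDS,
                method="bounded",
                options={"xatol": 1e-8},
            )
            pruner.set_branch(v, float(res.x))
        cur = pruner.loglik()
        if cur - best < tol:
            best = max(best, cur)
            break
        best = cur

    if polish:
        x0 = pruner.nvec[free].copy()

        def negll(x):
            vec = np.zeros(pruner.n_nodes)
            vec[free] = x
            return -pruner.set_all(vec)

        res = minimize(
            negll, x0, method="L-BFGS-B", bounds=[N_BOUNDS] * len(free),
            options={"ftol": 1e-12, "gtol": 1e-8},
        )
        if -res.fun >= best:
            negll(res.x)
            best = -res.fun
        else:  # keep the coordinate-search optimum
            vec = np.zeros(pruner.n_nodes)
            vec[free] = x0
            best = pruner.set_all(vec)

    estimates = {v: float(pruner.nvec[v]) for v in free}
    estimates[c1] = estimates[c0]  # the pair is reported jointly as its sum
    return UnrootedNFit(estimates=estimates, root_pair=(c0, c1), loglik=best)


# ---------------------------------------------------------------------------
# node ages (t) under a strict clock
# ---------------------------------------------------------------------------


def _clock_init_ages(
    alignment: Alignment, tree: TimeTree, clock: ClockConfig
) -> tuple[np.ndarray, float]:
    """Initial ages from pairwise JC clock distances (node height = mean
    cross-clade distance / 2), plus a rate guess for the free-rate mode."""
    taxa = sorted(tree.taxa)
    sub = alignment.subset(taxa)
    D = sub.jc_distance_matrix()
    row = {t: i for i, t in enumerate(taxa)}

    heights = np.zeros(len(tree.nodes))
    for node in tree.postorder():
        if node.is_leaf:
            continue
        left = [row[t] for t in tree.clade_of(node.children[0])]
        right = [row[t] for t in tree.clade_of(node.children[1])]
        heights[node.id] = D[np.ix_(left, right)].mean() / 2.0

    if clock.mode == "strict_fixed_rate":
        rate = clock.rate
    else:
        rate = float(
            np.clip(heights[tree.root.id] / clock.root_age, *clock.rate_bounds)
        )
    ages = heights / rate
    return ages, rate


class _ClockObjective:
    """Mutable strict-clock state: ages + rate -> branch n -> pruning loglik."""

    def __init__(self, pruner: JCPruner, tree: TimeTree):
        self.pruner = pruner
        self.tree = tree
        self.nodes = tree.postorder()
        self.parent = pruner.parent
        self.ages = np.zeros(len(self.nodes))
        self.rate = None
        self.children = {
            n.id: [c.id for c in n.children] for n in self.nodes if not n.is_leaf
        }

    def set_state(self, ages: np.ndarray, rate: float) -> float:
        self.ages = ages.copy()
        self.rate = rate
        nvec = np.zeros_like(ages)
        for n in self.nodes:
            if n.parent is not None:
                nvec[n.id] = rate * (self.ages[n.parent.id] - self.ages[n.id])
        return self.pruner.set_all(nvec)

    def set_age(self, v: int, a: float) -> float:
        self.ages[v] = a
        nv = self.pruner.nvec
        p = self.parent[v]
        if p != -1:
            nv[v] = self.rate * (self.ages[p] - a)
        for c in self.children[v]:
            nv[c] = self.rate * (a - self.ages[c])
        return self.pruner.update_from(v)

    def set_rate(self, rate: float) -> float:
        return self.set_state(self.ages, rate)


def _repair_ages(tree: TimeTree, ages: np.ndarray, root_age: float) -> np.ndarray:
    """Project a raw age vector into the feasible region (strict child < parent,
    tips pinned, root pinned)."""
    eps = 1e-6 * root_age
    ages = ages.copy()
    for n in tree.postorder():
        if n.is_leaf:
            ages[n.id] = n.age  # tips keep their (zero) sampling age
        else:
            lb = max(ages[c.id] for c in n.children) + eps
            ages[n.id] = max(ages[n.id], lb)
    ages[tree.root.id] = root_age
    for n in tree.preorder():
        if n.parent is None or n.is_leaf:
            continue
        hi = ages[n.parent.id] - eps
        if ages[n.id] > hi:
            lb = max(ages[c.id] for c in n.children)
            ages[n.id] = max(0.5 * (lb + ages[n.parent.id]), min(ages[n.id], hi))
            ages[n.id] = min(ages[n.id], hi)
    return ages


def estimate_t_strict_clock(
    alignment: Alignment,
    topology: TimeTree,
    clock: ClockConfig,
    seed: int | None = None,
    n_restarts: int = 1,
    tol: float = LOGLIK_TOL,
    max_sweeps: int = 100,
    age_xatol_frac: float = 1e-6,
) -> ClockFit:
    """Strict-clock chronogram: ML internal node ages with the root fixed.

    Each internal node's age is optimized by Brent within its feasible
    interval (above its oldest child, below its parent), cycling until a full
    sweep improves the log-likelihood by less than ``tol``; in the free-rate
    mode the clock rate is profiled (Brent on a log scale within the bound
    box) once per sweep.  The default single start uses ages initialized from
    pairwise clock distances, which lands inside the basin of the optimum;
    extra ``n_restarts`` draw random feasible starts from ``seed``.
    """
    fitted = topology.copy()
    pruner = JCPruner(fitted, alignment)
    obj = _ClockObjective(pruner, fitted)
    free_nodes = [
        n.id for n in fitted.postorder() if not n.is_leaf and n.parent is not None
    ]
    root_id = fitted.root.id
    root_age = clock.root_age
    eps = 1e-9 * root_age
    xatol = age_xatol_frac * root_age
    rng = np.random.default_rng(seed)

    starts: list[tuple[np.ndarray, float]] = []
    ages0, rate0 = _clock_init_ages(alignment, fitted, clock)
    starts.append((_repair_ages(fitted, ages0, root_age), rate0))
    for _ in range(max(0, n_restarts - 1)):
        ages = np.zeros_like(ages0)
        ages[root_id] = root_age
        for n in fitted.preorder():
            if n.parent is not None and not n.is_leaf:
                ages[n.id] = ages[n.parent.id] * rng.uniform(0.05, 0.95)
        if clock.mode == "strict_free_rate":
            lo, hi = clock.rate_bounds
            r = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            r = clock.rate
        starts.append((_repair_ages(fitted, ages, root_age), r))

    best_state = None
    for ages_init, rate_init in starts:
        ll = obj.set_state(ages_init, rate_init)
        sweeps = 0
        for sweeps in range(1, max_sweeps + 1):
            for v in free_nodes:
                p = obj.parent[v]
                lo = max(obj.ages[c] for c in obj.children[v]) + eps
                hi = obj.ages[p] - eps
                if hi - lo <= 2 * xatol:
                    continue
                res = minimize_scalar(
                    lambda a: -obj.set_age(v, a),
                    bounds=(lo, hi),
                    method="bounded",
                    options={"xatol": xatol},
                )
                obj.set_age(v, float(res.x))
            if clock.mode == "strict_free_rate":
                lo_r, hi_r = np.log(clock.rate_bounds)
                res = minimize_scalar(
                    lambda lr: -obj.set_rate(float(np.exp(lr))),
                    bounds=(lo_r, hi_r),
                    method="bounded",
                    options={"xatol": 1e-5},
                )
                obj.set_rate(float(np.exp(res.x)))
            cur = obj.pruner.loglik()
            if cur - ll < tol:
                ll = max(ll, cur)
                break
            ll = cur
        if best_state is None or ll > best_state[0]:
            best_state = (ll, obj.ages.copy(), obj.rate, sweeps)

    ll, ages, rate, sweeps = best_state
    for n in fitted.postorder():
        n.age = float(ages[n.id])
        if n.parent is not None:
            n.rate = rate
    fitted._clades = None
    # refresh n_subs so the fitted tree is self-describing
    for n in fitted.postorder():
        if n.parent is not None:
            n.n_subs = rate * n.branch_t
    return ClockFit(tree=fitted, rate=float(rate), loglik=float(ll), n_sweeps=sweeps)


# ---------------------------------------------------------------------------
# posterior sampling of node ages (strict clock)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MCMCConfig:
    """Chain settings for :func:`mcmc_t_strict_clock`.

    ``yule_birth_rate`` sets the conditioned-Yule tree prior's intensity
    (its node-age log-density is -birth_rate x age per free node, root
    fixed); the clock-rate prior is the uniform box of the clock config.
    """

    n_sweeps: int = 750
    burn: int = 150
    thin: int = 5
    yule_birth_rate: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.burn < self.n_sweeps:
            raise ValueError("need 0 <= burn < n_sweeps")
        if self.thin < 1 or self.yule_birth_rate < 0:
            raise ValueError("invalid thin or birth rate")


@dataclass
class ClockPosterior:
    """Posterior summary of a strict-clock dating: a tree whose node ages are
    posterior means, the posterior-mean rate, and thinned (ages, rate)
    samples (columns: free internal nodes in postorder, then the rate)."""

    tree: TimeTree
    rate: float
    samples: np.ndarray
    free_node_ids: list
    acceptance_rate: float

    def branch_durations(self) -> dict[int, float]:
        return {
            n.id: n.branch_t for n in self.tree.postorder() if n.parent is not None
        }


def mcmc_t_strict_clock(
    alignment: Alignment,
    topology: TimeTree,
    clock: ClockConfig,
    mcmc: MCMCConfig = MCMCConfig(),
) -> ClockPosterior:
    """Metropolis-Hastings over node ages (and the rate, when free) under a
    conditioned-Yule tree prior.

    Proposals are uniform sliding windows inside each node's feasible age
    interval (reflected at the bounds) plus a multiplicative rate walk.  The
    chain starts from a coarse ML fit, so short chains already sample the
    stationary neighborhood; posterior means converge to the ML estimates as
    the alignment grows.  Single-locus posterior means differ from ML by the
    prior's pull — which is the point: they reproduce the behavior of
    Bayesian per-locus dating.
    """
    from ._mcmc import _mh_ages

    # coarse ML start (the chain only needs the basin, not the optimum)
    fit = estimate_t_strict_clock(
        alignment, topology, clock, age_xatol_frac=3e-4
    )
    fitted = fit.tree
    pruner = JCPruner(fitted, alignment)
    n = pruner.n_nodes
    max_len = max(len(p) for p in pruner._ancestor_paths.values())
    paths = np.zeros((n, max_len), dtype=np.int64)
    path_len = np.zeros(n, dtype=np.int64)
    for v, path in pruner._ancestor_paths.items():
        paths[v, : len(path)] = path
        path_len[v] = len(path)
    free = np.array(
        [m.id for m in fitted.postorder() if not m.is_leaf and m.parent is not None],
        dtype=np.int64,
    )
    ages = np.array([m.age for m in fitted.postorder()])
    nvec = np.array(
        [
            fit.rate * m.branch_t if m.parent is not None else 0.0
            for m in fitted.postorder()
        ]
    )
    log_rlo, log_rhi = np.log(clock.rate_bounds)
    mean_ages, mean_rate, samples, acc = _mh_ages(
        pruner.cond, nvec, pruner.child0, pruner.child1, pruner.parent,
        paths, path_len, free, ages, fit.rate, pruner.root_id, pruner.weights,
        mcmc.n_sweeps, mcmc.burn, mcmc.yule_birth_rate, log_rlo, log_rhi,
        clock.mode == "strict_free_rate", pruner.internal_postorder,
        mcmc.thin, int(mcmc.seed) % (2**31 - 1) + 1,
    )
    for m in fitted.postorder():
        m.age = float(mean_ages[m.id])
        if m.parent is not None:
            m.rate = float(mean_rate)
    fitted._clades = None
    return ClockPosterior(
        tree=fitted,
        rate=float(mean_rate),
        samples=samples,
        free_node_ids=[int(v) for v in free],
        acceptance_rate=float(acc),
    )


# ---------------------------------------------------------------------------
# branch rates (r) with times fixed
# ---------------------------------------------------------------------------


def estimate_r_fixed_times(
    alignment: Alignment,
    chronogram: TimeTree,
    prior: UCLNPrior,
    tol: float = LOGLIK_TOL,
    max_sweeps: int = 60,
) -> RateFit:
    """MAP per-branch rates with node ages fixed to the chronogram's.

    Maximizes JC log-likelihood plus independent lognormal log-densities on
    each branch rate.  ``v = 0`` is the strict-clock degenerate case and
    returns ``r = m`` exactly.  A zero-duration branch leaves the prior's
    contribution to that branch's substitution count undefined and is
    rejected.
    """
    durations = {
        n.id: n.branch_t for n in chronogram.postorder() if n.parent is not None
    }
    if any(t <= 0 for t in durations.values()):
        raise ValueError("zero-duration branch: per-branch rate is undefined")

    if prior.v == 0:
        return RateFit(rates={v: prior.m for v in durations}, log_posterior=math.nan)

    pruner = JCPruner(chronogram, alignment)
    free = sorted(durations)
    rates = {v: prior.m for v in free}
    nvec = np.zeros(pruner.n_nodes)
    for v in free:
        nvec[v] = rates[v] * durations[v]
    ll = pruner.set_all(nvec)
    post = ll + sum(prior.logpdf(rates[v]) for v in free)

    log_bounds = (math.log(1e-8), math.log(10.0))
    for _ in range(max_sweeps):
        for v in free:
            t_v = durations[v]

            def neg(lr):
                r = math.exp(lr)
                return -(pruner.set_branch(v, r * t_v) + prior.logpdf(r))

            res = minimize_scalar(
                neg, bounds=log_bounds, method="bounded", options={"xatol": 1e-7}
            )
            rates[v] = math.exp(float(res.x))
            pruner.set_branch(v, rates[v] * t_v)
        cur = pruner.loglik() + sum(prior.logpdf(rates[v]) for v in free)
        if cur - post < tol:
            post = max(post, cur)
            break
        post = cur

    return RateFit(rates={v: float(r) for v, r in rates.items()},
                   log_posterior=float(post))
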
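"""Pruning likelihood and the n / t / r estimators."""

import itertools

import numpy as np
import pytest

from discordate.alignment import Alignment
from discordate.inference import (
    ClockConfig,
    MCMCConfig,
    UCLNPrior,
    estimate_n_unrooted,
    estimate_r_fixed_times,
    estimate_t_strict_clock,
    jc_log_likelihood,
    mcmc_t_strict_clock,
)
from discordate.simulate import (
    FixedSchemeConfig,
    SeqSimConfig,
    build_canonical_trees,
    simulate_dataset,
    simulate_fixed_scheme,
    simulate_jc_alignment,
)
from discordate.estimators import concatenate
from discordate.trees import Node, TimeTree

from conftest import random_clock_tree


def _jc_p(n):
    """JC transition matrix for branch length n (expected substitutions)."""
    e = np.exp(-4.0 / 3.0 * n)
    return np.full((4, 4), 0.25 * (1 - e)) + np.eye(4) * e


def _enumeration_loglik(tree: TimeTree, aln: Alignment, rate: float) -> float:
    """Brute-force likelihood: sum over all internal-state assignments."""
    nodes = tree.postorder()
    internals = [n for n in nodes if not n.is_leaf]
    P = {n.id: _jc_p(rate * n.branch_t) for n in nodes if n.parent is not None}
    total = 0.0
    for site in range(aln.n_sites):
        tip_state = {t.label: aln.row(t.label)[site] for t in tree.tips()}
        site_lik = 0.0
        for states in itertools.product(range(4), repeat=len(internals)):
            assign = {n.id: s for n, s in zip(internals, states)}
            for t in tree.tips():
                assign[t.id] = tip_state[t.label]
            lik = 0.25  # root state prior
            for n in nodes:
                if n.parent is not None:
                    lik *= P[n.id][assign[n.parent.id], assign[n.id]]
            site_lik += lik
        total += np.log(site_lik)
    return total


class TestPruningLikelihood:
    @pytest.mark.parametrize("n_tips,seed", [(2, 0), (3, 1), (4, 2), (4, 3)])
    def test_matches_state_enumeration(self, n_tips, seed):
        rng = np.random.default_rng(seed)
        tree = random_clock_tree(n_tips, rng)
        aln = simulate_jc_alignment(tree, SeqSimConfig(6, 0.3, seed=seed))
        assert jc_log_likelihood(tree, aln, rate=0.3) == pytest.approx(
            _enumeration_loglik(tree, aln, 0.3), abs=1e-9
        )

    def test_identical_sites_zero_branches(self):
        tree = TimeTree(Node(age=1.0, children=[Node(label="A"), Node(label="B")]))
        L = 50
        aln = Alignment(["A", "B"], np.zeros((2, L), dtype=np.uint8))
        assert jc_log_likelihood(tree, aln, rate=0.0 + 1e-300) == pytest.approx(
            L * np.log(0.25)
        )

    def test_saturation_limit(self):
        species, _ = build_canonical_trees("four_taxon")
        aln = simulate_jc_alignment(species, SeqSimConfig(40, 0.05, seed=1))
        ll = jc_log_likelihood(species, aln, rate=1e4)
        assert ll == pytest.approx(aln.n_sites * 4 * np.log(0.25), rel=1e-9)

    def test_invariant_to_site_and_taxon_order(self):
        species, _ = build_canonical_trees("four_taxon")
        aln = simulate_jc_alignment(species, SeqSimConfig(300, 0.05, seed=2))
        rng = np.random.default_rng(0)
        shuffled_sites = Alignment(aln.taxa, aln.data[:, rng.permutation(aln.n_sites)])
        perm = rng.permutation(len(aln.taxa))
        shuffled_taxa = Alignment(
            [aln.taxa[i] for i in perm], aln.data[perm]
        )
        base = jc_log_likelihood(species, aln, rate=0.05)
        assert jc_log_likelihood(species, shuffled_sites, rate=0.05) == pytest.approx(base)
        assert jc_log_likelihood(species, shuffled_taxa, rate=0.05) == pytest.approx(base)

    def test_taxon_mismatch_errors(self):
        species, _ = build_canonical_trees("four_taxon")
        aln = Alignment(["A", "B", "C"], np.zeros((3, 10), dtype=np.uint8))
        with pytest.raises(ValueError):
            jc_log_likelihood(species, aln, rate=0.05)

    def test_pattern_compression_equals_uncompressed(self):
        """Compressing to unique site patterns is exact, not approximate."""
        species, _ = build_canonical_trees("four_taxon")
        aln = simulate_jc_alignment(species, SeqSimConfig(400, 0.05, seed=3))
        single_sites = [
            jc_log_likelihood(
                species, Alignment(aln.taxa, aln.data[:, [i]]), rate=0.05
            )
            for i in range(0, 400, 37)
        ]
        for i, ll in zip(range(0, 400, 37), single_sites):
            assert np.isfinite(ll)
        assert jc_log_likelihood(species, aln, rate=0.05) == pytest.approx(
            sum(
                jc_log_likelihood(
                    species, Alignment(aln.taxa, aln.data[:, [i]]), rate=0.05
                )
                for i in range(400)
            ),
            rel=1e-9,
        )


class TestEstimateN:
    def test_two_taxon_equals_jc_distance(self):
        tree = TimeTree(Node(age=1.0, children=[Node(label="A"), Node(label="B")]))
        aln = simulate_jc_alignment(tree, SeqSimConfig(5000, 0.05, seed=5))
        p = np.mean(aln.data[0] != aln.data[1])
        d = -0.75 * np.log1p(-4.0 / 3.0 * p)
        fit = estimate_n_unrooted(aln, tree)
        c0, c1 = fit.root_pair
        assert fit.estimates[c0] == pytest.approx(d, abs=1e-4)
        assert fit.estimates[c0] == fit.estimates[c1]

    def test_recovery_on_clean_four_taxon(self, small_clean_dataset):
        species, genes, alignments = small_clean_dataset
        concat = concatenate(alignments)
        fit = estimate_n_unrooted(concat, species)
        truth = {
            n.id: 0.05 * n.branch_t
            for n in species.postorder()
            if n.parent is not None
        }
        pair_sum = sum(truth[v] for v in fit.root_pair)
        # Monte-Carlo SE of a JC distance at 32 kb is ~1e-3
        for node_id, est in fit.estimates.items():
            expected = pair_sum if node_id in fit.root_pair else truth[node_id]
            assert est == pytest.approx(expected, abs=4e-3)


class TestEstimateT:
    def test_recovery_at_zero_incongruence(self, small_clean_dataset):
        """With congruent, clock-true data the chronogram is recovered to
        within Monte-Carlo error."""
        species, genes, alignments = small_clean_dataset
        concat = concatenate(alignments)
        clock = ClockConfig(mode="strict_fixed_rate", root_age=1.0, rate=0.05)
        fit = estimate_t_strict_clock(concat, species, clock)
        for node in fit.tree.postorder():
            if not node.is_leaf and node.parent is not None:
                assert node.age == pytest.approx(0.5, abs=0.02)

    def test_output_is_ultrametric_with_exact_root(self, small_clean_dataset):
        species, _, alignments = small_clean_dataset
        concat = concatenate(alignments)
        clock = ClockConfig(mode="strict_fixed_rate", root_age=1.0, rate=0.05)
        fit = estimate_t_strict_clock(concat, species, clock)
        assert fit.tree.root_age == 1.0
        assert fit.tree.is_ultrametric()
        for n in fit.tree.postorder():
            if n.parent is not None:
                assert n.age < n.parent.age

    def test_sister_terminals_share_estimate(self, small_clean_dataset):
        species, _, alignments = small_clean_dataset
        concat = concatenate(alignments)
        clock = ClockConfig(mode="strict_fixed_rate", root_age=1.0, rate=0.05)
        fit = estimate_t_strict_clock(concat, species, clock)
        durations = fit.branch_durations()
        for node in fit.tree.postorder():
            kids = node.children
            if len(kids) == 2 and all(c.is_leaf for c in kids):
                assert durations[kids[0].id] == pytest.approx(durations[kids[1].id])

    def test_free_rate_recovers_rate_and_ages(self, small_clean_dataset):
        species, _, alignments = small_clean_dataset
        concat = concatenate(alignments)
        clock = ClockConfig(mode="strict_free_rate", root_age=1.0)
        fit = estimate_t_strict_clock(concat, species, clock)
        assert fit.rate == pytest.approx(0.05, rel=0.05)
        for node in fit.tree.postorder():
            if not node.is_leaf and node.parent is not None:
                assert node.age == pytest.approx(0.5, abs=0.03)

    def test_random_restarts_reach_same_optimum(self, small_clean_dataset):
        species, _, alignments = small_clean_dataset
        concat = concatenate(alignments[:10])
        clock = ClockConfig(mode="strict_fixed_rate", root_age=1.0, rate=0.05)
        fit1 = estimate_t_strict_clock(concat, species, clock, n_restarts=1)
        fit3 = estimate_t_strict_clock(concat, species, clock, seed=42, n_restarts=3)
        assert fit3.loglik == pytest.approx(fit1.loglik, abs=1e-4)
        for n1 in fit1.tree.postorder():
            assert fit3.tree.node(n1.id).age == pytest.approx(n1.age, abs=1e-4)

    def test_rmse_decreases_with_alignment_length(self):
        """More data, tighter ages: RMSE over internal ages shrinks as loci
        accumulate (fixed seed, three sizes)."""
        species, alt = build_canonical_trees("four_taxon")
        clock = ClockConfig(mode="strict_fixed_rate", root_age=1.0, rate=0.05)
        rmses = []
        genes = simulate_fixed_scheme(
            FixedSchemeConfig(species, alt, 0.0, n_loci=64, seed=21)
        )
        alignments = simulate_dataset(genes, SeqSimConfig(800, 0.05, seed=22))
        for n_loci in (1, 8, 64):
            concat = concatenate(alignments[:n_loci])
            fit = estimate_t_strict_clock(concat, species, clock)
            errs = [
                fit.tree.node(n.id).age - n.age
                for n in species.postorder()
                if not n.is_leaf and n.parent is not None
            ]
            rmses.append(float(np.sqrt(np.mean(np.square(errs)))))
        assert rmses[0] > rmses[1] > rmses[2]


class TestEstimateR:
    def test_degenerate_prior_returns_mean(self, small_clean_dataset):
        species, _, alignments = small_clean_dataset
        fit = estimate_r_fixed_times(
            alignments[0], species, UCLNPrior(m=0.05, v=0.0)
        )
        assert all(r == 0.05 for r in fit.rates.values())

    def test_low_variance_shrinks_to_prior_mean(self, small_clean_dataset):
        species, _, alignments = small_clean_dataset
        concat = concatenate(alignments[:5])
        fit = estimate_r_fixed_times(concat, species, UCLNPrior(m=0.05, v=1e-7))
        for r in fit.rates.values():
            assert r == pytest.approx(0.05, rel=0.02)

    def test_high_variance_tracks_data(self, small_clean_dataset):
        """A diffuse prior leaves the per-branch MAP rates near the truth on
        clean data (times fixed to the correct values)."""
        species, _, alignments = small_clean_dataset
        concat = concatenate(alignments)
        fit = estimate_r_fixed_times(concat, species, UCLNPrior(m=0.05, v=0.1))
        rates = np.array(list(fit.rates.values()))
        assert np.mean(rates) == pytest.approx(0.05, rel=0.1)

    def test_variance_governs_response_to_incongruence(self):
        """With times fixed to the truth on half-incongruent data, a diffuse
        branch-rate prior lets internal rates track the (halved) substitution
        signal, while a near-degenerate prior holds them marginally below the
        clock mean.  At tens of kilobases the likelihood dominates any prior
        whose rate sd is not far below the per-branch standard error, so the
        near-clock regime needs a very small variance."""
        species, alt = build_canonical_trees("four_taxon")
        genes = simulate_fixed_scheme(
            FixedSchemeConfig(species, alt, 0.5, 100, seed=51)
        )
        alignments = simulate_dataset(genes, SeqSimConfig(800, 0.05, seed=52))
        concat = concatenate(alignments)
        internal = [
            n.id for n in species.postorder()
            if not n.is_leaf and n.parent is not None
        ]
        loose = estimate_r_fixed_times(concat, species, UCLNPrior(0.05, 0.1))
        tight = estimate_r_fixed_times(concat, species, UCLNPrior(0.05, 1e-7))
        loose_internal = np.mean([loose.rates[v] for v in internal])
        tight_internal = np.mean([tight.rates[v] for v in internal])
        assert loose_internal < 0.035  # tracks the halved n signal
        assert tight_internal == pytest.approx(0.05, rel=0.05)
        assert tight_internal < 0.05  # still marginally below the truth

    def test_zero_duration_branch_rejected(self):
        tree = TimeTree(
            Node(
                age=1.0,
                children=[
                    Node(
                        age=1.0,  # zero-duration branch above this node
                        children=[Node(label="A"), Node(label="B")],
                    ),
                    Node(label="C"),
                ],
            ),
            validate=False,
        )
        aln = Alignment(["A", "B", "C"], np.zeros((3, 10), dtype=np.uint8))
        with pytest.raises(ValueError):
            estimate_r_fixed_times(aln, tree, UCLNPrior(m=0.05, v=0.1))

    def test_prior_moments(self):
        prior = UCLNPrior(m=0.05, v=0.001)
        # real-scale mean/variance round-trip through the underlying normal
        mean = np.exp(prior.mu + prior.sigma2 / 2)
        var = (np.exp(prior.sigma2) - 1) * np.exp(2 * prior.mu + prior.sigma2)
        assert mean == pytest.approx(0.05)
        assert var == pytest.approx(0.001)


class TestMCMC:
    def test_posterior_mean_approaches_ml_on_long_alignments(
        self, small_clean_dataset
    ):
        """With 32 kb of data the Yule prior is irrelevant: posterior-mean
        ages agree with the ML ages to well under half a percent."""
        species, _, alignments = small_clean_dataset
        concat = concatenate(alignments)
        clock = ClockConfig(mode="strict_fixed_rate", root_age=1.0, rate=0.05)
        ml = estimate_t_strict_clock(concat, species, clock)
        post = mcmc_t_strict_clock(
            concat, species, clock, MCMCConfig(n_sweeps=2000, burn=400, seed=3)
        )
        for node in species.postorder():
            if not node.is_leaf and node.parent is not None:
                delta = abs(post.tree.node(node.id).age - ml.tree.node(node.id).age)
                assert delta < 0.005 * clock.root_age

    def test_single_free_node_matches_quadrature(self):
        """One variable node age under a fixed-rate clock: the sampler's
        posterior mean matches direct numeric normalization of
        likelihood x prior on an age grid."""
        from discordate.trees import Node, TimeTree

        tree = TimeTree(
            Node(
                age=1.0,
                children=[
                    Node(age=0.4, children=[Node(label="A"), Node(label="B")]),
                    Node(label="C"),
                ],
            )
        )
        aln = simulate_jc_alignment(tree, SeqSimConfig(200, 0.1, seed=7))
        clock = ClockConfig(mode="strict_fixed_rate", root_age=1.0, rate=0.1)
        lam = 1.0

        grid = np.linspace(1e-4, 1.0 - 1e-4, 2001)
        log_post = np.empty_like(grid)
        work = tree.copy()
        free_node = next(
            n for n in work.postorder() if not n.is_leaf and n.parent is not None
        )
        for i, a in enumerate(grid):
            free_node.age = a
            log_post[i] = jc_log_likelihood(work, aln, rate=0.1) - lam * a
        w = np.exp(log_post - log_post.max())
        quad_mean = float((grid * w).sum() / w.sum())
        quad_sd = float(np.sqrt((w * (grid - quad_mean) ** 2).sum() / w.sum()))

        post = mcmc_t_strict_clock(
            aln, tree, clock, MCMCConfig(n_sweeps=8000, burn=1000, seed=11)
        )
        n_eff = 400  # conservative effective sample size for 7000 sweeps
        sampler_mean = post.tree.node(free_node.id).age
        assert abs(sampler_mean - quad_mean) < 4 * quad_sd / np.sqrt(n_eff)

    def test_deterministic_under_seed(self, small_clean_dataset):
        species, _, alignments = small_clean_dataset
        clock = ClockConfig(mode="strict_fixed_rate", root_age=1.0, rate=0.05)
        a = mcmc_t_strict_clock(alignments[0], species, clock, MCMCConfig(seed=5))
        b = mcmc_t_strict_clock(alignments[0], species, clock, MCMCConfig(seed=5))
        assert np.array_equal(a.samples, b.samples)
        assert a.rate == b.rate

    def test_config_validation(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_sweeps=100, burn=100)
        with pytest.raises(ValueError):
            MCMCConfig(thin=0)


class TestClockConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            ClockConfig(mode="strict_fixed_rate", root_age=1.0)  # no rate
        with pytest.raises(ValueError):
            ClockConfig(mode="strict_free_rate", root_age=-1.0)
        with pytest.raises(ValueError):
            ClockConfig(mode="wiggly", root_age=1.0)
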
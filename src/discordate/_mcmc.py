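"""Metropolis-Hastings kernel for strict-clock node ages (numba-compiled).

Single-component sliding-window proposals on each free internal node age
(reflected into its feasible interval) and, in the free-rate mode, a
multiplicative random-walk proposal on the clock rate inside its uniform
box.  The tree prior is the Yule process conditioned on the fixed root age,
whose node-age density contributes -birth_rate * age per free node on the
log scale; the rate prior is uniform on the box.

The kernel mutates the pruner's conditional-likelihood workspace in place
and returns posterior sums plus thinned samples.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from ._pruning import _root_loglik, _update_nodes


@njit(cache=True)
def _mh_ages(cond, nvec, child0, child1, parent, paths, path_len, free_nodes,
             ages, rate0, root, weights, n_sweeps, burn, lam,
             log_rlo, log_rhi, free_rate, internal_postorder, thin, seed):
    np.random.seed(seed)
    rate = rate0
    n_nodes = nvec.shape[0]
    _update_nodes(cond, nvec, child0, child1, internal_postorder)
    ll = _root_loglik(cond[root], weights)
    sum_ages = np.zeros(n_nodes)
    sum_rate = 0.0
    n_samp = 0
    n_free = free_nodes.shape[0]
    n_keep = (n_sweeps - burn + thin - 1) // thin
    samples = np.zeros((n_keep, n_free + 1))
    kept = 0
    accepted = 0
    proposed = 0
    for sweep in range(n_sweeps):
        for fi in range(n_free):
            v = free_nodes[fi]
            c0 = child0[v]
            c1 = child1[v]
            lo = max(ages[c0], ages[c1])
            hi = ages[parent[v]]
            w = 0.5 * (hi - lo)
            a_old = ages[v]
            a_new = a_old + (np.random.random() * 2.0 - 1.0) * w
            for _ in range(100):  # reflect into (lo, hi)
                if a_new < lo:
                    a_new = 2.0 * lo - a_new
                elif a_new > hi:
                    a_new = 2.0 * hi - a_new
                else:
                    break
            ages[v] = a_new
            nvec[v] = rate * (ages[parent[v]] - a_new)
            nvec[c0] = rate * (a_new - ages[c0])
            nvec[c1] = rate * (a_new - ages[c1])
            _update_nodes(cond, nvec, child0, child1, paths[v, : path_len[v]])
            ll_new = _root_loglik(cond[root], weights)
            proposed += 1
            if np.log(np.random.random()) < (ll_new - ll) - lam * (a_new - a_old):
                ll = ll_new
                accepted += 1
            else:
                ages[v] = a_old
                nvec[v] = rate * (ages[parent[v]] - a_old)
                nvec[c0] = rate * (a_old - ages[c0])
                nvec[c1] = rate * (a_old - ages[c1])
                _update_nodes(cond, nvec, child0, child1, paths[v, : path_len[v]])
        if free_rate:
            lr_old = np.log(rate)
            lr_new = lr_old + np.random.normal() * 0.05
            if log_rlo <= lr_new <= log_rhi:
                r_new = np.exp(lr_new)
                scale = r_new / rate
                for i in range(n_nodes):
                    nvec[i] *= scale
                _update_nodes(cond, nvec, child0, child1, internal_postorder)
                ll_new = _root_loglik(cond[root], weights)
                # multiplicative proposal: Hastings term log(r_new/r_old);
                # the rate prior is uniform on the box
                if np.log(np.random.random()) < (ll_new - ll) + (lr_new - lr_old):
                    ll = ll_new
                    rate = r_new
                else:
                    for i in range(n_nodes):
                        nvec[i] /= scale
                    _update_nodes(cond, nvec, child0, child1, internal_postorder)
        if sweep >= burn:
            for i in range(n_nodes):
                sum_ages[i] += ages[i]
            sum_rate += rate
            n_samp += 1
            if (sweep - burn) % thin == 0 and kept < n_keep:
                for fi in range(n_free):
                    samples[kept, fi] = ages[free_nodes[fi]]
                samples[kept, n_free] = rate
                kept += 1
    return (sum_ages / n_samp, sum_rate / n_samp, samples[:kept],
            accepted / proposed)
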
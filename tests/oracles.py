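"""Independent brute-force / closed-form oracles used by the tests.

These deliberately avoid the code paths they certify: the Mk oracle sums
over all internal-state assignments instead of pruning, the contrasts
oracle implements Felsenstein's pruning average, and the Yule shared-time
expectation comes from the uniform-composition property of the pure-birth
jump chain.
"""

import itertools
import math
from math import comb

import numpy as np
from scipy.linalg import expm


def brute_force_mk_loglik(tree, tip_states, Q, states, root_prior):
    """Sum over every internal-node state assignment (exponential cost)."""
    k = len(states)
    idx = {s: i for i, s in enumerate(states)}
    P = {n.index: expm(Q * n.length) for n in tree.nodes if n.parent}
    internals = [n for n in tree.nodes if not n.is_tip]
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internals)):
        st = {n.index: a for n, a in zip(internals, assign)}
        for t in tree.tips:
            st[t.index] = idx[str(tip_states[t.label])]
        prob = root_prior[st[tree.root.index]]
        for n in tree.nodes:
            if n.parent is not None:
                prob *= P[n.index][st[n.parent.index], st[n.index]]
        total += prob
    return math.log(total)


def contrasts_root_mean(tree, values):
    """Felsenstein independent-contrasts estimate of the BM root state.

    Equals the GLS grand mean under V proportional to shared branch length.
    Requires a strictly binary tree.
    """

    def rec(node):
        if node.is_tip:
            return float(values[node.label]), node.length
        (x1, v1), (x2, v2) = (rec(c) for c in node.children)
        x = (x1 / v1 + x2 / v2) / (1.0 / v1 + 1.0 / v2)
        v = node.length + v1 * v2 / (v1 + v2)
        return x, v

    return rec(tree.root)[0]


def yule_mean_pairwise_shared_time(n):
    """E[mean pairwise root-to-MRCA time] of an (unscaled) pure-birth tree
    grown with per-lineage rate 1, cut one Exp(n) wait after the last split.

    While k lineages exist the waiting time has mean 1/k, and the subtree
    sizes of the k lineages are uniform over compositions of n (so the
    probability that a random tip pair is still together has a closed
    form); sharing accrues for k = 2..n-1.
    """

    def q(k):
        tot = sum(comb(m, 2) * comb(n - m - 1, k - 2)
                  for m in range(1, n - k + 2))
        return k * tot / comb(n - 1, k - 1) / comb(n, 2)

    return sum(q(k) / k for k in range(2, n))


def two_state_conditioned_mean_changes(q, t):
    """E[# changes | same start and end state] for the symmetric 2-state
    chain: jumps are Poisson(q t) and the endpoint repeats iff the count is
    even, so the conditional mean is q t * tanh(q t)."""
    return q * t * math.tanh(q * t)


def ou_weight_by_quadrature(epochs, alpha, T):
    """Regime weights by numerical quadrature of alpha*exp(-alpha(T-t))."""
    from scipy.integrate import quad

    out = {}
    for r, s, e in epochs:
        val, _ = quad(lambda t: alpha * math.exp(-alpha * (T - t)), s, e,
                      epsabs=1e-12, epsrel=1e-12)
        out[r] = out.get(r, 0.0) + val
    return out
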
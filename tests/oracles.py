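"""Independent brute-force oracles used to validate the package.

Everything here is written from the payoff definitions and test
statistics directly, in plain Python, without calling the implementation
under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_force_equilibria(
    F=10.0, a=0.5, c=2.0, A=10, R=10.0,
    gamma_official=0.0, gamma_firm1=0.0, gamma_firm2=0.0,
):
    """Exhaustive deviation check over all (A+1)^2 integer bid profiles.

    Returns a set of (bribe1, bribe2, strict) triples.  Expected payoffs
    use the uniform tie rule.
    """

    def win_prob(b_own, b_opp):
        if a >= 1.0 - gamma_official:
            q_own, q_opp = A - b_own, A - b_opp
            if q_own > q_opp:
                return 1.0
            if q_own < q_opp:
                return 0.0
            return 0.5
        s_own = a * (A - b_own) + (1.0 - gamma_official) * b_own
        s_opp = a * (A - b_opp) + (1.0 - gamma_official) * b_opp
        if s_own > s_opp:
            return 1.0
        if s_own < s_opp:
            return 0.0
        return 0.5

    def eu(b_own, b_opp, gamma):
        p = win_prob(b_own, b_opp)
        u_win = F + a * (A - b_own) - (c + gamma) * b_own + R
        u_lose = F + a * (A - b_opp)
        return p * u_win + (1.0 - p) * u_lose

    eqs = set()
    grid = range(A + 1)
    for b1, b2 in itertools.product(grid, grid):
        e1 = eu(b1, b2, gamma_firm1)
        e2 = eu(b2, b1, gamma_firm2)
        dev1 = [eu(x, b2, gamma_firm1) for x in grid if x != b1]
        dev2 = [eu(x, b1, gamma_firm2) for x in grid if x != b2]
        if all(d <= e1 + 1e-9 for d in dev1) and all(
            d <= e2 + 1e-9 for d in dev2
        ):
            strict = all(d < e1 - 1e-9 for d in dev1) and all(
                d < e2 - 1e-9 for d in dev2
            )
            eqs.add((b1, b2, strict))
    return eqs


def enumeration_mann_whitney_z(sample_a, sample_b):
    """z score of the rank-sum U against its exact permutation moments.

    Enumerates every assignment of the pooled values to group A (all
    C(n, n1) splits) to obtain the exact null mean and variance of U.
    """
    pooled = list(sample_a) + list(sample_b)
    n1 = len(sample_a)
    n = len(pooled)
    # ranks with midrank ties, computed by hand
    order = sorted(range(n), key=lambda i: pooled[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        midrank = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = midrank
        i = j + 1

    def u_of(indices):
        r = sum(ranks[i] for i in indices)
        return r - n1 * (n1 + 1) / 2.0

    u_obs = u_of(range(n1))
    us = [u_of(comb) for comb in itertools.combinations(range(n), n1)]
    mean = sum(us) / len(us)
    var = sum((u - mean) ** 2 for u in us) / len(us)
    return (u_obs - mean) / math.sqrt(var)


def exact_permutation_pvalues(data_a, data_b):
    """Exact per-sample two-sided permutation p-values for tiny samples.

    Enumerates all C(n, n_a) label assignments of the pooled trials; the
    p-value at each time sample is the fraction of assignments whose
    |mean difference| is at least the observed one (the identity
    assignment counts, so p >= 1/C(n, n_a)).
    """
    X = np.vstack([data_a, data_b])
    na = len(data_a)
    n = X.shape[0]
    obs = X[:na].mean(axis=0) - X[na:].mean(axis=0)
    count = np.zeros(X.shape[1])
    total = 0
    for comb in itertools.combinations(range(n), na):
        idx_a = list(comb)
        idx_b = [i for i in range(n) if i not in comb]
        diff = X[idx_a].mean(axis=0) - X[idx_b].mean(axis=0)
        count += np.abs(diff) >= np.abs(obs) - 1e-12
        total += 1
    return count / total
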
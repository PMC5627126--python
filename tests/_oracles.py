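"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's compiled kernels: the one-step
transmission oracle enumerates every visiting order and partner choice
exactly, and the KS oracle evaluates the sup over the pooled grid directly.
"""

from itertools import permutations

import numpy as np


def eligible_partners(ages, parents, rule, i):
    """Partner indices for individual i under rule 'h', 'o' or 'n'."""
    n = len(ages)
    if rule == "h":
        return [j for j in range(n) if j != i and ages[j] == ages[i]]
    if rule == "o":
        return [j for j in range(n) if ages[j] > ages[i] and j != parents[i]]
    if rule == "n":
        return [j for j in range(n) if j != i]
    raise ValueError(rule)


def enumerate_one_step_transmission(ages, parents, variants, rule, p_w):
    """Exact distribution of post-step variant counts (mu = 0, b = 0).

    Enumerates all visiting orders (uniform over permutations) and, per
    individual, the event/no-event branch (probability p_w) and the uniform
    partner choice, with asynchronous state updates.  Returns a dict mapping
    count tuples (variants 1..5) to probabilities.
    """
    n = len(ages)
    dist: dict[tuple, float] = {}

    def recurse(order, pos, state, prob):
        if pos == n:
            key = tuple(int(c) for c in np.bincount(state, minlength=6)[1:])
            dist[key] = dist.get(key, 0.0) + prob
            return
        i = order[pos]
        if p_w < 1.0:
            recurse(order, pos + 1, state, prob * (1.0 - p_w))
        if p_w > 0.0:
            partners = eligible_partners(ages, parents, rule, i)
            if not partners:
                recurse(order, pos + 1, state, prob * p_w)
            else:
                for j in partners:
                    new_state = list(state)
                    new_state[i] = state[j]
                    recurse(order, pos + 1, new_state, prob * p_w / len(partners))

    perms = list(permutations(range(n)))
    for order in perms:
        recurse(order, 0, list(variants), 1.0 / len(perms))
    assert abs(sum(dist.values()) - 1.0) < 1e-12
    return dist


def brute_force_ks(samples_x, samples_y):
    """Sup over the pooled grid of |F_x - F_y|, with the lowest attaining z."""
    samples_x = np.asarray(samples_x, float)
    samples_y = np.asarray(samples_y, float)
    grid = np.unique(np.concatenate([samples_x, samples_y]))
    best_k, best_z = -1.0, None
    for z in grid:
        fx = np.mean(samples_x <= z)
        fy = np.mean(samples_y <= z)
        gap = abs(fx - fy)
        if gap > best_k + 1e-15:
            best_k, best_z = gap, z
    return best_k, best_z


def total_variation(dist_a: dict, dist_b: dict) -> float:
    keys = set(dist_a) | set(dist_b)
    return 0.5 * sum(abs(dist_a.get(k, 0.0) - dist_b.get(k, 0.0)) for k in keys)
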
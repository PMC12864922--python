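"""Independent oracles used to check the package's statistics and folding.

These deliberately avoid the code paths they validate: structure
probabilities by exhaustive enumeration of nested pairings, Fisher exact
p by direct hypergeometric summation, and the rank-sum null by full
enumeration of group assignments.
"""

import itertools
import math

import numpy as np
from scipy.stats import hypergeom

PAIR_E = {("G", "C"): 3.0, ("C", "G"): 3.0, ("A", "T"): 2.0, ("T", "A"): 2.0,
          ("G", "T"): 1.0, ("T", "G"): 1.0}


def enumerate_structures(seq, i=0, j=None, min_loop=3):
    """Yield every nested set of pairs of seq[i..j] (inclusive)."""
    if j is None:
        j = len(seq) - 1
    if j - i < 0:
        yield []
        return
    for s in enumerate_structures(seq, i, j - 1, min_loop):
        yield s
    for k in range(i, j - min_loop):
        if (seq[k], seq[j]) in PAIR_E:
            for left in enumerate_structures(seq, i, k - 1, min_loop):
                for inner in enumerate_structures(seq, k + 1, j - 1, min_loop):
                    yield left + inner + [(k, j)]


def oracle_pair_probs(seq, loop_penalty=8.0, min_loop=3):
    """Boltzmann pair probabilities by brute force (upper triangle)."""
    n = len(seq)
    g = math.exp(-loop_penalty)
    z = 0.0
    acc = np.zeros((n, n))
    for s in enumerate_structures(seq, min_loop=min_loop):
        pairs = set(s)
        w = 1.0
        for a, b in s:
            w *= math.exp(PAIR_E[(seq[a], seq[b])])
            if (a + 1, b - 1) not in pairs:  # this pair closes a loop
                w *= g
        z += w
        for a, b in s:
            acc[a, b] += w
    return acc / z if z > 0 else acc


def fisher_two_sided(table):
    """Two-sided Fisher exact p: sum of hypergeometric probabilities <= the
    observed one (within a relative tolerance, as the exact test defines)."""
    (a, b), (c, d) = table
    n = a + b + c + d
    k = a + b  # row 1 total (draws)
    K = a + c  # col 1 total (successes in population)
    rv = hypergeom(n, K, k)
    lo = max(0, k - (n - K))
    hi = min(k, K)
    p_obs = rv.pmf(a)
    return float(sum(rv.pmf(x) for x in range(lo, hi + 1)
                     if rv.pmf(x) <= p_obs * (1 + 1e-7)))


def wilcoxon_exact_two_sided(x, y):
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    pooled = sorted(list(x) + list(y))
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    obs = sum(ranks[v] for v in x)
    n = len(pooled)
    m = len(x)
    mean = m * (n + 1) / 2
    stats = [sum(combo) for combo in itertools.combinations(range(1, n + 1), m)]
    dev = abs(obs - mean)
    extreme = sum(1 for s in stats if abs(s - mean) >= dev - 1e-12)
    return extreme / len(stats)
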
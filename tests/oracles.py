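"""Independent reference implementations used only to check the package.

These deliberately avoid scipy's hypergeometric distribution and
statsmodels' multiple-testing code so that each check runs through two
unrelated routes.
"""

import math
from itertools import combinations

import numpy as np


def hypergeom_tail_comb(k: int, N: int, K: int, n: int) -> float:
    """Closed-form upper tail P(X >= k) via math.comb."""
    total = math.comb(N, n)
    return sum(math.comb(K, i) * math.comb(N - K, n - i)
               for i in range(max(k, 0), min(K, n) + 1)) / total


def hypergeom_tail_enumerate(k: int, N: int, K: int, n: int) -> float:
    """Brute-force upper tail by enumerating every n-subset of an
    N-element universe whose first K elements are 'successes'."""
    universe = list(range(N))
    successes = set(range(K))
    hits = sum(1 for sub in combinations(universe, n)
               if len(successes.intersection(sub)) >= k)
    return hits / math.comb(N, n)


def hypergeom_tail_permutation(k: int, N: int, K: int, n: int,
                               n_draws: int, rng: np.random.Generator) -> tuple[float, float]:
    """Monte-Carlo upper tail from random n-subsets; returns (estimate,
    standard error)."""
    hits = 0
    universe = np.arange(N)
    for _ in range(n_draws):
        draw = rng.choice(universe, size=n, replace=False)
        if (draw < K).sum() >= k:
            hits += 1
    p = hits / n_draws
    se = math.sqrt(max(p * (1 - p), 1.0 / n_draws) / n_draws)
    return p, se


def bh_adjust_reference(pvals):
    """Textbook BH step-up, executed by a hand-followable rule."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = min(prev, pvals[i] * m / rank_from_top)
        q[i] = value
        prev = value
    return q
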
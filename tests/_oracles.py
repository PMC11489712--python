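"""Independent oracles used by the tests.

These deliberately avoid the package's own code paths: the fan bound is
checked against a dynamic program over all binary-tree leaf splits, the comb
bound against the caterpillar's literal depth sequence, the chi-square
statistic against the raw sum, and the Mann–Whitney exact p against direct
enumeration of rank interleavings.
"""

from functools import lru_cache
from itertools import combinations
from math import comb


@lru_cache(maxsize=None)
def min_external_path_length(n: int) -> int:
    """Minimum external path length of a binary tree with n leaves, by
    exhaustive DP over the root split."""
    if n == 1:
        return 0
    return n + min(
        min_external_path_length(k) + min_external_path_length(n - k) for k in range(1, n // 2 + 1)
    )


def min_mean_leaf_depth(n: int) -> float:
    return min_external_path_length(n) / n


def caterpillar_mean_depth(n: int) -> float:
    """Mean leaf depth of the caterpillar with n leaves: depths 1..n-1 plus
    a second leaf at depth n-1."""
    depths = list(range(1, n)) + [n - 1]
    return sum(depths) / n


def chi_square_stat(table) -> float:
    """Σ (O−E)²/E computed longhand from the margins."""
    rows = [sum(r) for r in table]
    cols = [sum(c) for c in zip(*table)]
    total = sum(rows)
    stat = 0.0
    for i, r in enumerate(table):
        for j, o in enumerate(r):
            e = rows[i] * cols[j] / total
            stat += (o - e) ** 2 / e
    return stat


def mwu_enumeration(a, b):
    """Exact Mann–Whitney: midranks on the pooled sample, U = min(U_a, U_b),
    p = proportion of all C(n, n_a) rank assignments with min-U ≤ observed."""
    pooled = sorted(list(a) + list(b))
    # midranks
    ranks = {}
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and pooled[j] == pooled[i]:
            j += 1
        mid = (i + 1 + j) / 2
        ranks[pooled[i]] = mid
        i = j
    rank_list = []
    # assign rank per position (ties share the midrank)
    for v in list(a) + list(b):
        rank_list.append(ranks[v])
    n_a, n = len(a), len(a) + len(b)
    n_b = n - n_a

    def u_of(idx):
        ra = sum(rank_list[i] for i in idx)
        ua = ra - n_a * (n_a + 1) / 2
        return min(ua, n_a * n_b - ua)

    obs = u_of(range(n_a))
    hits = sum(1 for idx in combinations(range(n), n_a) if u_of(idx) <= obs + 1e-12)
    return obs, hits / comb(n, n_a)
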
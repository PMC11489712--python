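"""Corpus-level statistics: group proportions and the survey test battery.

The survey-style questions these answer: what proportion of papers in each
insect order (or journal) include a key (Pearson chi-square across groups);
do two observed proportions differ (pooled two-proportion z); do two samples
of counts differ in location (Mann–Whitney U with midrank ties, exact for
small samples)?
"""

from __future__ import annotations

from itertools import combinations
from math import comb, sqrt

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import PaperMetadata

__all__ = [
    "proportions_by_group",
    "pearson_chi_square",
    "two_proportion_z",
    "mann_whitney_u",
    "corpus_to_frame",
]

#: column dictionary for corpus CSV, mirroring survey-style spreadsheets
CORPUS_COLUMNS = {
    "paper_id": "identifier",
    "journal": "journal (col. C)",
    "order": "insect order (col. D)",
    "has_key": "paper includes a key",
    "n_genera_in_key": "genera treated in the key (col. I)",
    "n_new_genera": "new genera described (col. H)",
    "n_new_genera_keyed": "new genera identifiable through the key",
}


def corpus_to_frame(corpus) -> pd.DataFrame:
    rows = []
    for m in corpus:
        if isinstance(m, PaperMetadata):
            rows.append(dict(m.__dict__))
        else:
            rows.append(dict(m))
    return pd.DataFrame(rows)


def proportions_by_group(corpus, group_field: str, pool_threshold: int = 20) -> pd.DataFrame:
    """Per-group counts and proportions of papers with keys.

    Groups with at most ``pool_threshold`` papers are pooled into
    ``"other"`` (the usual convention of analysing only frequently
    represented orders/journals separately; the threshold is configuration,
    not dogma).  Genus columns count each paper's genera once regardless of
    how many keys it contains.
    """
    df = corpus_to_frame(corpus)
    if group_field not in df.columns:
        raise KeyError(f"no such metadata field: {group_field}")
    sizes = df.groupby(group_field).size()
    small = set(sizes[sizes <= pool_threshold].index)
    grp = df[group_field].where(~df[group_field].isin(small), "other")
    out = (
        df.assign(_group=grp)
        .groupby("_group")
        .agg(
            n_papers=("paper_id", "size"),
            n_with_key=("has_key", "sum"),
            n_new_genera=("n_new_genera", "sum"),
            n_new_genera_keyed=("n_new_genera_keyed", "sum"),
        )
        .reset_index()
        .rename(columns={"_group": "group"})
    )
    out["prop"] = out["n_with_key"] / out["n_papers"]
    return out[["group", "n_papers", "n_with_key", "prop", "n_new_genera", "n_new_genera_keyed"]]


def pearson_chi_square(table, yates: bool = False):
    """Pearson chi-square test of independence on an r×c count table.

    Returns ``(statistic, df, p)``.  No continuity correction by default;
    Yates' correction is available for 2×2 tables via ``yates=True``.
    All expected counts must be positive.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    with np.errstate(invalid="ignore", divide="ignore"):
        expected = sps.contingency.expected_freq(table)
    if not np.all(expected > 0):
        raise ValueError("all expected counts must be positive")
    stat, p, df, _ = sps.chi2_contingency(table, correction=yates)
    return float(stat), int(df), float(p)


def two_proportion_z(x1: int, n1: int, x2: int, n2: int):
    """Pooled two-proportion z test.

    ``z = (p1 − p2) / sqrt(p̂(1−p̂)(1/n1 + 1/n2))`` with
    ``p̂ = (x1+x2)/(n1+n2)``; the p value is two-sided from the normal tail.
    Swapping the groups negates z and leaves p unchanged.
    """
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2) or n1 == 0 or n2 == 0:
        raise ValueError("need 0 <= x <= n with n > 0 for both groups")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if var == 0:
        return 0.0, 1.0
    z = (p1 - p2) / sqrt(var)
    return float(z), float(2 * sps.norm.sf(abs(z)))


_EXACT_LIMIT = 12


def _u_from_ranks(rank_sum_a: float, n_a: int, n_b: int):
    u_a = rank_sum_a - n_a * (n_a + 1) / 2
    return u_a, n_a * n_b - u_a


def mann_whitney_u(sample_a, sample_b):
    """Mann–Whitney U with midrank ties.

    Reports ``U = min(U_a, U_b)``.  For combined samples of at most 12
    observations the two-sided p value is exact — the proportion of all
    ``C(n_a+n_b, n_a)`` assignments of the pooled (mid)ranks whose min-U is
    at least as extreme as observed — which remains valid under ties.
    Larger samples use the normal approximation with tie correction and a
    0.5 continuity correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    n_a, n_b = len(a), len(b)
    if n_a == 0 or n_b == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_a, u_b = _u_from_ranks(ranks[:n_a].sum(), n_a, n_b)
    u = min(u_a, u_b)

    n = n_a + n_b
    if n <= _EXACT_LIMIT:
        count = 0
        total = comb(n, n_a)
        for idx in combinations(range(n), n_a):
            ua, ub = _u_from_ranks(ranks[list(idx)].sum(), n_a, n_b)
            if min(ua, ub) <= u + 1e-12:
                count += 1
        return float(u), count / total

    # normal approximation with tie correction
    mu = n_a * n_b / 2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = n_a * n_b / 12 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return float(u), 1.0
    z = (u - mu + 0.5) / sqrt(sigma2)
    return float(u), float(min(1.0, 2 * sps.norm.sf(abs(z))))
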
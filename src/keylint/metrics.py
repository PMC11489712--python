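"""Path-length statistics for identification keys.

A dichotomous key is a rooted binary tree whose leaves are taxa; the number
of couplets a user traverses to reach a taxon (the deciding couplet counts,
so the root contributes 1) is the taxon's path length.  For ``n`` taxa the
mean path length is bounded between two extreme topologies:

* the *comb* (caterpillar) — maximally unbalanced, one taxon keys out at
  every couplet — with mean ``S_max = (n+1)/2 − 1/n``;
* the *fan* — as balanced as a binary tree can be — with mean
  ``S_min = (Q·(2^Q − x) + (Q+1)·2x)/n`` where ``Q = ⌊log2 n⌋`` and
  ``x = n − 2^Q``.  When ``n`` is a power of two this collapses to
  ``S_min = Q = log2 n``.

The fan bound is the minimum external path length of a binary tree with
``n`` leaves divided by ``n``; the comb bound is the caterpillar's mean leaf
depth.  Mean path length therefore grows linearly with ``n`` for comb-shaped
keys but only logarithmically for fan-shaped ones — the practical reason to
prefer balanced keys.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .model import Couplet, Key, KeyGraph, KeyMetrics, Lead, build_graph, normalize_taxon

__all__ = [
    "mean_steps_comb",
    "mean_steps_fan",
    "compute_metrics",
    "couplet_count_discrepancy",
    "prune_to_taxa",
    "metrics_to_frame",
]

_TOL = 1e-9


def _check_n(n: int) -> int:
    n = int(n)
    if n < 2:
        raise ValueError("a key needs at least two taxa")
    return n


def mean_steps_comb(n: int) -> float:
    """Mean couplets to an identification in a fully comb-shaped key of
    ``n`` taxa: ``(n+1)/2 − 1/n``.  Path lengths run 1, 2, …, n−1, n−1."""
    n = _check_n(n)
    return (n + 1) / 2 - 1 / n


def mean_steps_fan(n: int) -> float:
    """Mean couplets to an identification in a maximally fan-shaped key of
    ``n`` taxa.

    With ``Q = ⌊log2 n⌋`` and ``x = n − 2^Q``, the balanced tree has
    ``2^Q − x`` leaves at depth ``Q`` and ``2x`` at depth ``Q+1``, giving
    ``(Q·(2^Q − x) + (Q+1)·2x)/n`` — exactly ``Q`` when ``x = 0``.
    """
    n = _check_n(n)
    q, x = fan_q_x(n)
    return (q * (2**q - x) + (q + 1) * 2 * x) / n


def fan_q_x(n: int) -> tuple:
    """``(Q, x)`` of the fan formula: Q = ⌊log2 n⌋ (via bit length, exact for
    any integer), x = n − 2^Q."""
    n = _check_n(n)
    q = n.bit_length() - 1
    return q, n - 2**q


def compute_metrics(key: Key, graph: Optional[KeyGraph] = None) -> KeyMetrics:
    """Compute :class:`KeyMetrics` for a key.

    ``s_actual`` averages per taxon first: a taxon keying out more than once
    contributes the mean of its path lengths, and the key-level mean is over
    distinct taxa.  Keys with loops have no well-defined per-taxon path, so
    ``s_actual`` is left unset and the key is flagged rather than guessed at.
    ``s_min``/``s_max`` are only filled for strictly dichotomous keys with a
    clean graph — the closed forms rely on every couplet being dichotomous.
    """
    if graph is None:
        graph = build_graph(key)
    taxa = key.taxa()
    n = len(taxa)
    m = KeyMetrics(
        key_id=key.key_id,
        n_taxa=n,
        n_couplets=len(key.couplets),
        n_couplets_expected=n - 1,
    )
    depths = graph.all_depths()
    if depths:
        m.depth_range = (depths[0], depths[-1])
    if not graph.has_loop and graph.taxon_paths:
        per_taxon = [sum(ds) / len(ds) for ds in graph.taxon_paths.values()]
        m.s_actual = sum(per_taxon) / len(per_taxon)
    if n >= 2:
        m.q, m.x = fan_q_x(n)
        if key.is_strictly_dichotomous and graph.is_clean:
            m.s_max = mean_steps_comb(n)
            m.s_min = mean_steps_fan(n)
    if m.s_min is not None and m.s_actual is not None:
        m.is_max_fan = abs(m.s_actual - m.s_min) < _TOL
    return m


def couplet_count_discrepancy(key: Key) -> int:
    """Observed couplets minus the ``n − 1`` expected for ``n`` taxa.

    Positive values arise when taxa key out repeatedly; negative ones when
    couplets are polychotomous.
    """
    return len(key.couplets) - (len(key.taxa()) - 1)


def prune_to_taxa(key: Key, keep) -> Key:
    """Restrict a key to the couplets that eventually lead to a kept taxon.

    Published keys sometimes mix ranks (tribes, subgenera, species) among
    their terminals; numerical analysis should only see couplets that lead to
    the rank of interest.  Leads keying out a dropped taxon are kept in place
    (the couplet still exists on the user's path) but couplets none of whose
    descendants are kept are removed, with references to them rewired past
    the removed subtree when possible.

    Implemented as a leaf-up sweep: a couplet survives iff any lead keys out
    a kept taxon or targets a surviving couplet.  A lead targeting a dead
    couplet is rewritten to key out a placeholder that is then dropped from
    taxon statistics by virtue of not being in ``keep``.
    """
    keep = {normalize_taxon(t) for t in keep}
    alive: dict = {}
    # iterate until fixpoint (documents can reference forward)
    changed = True
    by_number = {}
    for c in key.couplets:
        by_number.setdefault(c.number, c)
    while changed:
        changed = False
        for c in key.couplets:
            live = False
            for ld in c.leads:
                if ld.is_terminal and normalize_taxon(ld.target_taxon) in keep:
                    live = True
                elif not ld.is_terminal and alive.get(ld.target_couplet):
                    live = True
            if live and not alive.get(c.number):
                alive[c.number] = True
                changed = True
    new_couplets = []
    for c in key.couplets:
        if not alive.get(c.number):
            continue
        leads = []
        for ld in c.leads:
            if not ld.is_terminal and not alive.get(ld.target_couplet):
                # subtree removed entirely: the lead keys out a placeholder
                # that, not being in `keep`, stays outside taxon statistics
                leads.append(
                    Lead(
                        ordinal=ld.ordinal,
                        features=list(ld.features),
                        target_taxon="Excluded",
                        figure_refs=list(ld.figure_refs),
                        ancillary=ld.ancillary,
                    )
                )
            else:
                leads.append(ld)
        new_couplets.append(Couplet(number=c.number, leads=leads, retrace_ref=c.retrace_ref))
    if not new_couplets:
        raise ValueError("no couplet leads to any kept taxon")
    return Key(
        key_id=key.key_id,
        title=key.title,
        scope=key.scope,
        style=key.style,
        couplets=new_couplets,
    )


def metrics_to_frame(metrics) -> pd.DataFrame:
    """One row per key, columns matching :class:`KeyMetrics` fields."""
    rows = []
    for m in metrics:
        d = dict(m.__dict__)
        dr = d.pop("depth_range")
        d["depth_min"] = dr[0] if dr else None
        d["depth_max"] = dr[1] if dr else None
        rows.append(d)
    return pd.DataFrame(rows)
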
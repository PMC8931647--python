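"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's own counting/AUC code paths: the
matrix oracle is a double loop over patients and item pairs, and the AUC
oracle is the literal mean over all positive-negative score pairs.
"""

from __future__ import annotations

import numpy as np


def brute_force_matrix(episodes):
    """Counts by explicit enumeration over (patient, query item, target item)."""
    query_counts, target_counts, pair_counts = {}, {}, {}
    all_queries = set()
    all_targets = set()
    for ep in episodes:
        all_queries |= set(ep.query_items)
        all_targets |= set(ep.target_items)
    for a in all_queries:
        n = 0
        for ep in episodes:
            if a in ep.query_items:
                n += 1
        query_counts[a] = n
    for b in all_targets:
        n = 0
        for ep in episodes:
            if b in ep.target_items:
                n += 1
        target_counts[b] = n
    for a in all_queries:
        for b in all_targets:
            n = 0
            for ep in episodes:
                if a in ep.query_items and b in ep.target_items:
                    n += 1
            if n:
                pair_counts[(a, b)] = n
    return len(episodes), query_counts, target_counts, pair_counts


def pairwise_auc(scores, labels) -> float:
    """AUC as the mean of 1[s+ > s-] + 0.5 * 1[s+ = s-] over all pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need both classes")
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))
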
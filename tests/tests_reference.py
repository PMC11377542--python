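"""Naive exhaustive reference implementations of the screening metrics.

Kept deliberately independent of the package implementation: plain-Python
O(n^2) pair counting and sort-and-walk scans, used as oracles by the tests.
"""

import math


def brute_force_auc(labels, goodness):
    """Exhaustive pair counting over all active-decoy pairs (ties = 1/2)."""
    actives = [g for l, g in zip(labels, goodness) if l == 1]
    decoys = [g for l, g in zip(labels, goodness) if l == 0]
    wins = 0.0
    for a in actives:
        for d in decoys:
            if a > d:
                wins += 1.0
            elif a == d:
                wins += 0.5
    return wins / (len(actives) * len(decoys))


def brute_force_ef(labels, goodness, ids, x_percent):
    """Sorted top-window active rate over the overall active rate."""
    n = len(labels)
    k = math.ceil(x_percent / 100.0 * n)
    order = sorted(range(n), key=lambda i: (-goodness[i], ids[i]))
    hits = sum(labels[i] for i in order[:k])
    return (hits / sum(labels)) / (x_percent / 100.0)


def brute_force_roce(labels, goodness, ids, fpr_percent):
    """Walk the ranking until the whole-decoy FPR threshold is crossed."""
    n_decoys = len(labels) - sum(labels)
    k_decoys = math.ceil(fpr_percent / 100.0 * n_decoys)
    order = sorted(range(len(labels)), key=lambda i: (-goodness[i], ids[i]))
    actives_seen = decoys_seen = 0
    for i in order:
        if labels[i]:
            actives_seen += 1
        else:
            decoys_seen += 1
            if decoys_seen >= k_decoys:
                break
    return (actives_seen / sum(labels)) / (fpr_percent / 100.0)
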
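"""Deliberately naive reference implementations used only by tests.

Everything here is written as plain Python loops straight from the
definitions, independent of the vectorised package code it checks.
"""

from __future__ import annotations

import math


def oracle_leave_one_out_consensus(labels, excluded, n_classes):
    """z^j by direct counting.  labels: T x J lists of codes (<0 invalid)."""
    T = len(labels)
    z = [[0.0] * T for _ in range(n_classes)]
    valid = [False] * T
    for t in range(T):
        counts = [0] * n_classes
        for j, lab in enumerate(labels[t]):
            if j != excluded and lab >= 0:
                counts[lab] += 1
        mx = max(counts)
        if mx > 0:
            valid[t] = True
            for k in range(n_classes):
                z[k][t] = counts[k] / mx
    return z, valid


def oracle_soft_agreement(labels, j, n_classes):
    """Mean of z^j at scorer j's own labels over contributing epochs."""
    z, valid = oracle_leave_one_out_consensus(labels, j, n_classes)
    total, count = 0.0, 0
    for t in range(len(labels)):
        own = labels[t][j]
        if own >= 0 and valid[t]:
            total += z[own][t]
            count += 1
    if count == 0:
        return None
    return total / count


def oracle_soft_consensus(labels, n_classes):
    """Occurrences over observations, per epoch."""
    out = []
    for row in labels:
        votes = [lab for lab in row if lab >= 0]
        assert votes, "oracle requires >= 1 valid label per epoch"
        out.append([sum(1 for v in votes if v == k) / len(votes)
                    for k in range(n_classes)])
    return out


def oracle_ece(confidences, correct, n_bins):
    """Per-sample loop over bins ((m-1)/M, m/M]; conf 0 goes to bin 1."""
    n = len(confidences)
    total = 0.0
    for m in range(1, n_bins + 1):
        lo, hi = (m - 1) / n_bins, m / n_bins
        members = [i for i, c in enumerate(confidences)
                   if (lo < c <= hi) or (m == 1 and c == 0.0)]
        if not members:
            continue
        acc = sum(1 for i in members if correct[i]) / len(members)
        conf = sum(confidences[i] for i in members) / len(members)
        total += (len(members) / n) * abs(acc - conf)
    return total


def oracle_cosine(u, v):
    dot = sum(a * b for a, b in zip(u, v))
    nu = math.sqrt(sum(a * a for a in u))
    nv = math.sqrt(sum(b * b for b in v))
    return dot / (nu * nv)
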
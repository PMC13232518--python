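"""Independent brute-force oracles used to validate the package's
statistics. These deliberately share no code with the implementation."""

from __future__ import annotations

from math import comb

import numpy as np


def auprc_bruteforce(scores, labels) -> float:
    """Step-wise average precision by explicit iteration over every
    distinct threshold (descending)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = labels.sum()
    thresholds = sorted(set(scores), reverse=True)
    area = 0.0
    prev_recall = 0.0
    for t in thresholds:
        called = scores >= t
        tp = int(np.sum(called & (labels == 1)))
        fp = int(np.sum(called & (labels == 0)))
        precision = tp / (tp + fp)
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def hypergeom_pmf(k, M, n, N) -> float:
    """P(X = k) drawing N from M with n successes."""
    if k < max(0, N - (M - n)) or k > min(n, N):
        return 0.0
    return comb(n, k) * comb(M - n, N - k) / comb(M, N)


def fisher_greater_enumeration(a, b, c, d) -> float:
    """One-sided Fisher p by enumerating all tables with fixed margins."""
    M = a + b + c + d
    row1 = a + b          # motif-present total
    col1 = a + c          # condition-specific total
    if M == 0:
        return 1.0
    return sum(
        hypergeom_pmf(k, M, row1, col1)
        for k in range(a, min(row1, col1) + 1)
    )


def hypergeom_sf_enumeration(M, n, k, x) -> float:
    """P(X >= x) by summing point masses."""
    return sum(hypergeom_pmf(j, M, n, k) for j in range(x, min(n, k) + 1))


def bh_textbook(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up, written from the textbook definition."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adj[i] = running_min
    return np.minimum(adj, 1.0)


def merge_unionfind(labeled):
    """Merge >=1 bp-overlapping intervals by union-find over all pairs.

    ``labeled``: list of ((chrom, start, end), label). Returns a set of
    (chrom, start, end, frozenset(labels)).
    """
    items = list(labeled)
    parent = list(range(len(items)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i in range(len(items)):
        (ci, si, ei), _ = items[i]
        for j in range(i + 1, len(items)):
            (cj, sj, ej), _ = items[j]
            if ci == cj and si < ej and sj < ei:
                union(i, j)
    groups = {}
    for i, ((c, s, e), label) in enumerate(items):
        groups.setdefault(find(i), []).append((c, s, e, label))
    out = set()
    for members in groups.values():
        out.add((
            members[0][0],
            min(m[1] for m in members),
            max(m[2] for m in members),
            frozenset(m[3] for m in members),
        ))
    return out


def abc_loop(pairs, activity, contact, pseudocount=1e-6):
    """ABC scores by explicit per-gene loops."""
    act = {r.cre_id: (r.dnase, r.h3k27ac) for r in activity.itertuples(index=False)}
    out = []
    for row in pairs.itertuples(index=False):
        genes_pairs = pairs[pairs["gene_id"] == row.gene_id]
        total = 0.0
        for other in genes_pairs.itertuples(index=False):
            dn, ac = act[other.cre_id]
            cc = contact.get((other.cre_id, other.gene_id), 0.0)
            total += np.sqrt(dn * ac) * (cc if cc > 0 else pseudocount)
        dn, ac = act[row.cre_id]
        cc = contact.get((row.cre_id, row.gene_id), 0.0)
        num = np.sqrt(dn * ac) * (cc if cc > 0 else pseudocount)
        out.append(num / total if total > 0 else 0.0)
    return np.array(out)


def spearman_midrank(x, y) -> float:
    """Pearson correlation of average ranks, hand-rolled."""

    def midranks(v):
        v = np.asarray(v, dtype=float)
        ranks = np.empty(len(v))
        order = np.argsort(v, kind="stable")
        sv = v[order]
        i = 0
        while i < len(sv):
            j = i
            while j + 1 < len(sv) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))
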
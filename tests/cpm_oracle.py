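"""Exhaustive CPM optimization oracle for small graphs.

Enumerates every set partition (restricted-growth strings) and scores
Q(partition) = sum_c [ e_c - gamma * n_c (n_c - 1) / 2 ], the CPM objective
on an unweighted graph. Independent of the package's community detection.
"""

from __future__ import annotations

from itertools import combinations


def set_partitions(n: int):
    """Yield partitions of range(n) as tuples of block indices (RGS)."""
    rgs = [0] * n
    maxes = [0] * n

    while True:
        yield tuple(rgs)
        # next restricted growth string
        i = n - 1
        while i > 0:
            if rgs[i] <= maxes[i - 1]:
                rgs[i] += 1
                maxes[i] = max(maxes[i - 1], rgs[i])
                for j in range(i + 1, n):
                    rgs[j] = 0
                    maxes[j] = maxes[i]
                break
            i -= 1
        else:
            return


def cpm_quality(rgs, edges, gamma: float) -> float:
    intra = sum(1 for a, b in edges if rgs[a] == rgs[b])
    sizes: dict[int, int] = {}
    for block in rgs:
        sizes[block] = sizes.get(block, 0) + 1
    pairs = sum(s * (s - 1) // 2 for s in sizes.values())
    return intra - gamma * pairs


def brute_force_cpm(n: int, edges, gammas):
    """For each gamma return (max quality, set of optimal partitions).

    Partitions are canonicalized to frozensets of frozensets.
    """
    edges = [tuple(e) for e in edges]
    stats = []  # (rgs, intra, pairs)
    for rgs in set_partitions(n):
        intra = sum(1 for a, b in edges if rgs[a] == rgs[b])
        sizes: dict[int, int] = {}
        for block in rgs:
            sizes[block] = sizes.get(block, 0) + 1
        pairs = sum(s * (s - 1) // 2 for s in sizes.values())
        stats.append((rgs, intra, pairs))

    out = {}
    for gamma in gammas:
        best_q = max(intra - gamma * pairs for _, intra, pairs in stats)
        optima = set()
        for rgs, intra, pairs in stats:
            if intra - gamma * pairs >= best_q - 1e-9:
                blocks: dict[int, list[int]] = {}
                for i, b in enumerate(rgs):
                    blocks.setdefault(b, []).append(i)
                optima.add(frozenset(frozenset(v) for v in blocks.values()))
        out[gamma] = (best_q, optima)
    return out


def canonical(partition) -> frozenset:
    return frozenset(frozenset(c) for c in partition)


def clique_edges(nodes):
    return list(combinations(nodes, 2))
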
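"""Shared fixture generator: random additive trees with known topology."""
import numpy as np


def random_additive_tree(n, rng):
    """Random unrooted binary tree with branch lengths in [0.1, 1.0].

    Returns (taxa labels, leaf-to-leaf path-distance matrix, set of true
    non-trivial bipartitions normalized away from taxon L0).
    """
    graph = {i: [] for i in range(n)}
    next_id = n
    active = list(range(n))
    while len(active) > 3:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        parent = next_id
        next_id += 1
        graph[parent] = []
        for child in (a, b):
            w = float(rng.uniform(0.1, 1.0))
            graph[parent].append((child, w))
            graph[child].append((parent, w))
        active = [x for x in active if x not in (a, b)] + [parent]
    root = next_id
    graph[root] = []
    for child in active:
        w = float(rng.uniform(0.1, 1.0))
        graph[root].append((child, w))
        graph[child].append((root, w))

    def dist_from(src):
        seen = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in graph[u]:
                if v not in seen:
                    seen[v] = seen[u] + w
                    stack.append(v)
        return seen

    d = np.zeros((n, n))
    for i in range(n):
        seen = dist_from(i)
        for j in range(n):
            d[i, j] = seen[j]
    np.fill_diagonal(d, 0.0)

    def leaves_below(u, parent):
        if u < n:
            return {u}
        out = set()
        for v, _ in graph[u]:
            if v != parent:
                out |= leaves_below(v, u)
        return out

    bips = set()
    all_leaves = frozenset(range(n))
    for u in graph:
        for v, _ in graph[u]:
            side = frozenset(leaves_below(v, u))
            if 2 <= len(side) <= n - 2:
                norm = side if 0 not in side else all_leaves - side
                bips.add(frozenset(f"L{x}" for x in norm))
    return [f"L{i}" for i in range(n)], d, bips
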
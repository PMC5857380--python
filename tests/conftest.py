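import warnings

import numpy as np
import pytest

from kmlst.profiles import load_packaged_profiles
from kmlst.scheme import load_scheme


@pytest.fixture(scope="session")
def scheme():
    """Packaged five-locus K. marxianus scheme (known warnings silenced)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return load_scheme("kmarxianus")


@pytest.fixture(scope="session")
def table3():
    """The packaged 83-strain profile database."""
    return load_packaged_profiles()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_unrooted_tree(n_leaves, rng, min_bl=0.5, max_bl=2.0):
    """Random unrooted binary tree by random edge attachment.

    Returns (labels, distance_matrix, split_weights) where split_weights
    maps each edge's leaf bipartition (canonical smaller side, ties by
    sorted labels) to its branch length. Independent oracle for NJ and
    split decomposition: built as an explicit graph, distances by DFS.
    """
    assert n_leaves >= 3
    g: dict[int, dict[int, float]] = {}

    def add_edge(u, v, w):
        g.setdefault(u, {})[v] = w
        g.setdefault(v, {})[u] = w

    leaf_ids = [0, 1]
    add_edge(0, 1, float(rng.uniform(min_bl, max_bl)))
    next_id = 2
    for _ in range(n_leaves - 2):
        edges = [(u, v) for u in g for v in g[u] if u < v]
        u, v = edges[int(rng.integers(len(edges)))]
        w = g[u][v]
        frac = float(rng.uniform(0.3, 0.7))
        del g[u][v]
        del g[v][u]
        mid = next_id
        next_id += 1
        add_edge(u, mid, w * frac)
        add_edge(mid, v, w * (1 - frac))
        leaf = next_id
        next_id += 1
        add_edge(mid, leaf, float(rng.uniform(min_bl, max_bl)))
        leaf_ids.append(leaf)

    labels = [f"t{i}" for i in range(n_leaves)]
    label_of = dict(zip(leaf_ids, labels))
    # all-pairs distances by DFS from each leaf
    n = n_leaves
    D = np.zeros((n, n))
    for a, src in enumerate(leaf_ids):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, w in g[x].items():
                if y not in dist:
                    dist[y] = dist[x] + w
                    stack.append(y)
        for b, dst in enumerate(leaf_ids):
            D[a, b] = dist[dst]
    D = (D + D.T) / 2  # exact symmetry despite float summation order
    # splits from edges
    all_leaves = frozenset(labels)

    def component_leaves(start, banned_edge):
        seen = {start}
        stack = [start]
        while stack:
            x = stack.pop()
            for y in g[x]:
                if (x, y) == banned_edge or (y, x) == banned_edge:
                    continue
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return frozenset(label_of[i] for i in seen if i in label_of)

    splits = {}
    for u in g:
        for v in g[u]:
            if u < v:
                side = component_leaves(u, (u, v))
                key = min(side, all_leaves - side,
                          key=lambda s: (len(s), sorted(s)))
                splits[key] = splits.get(key, 0.0) + g[u][v]
    return labels, D, splits


def random_ultrametric(n_leaves, rng):
    """Random ultrametric distance matrix via agglomeration at strictly
    increasing heights (cophenetic oracle for UPGMA)."""
    labels = [f"u{i}" for i in range(n_leaves)]
    clusters = [{i} for i in range(n_leaves)]
    D = np.zeros((n_leaves, n_leaves))
    h = 0.0
    while len(clusters) > 1:
        h += float(rng.uniform(0.5, 1.5))
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        for a in clusters[i]:
            for b in clusters[j]:
                D[a, b] = D[b, a] = 2 * h
        clusters[i] |= clusters[j]
        del clusters[j]
    return labels, D
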
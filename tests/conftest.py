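"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive re-derivations (literal counting,
O(n^3) loops, brute-force enumeration) kept independent of the package's
implementation paths, so agreement is evidence rather than tautology.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from barcodeaudit.records import Dataset, SpecimenRecord

_PURINE = {"A", "G"}
_PYRIMIDINE = {"C", "T"}
_BASES = "ACGT"


def make_record(sid, genus="Genus", species="alpha", seq="ACGT", region="BC"):
    return SpecimenRecord(
        specimen_id=sid, genus=genus, species=species, region=region, sequence=seq
    )


def make_dataset(rows):
    """rows: iterable of (specimen_id, genus, species, sequence)."""
    return Dataset.from_records(
        make_record(sid, genus=g, species=sp, seq=seq) for sid, g, sp, seq in rows
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20110328)


def random_sequence(rng, length):
    return "".join(rng.choice(list(_BASES), size=length))


def mutate(rng, seq, n_transitions=0, n_transversions=0, n_ambiguous=0):
    """Apply exact numbers of transitions/transversions/N-maskings at
    distinct random positions."""
    ts_map = {"A": "G", "G": "A", "C": "T", "T": "C"}
    tv_map = {"A": "C", "G": "T", "C": "G", "T": "A"}
    pos = rng.choice(len(seq), size=n_transitions + n_transversions + n_ambiguous,
                     replace=False)
    out = list(seq)
    for p in pos[:n_transitions]:
        out[p] = ts_map[out[p]]
    for p in pos[n_transitions:n_transitions + n_transversions]:
        out[p] = tv_map[out[p]]
    for p in pos[n_transitions + n_transversions:]:
        out[p] = "N"
    return "".join(out)


# ----------------------------------------------------------------------------
# K2P oracle: literal site-by-site counting + closed form.

def k2p_oracle(seq_a: str, seq_b: str):
    ts = tv = sites = 0
    for a, b in zip(seq_a, seq_b):
        if a not in _BASES or b not in _BASES:
            continue
        sites += 1
        if a == b:
            continue
        if (a in _PURINE) == (b in _PURINE):
            ts += 1
        else:
            tv += 1
    p, q = ts / sites, tv / sites
    return -0.5 * math.log((1 - 2 * p - q) * math.sqrt(1 - 2 * q)), sites


# ----------------------------------------------------------------------------
# Naive NJ oracle: plain-Python O(n^3), tracking splits and branch lengths.

def nj_oracle(D: np.ndarray, ids: list[str]):
    """Returns {frozenset(one side of split): branch length} over all edges,
    sides expressed relative to the full leaf set.  Mirrors the documented
    conventions: first-minimum tie-break, negative branches clamped to zero
    with the deficit moved to the sibling edge."""
    n = len(ids)
    D = [[float(D[i][j]) for j in range(n)] for i in range(n)]
    groups = [frozenset([i]) for i in range(n)]
    splits: dict[frozenset, float] = {}
    full = frozenset(range(n))

    def clamp(vi, vj):
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        return max(vi, 0.0), max(vj, 0.0)

    while len(groups) > 3:
        r = len(D)
        rows = [sum(row) for row in D]
        best, bi, bj = None, None, None
        for i in range(r):
            for j in range(i + 1, r):
                q = (r - 2) * D[i][j] - rows[i] - rows[j]
                if best is None or q < best:
                    best, bi, bj = q, i, j
        i, j = bi, bj
        dij = D[i][j]
        vi = 0.5 * dij + (rows[i] - rows[j]) / (2 * (r - 2))
        vj = dij - vi
        vi, vj = clamp(vi, vj)
        splits[groups[i]] = splits.get(groups[i], 0.0) + vi
        splits[groups[j]] = splits.get(groups[j], 0.0) + vj
        new_row = [0.5 * (D[i][k] + D[j][k] - dij) for k in range(r)]
        merged = groups[i] | groups[j]
        keep = [k for k in range(r) if k not in (i, j)]
        D = [[D[a][b] for b in keep] + [new_row[a]] for a in keep]
        D.append([new_row[b] for b in keep] + [0.0])
        groups = [groups[k] for k in keep] + [merged]

    if len(groups) == 3:
        a = 0.5 * (D[0][1] + D[0][2] - D[1][2])
        b = 0.5 * (D[0][1] + D[1][2] - D[0][2])
        c = 0.5 * (D[0][2] + D[1][2] - D[0][1])
        for g, v in zip(groups, (a, b, c)):
            splits[g] = splits.get(g, 0.0) + max(v, 0.0)
    else:  # n == 2
        splits[groups[0]] = D[0][1]

    # canonicalize: drop the full set; merge a split with its complement
    canon: dict[frozenset, float] = {}
    for g, v in splits.items():
        if g == full:
            continue
        key = min(g, full - g, key=lambda s: (len(s), sorted(s)))
        canon[key] = canon.get(key, 0.0) + v
    return {frozenset(ids[i] for i in g): v for g, v in canon.items()}


def tree_splits(tree):
    """Same canonical {split side: branch length} map from a dendropy tree."""
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    full = frozenset(labels)
    canon: dict[frozenset, float] = {}
    for nd in tree.postorder_node_iter():
        if nd is tree.seed_node:
            continue
        below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        key = min(below, full - below, key=lambda s: (len(s), sorted(s)))
        canon[key] = canon.get(key, 0.0) + (nd.edge.length or 0.0)
    return canon


def random_additive_tree(rng, n):
    """Random binary tree shape with uniform branch lengths; returns
    (ids, distance matrix, canonical split set)."""
    ids = [f"L{i}" for i in range(n)]
    # Build by sequential attachment: maintain leaf-to-leaf path distances.
    # Represent tree as adjacency with branch lengths over node indices.
    adj: dict[int, dict[int, float]] = {0: {}, 1: {}}
    w = float(rng.uniform(0.1, 1.0))
    adj[0][1] = w
    adj[1][0] = w
    next_node = 2
    leaves = [0, 1]
    for _ in range(n - 2):
        # pick a random edge, split it, hang a new leaf
        edges = [(a, b) for a in adj for b in adj[a] if a < b]
        a, b = edges[rng.integers(len(edges))]
        mid, leaf = next_node, next_node + 1
        next_node += 2
        wab = adj[a].pop(b)
        adj[b].pop(a)
        cut = float(rng.uniform(0.2, 0.8)) * wab
        adj.setdefault(mid, {})
        adj[a][mid] = cut
        adj[mid][a] = cut
        adj[mid][b] = wab - cut
        adj[b][mid] = wab - cut
        wl = float(rng.uniform(0.1, 1.0))
        adj.setdefault(leaf, {})
        adj[mid][leaf] = wl
        adj[leaf][mid] = wl
        leaves.append(leaf)
    # path distances by BFS from each leaf
    import collections
    idx = {nd: k for k, nd in enumerate(leaves)}
    D = np.zeros((n, n))
    for src in leaves:
        dist = {src: 0.0}
        dq = collections.deque([src])
        while dq:
            u = dq.popleft()
            for v, w_ in adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w_
                    dq.append(v)
        for dst in leaves:
            D[idx[src], idx[dst]] = dist[dst]
    # canonical splits: remove each edge, collect leaf side
    full = frozenset(ids)
    splits = {}
    for a in adj:
        for b in adj[a]:
            if a > b:
                continue
            seen = {a}
            dq = collections.deque([a])
            while dq:
                u = dq.popleft()
                for v in adj[u]:
                    if (u, v) == (a, b):
                        continue
                    if v not in seen:
                        seen.add(v)
                        dq.append(v)
            side = frozenset(ids[idx[l]] for l in leaves if l in seen)
            key = min(side, full - side, key=lambda s: (len(s), sorted(s)))
            splits[key] = splits.get(key, 0.0) + adj[a][b]
    return ids, D, splits
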
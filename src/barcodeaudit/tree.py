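"""Neighbour-joining tree construction, rooting and Newick output.

Classic agglomerative NJ: at each step join the active pair (i, j)
minimizing

    Q(i, j) = (r - 2) * d(i, j) - sum_k d(i, k) - sum_k d(j, k)

over the r active nodes, with branch lengths

    v_i = d(i, j) / 2 + (sum_k d(i, k) - sum_k d(j, k)) / (2 (r - 2))

and reduced distances d(u, k) = (d(i, k) + d(j, k) - d(i, j)) / 2.  For an
additive input matrix the unrooted result reproduces every leaf-to-leaf
path length exactly.

Determinism: when several pairs tie on Q, the lexicographically smallest
(i, j) in the current active-node order is joined.  Negative branch
lengths, which NJ can produce on noisy matrices, are clamped to zero with
the deficit transferred to the sibling edge (path lengths through the new
node are preserved); each clamp is logged at DEBUG level.

Trees are dendropy objects whose leaf taxa are labelled with specimen IDs,
so all of dendropy's traversal, bipartition and serialization machinery
applies downstream.
"""

from __future__ import annotations

import logging
from pathlib import Path

import dendropy
import numpy as np

from .distance import DistanceMatrix
from .errors import RootingError, ValidationError
from .records import Dataset

logger = logging.getLogger(__name__)


def _clamped(vi: float, vj: float, pair: str) -> tuple[float, float]:
    # Clamp negatives to 0, moving the deficit to the sibling edge so the
    # i--j path length is unchanged.
    if vi < 0.0:
        logger.debug("clamping negative branch %.6g at join %s", vi, pair)
        vj += vi
        vi = 0.0
    if vj < 0.0:
        logger.debug("clamping negative branch %.6g at join %s", vj, pair)
        vi += vj
        vj = 0.0
    return max(vi, 0.0), max(vj, 0.0)


def build_nj(m: DistanceMatrix) -> dendropy.Tree:
    """Build the unrooted neighbour-joining tree for a distance matrix."""
    n = len(m)
    if n < 2:
        raise ValidationError(f"neighbour joining needs >= 2 taxa, got {n}")

    tns = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    for sid in m.ids:
        nodes.append(dendropy.Node(taxon=tns.new_taxon(label=sid)))

    if n == 2:
        seed = dendropy.Node()
        half = float(m.d[0, 1]) / 2.0
        for nd in nodes:
            seed.add_child(nd)
            nd.edge.length = half
        tree = dendropy.Tree(taxon_namespace=tns, seed_node=seed)
        tree.is_rooted = False
        return tree

    D = np.array(m.d, dtype=np.float64)
    labels = list(m.ids)  # parallel to `nodes`, for log messages only
    while len(nodes) > 3:
        r = len(nodes)
        rowsum = D.sum(axis=1)
        Q = (r - 2) * D - rowsum[:, None] - rowsum[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # first minimum = lexicographically smallest (i, j)
        i, j = divmod(flat, r)
        if i > j:  # cannot happen with a symmetric Q, kept as a guard
            i, j = j, i

        dij = D[i, j]
        vi = 0.5 * dij + (rowsum[i] - rowsum[j]) / (2.0 * (r - 2))
        vj = dij - vi
        vi, vj = _clamped(vi, vj, f"({labels[i]},{labels[j]})")

        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = vi
        parent.add_child(nodes[j])
        nodes[j].edge.length = vj

        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        D[i, :] = dnew
        D[:, i] = dnew
        D[i, i] = 0.0
        keep = [k for k in range(r) if k != j]
        D = D[np.ix_(keep, keep)]
        nodes[i] = parent
        labels[i] = f"({labels[i]}+{labels[j]})"
        del nodes[j]
        del labels[j]

    # Final 3-node star: closed-form branches a = (d01 + d02 - d12)/2, etc.
    seed = dendropy.Node()
    a = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    b = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    c = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    for nd, v in zip(nodes, (a, b, c)):
        if v < 0.0:
            logger.debug("clamping negative terminal-star branch %.6g", v)
            v = 0.0
        seed.add_child(nd)
        nd.edge.length = float(v)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=seed)
    tree.is_rooted = False
    return tree


def leaf_labels(t: dendropy.Tree) -> set[str]:
    return {lf.taxon.label for lf in t.leaf_node_iter()}


def root_tree(t: dendropy.Tree, outgroup_ids: set[str]) -> dendropy.Tree:
    """Root a copy of ``t`` on the edge separating the outgroup from the rest.

    The root is placed at the midpoint of that edge.  The outgroup must be a
    strict, non-empty subset of the leaves and must sit on one side of a
    single edge; otherwise :class:`RootingError` is raised.
    """
    og = frozenset(outgroup_ids)
    leaves = leaf_labels(t)
    if not og:
        raise ValidationError("empty outgroup")
    unknown = og - leaves
    if unknown:
        raise ValidationError(f"outgroup IDs not in tree: {sorted(unknown)}")
    if og == leaves:
        raise ValidationError("outgroup cannot contain every leaf")

    t2 = t.clone(depth=1)
    if len(leaves) == 2:
        # the stored 2-leaf tree already has both leaves hanging off the
        # centre of their single edge; rooting there is the edge midpoint
        t2.is_rooted = True
        return t2
    below: dict[dendropy.Node, frozenset[str]] = {}
    for nd in t2.postorder_node_iter():
        if nd.is_leaf():
            below[nd] = frozenset((nd.taxon.label,))
        else:
            below[nd] = frozenset().union(*(below[c] for c in nd.child_nodes()))
    target = None
    for nd in t2.preorder_node_iter():
        if nd is t2.seed_node:
            continue
        if below[nd] == og or leaves - below[nd] == og:
            target = nd
            break
    if target is None:
        raise RootingError(
            f"outgroup {sorted(og)} is not separable by a single edge"
        )
    edge = target.edge
    half = (edge.length or 0.0) / 2.0
    t2.reroot_at_edge(edge, length1=half, length2=half)
    t2.is_rooted = True
    return t2


def midpoint_root(t: dendropy.Tree) -> dendropy.Tree:
    """Midpoint-root a copy of ``t`` (fallback when no outgroup is known)."""
    t2 = t.clone(depth=1)
    t2.reroot_at_midpoint()
    t2.is_rooted = True
    return t2


def write_newick(
    t: dendropy.Tree,
    path: str | Path | None = None,
    dataset: Dataset | None = None,
    label_template: str | None = None,
) -> str:
    """Serialize a tree to Newick (with branch lengths, labels auto-quoted).

    ``label_template`` optionally rewrites leaf labels from specimen
    metadata, e.g. ``"{specimen_id}|{genus}_{species}|{region}"``; it
    requires ``dataset``.
    """
    if label_template is not None:
        if dataset is None:
            raise ValidationError("label_template requires the dataset")
        t = t.clone(depth=1)
        # clone(depth=1) shares the TaxonNamespace; give the relabelled tree
        # its own taxa so the caller's tree is untouched.
        t.taxon_namespace = dendropy.TaxonNamespace()
        for lf in t.leaf_node_iter():
            r = dataset.record(lf.taxon.label)
            lf.taxon = t.taxon_namespace.new_taxon(
                label=label_template.format(
                    specimen_id=r.specimen_id,
                    genus=r.genus,
                    species=r.species,
                    region=r.region,
                )
            )
    text = t.as_string(schema="newick", suppress_rooting=True)
    if path is not None:
        Path(path).write_text(text)
    return text
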
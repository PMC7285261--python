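"""Neighbor-joining phylogeny from an intergenomic distance matrix.

Implements classical neighbor joining (Saitou-Nei agglomeration with the
Studier-Keppler Q criterion) over a :class:`~taxopan.distmat.DistanceMatrix`,
with a deterministic tie-break so repeated runs give identical trees, plus
outgroup rooting and Newick serialization.  Trees are held as
:class:`dendropy.Tree` objects so the usual tree toolkit applies.

Negative branch lengths, which NJ can produce on non-additive input, are
clamped to zero; the clamped deficit is reported through the module logger.
"""

from __future__ import annotations

import logging
from pathlib import Path

import dendropy
import numpy as np

from .distmat import DistanceMatrix

__all__ = ["neighbor_joining", "root_with_outgroup", "read_newick", "write_newick"]

logger = logging.getLogger(__name__)


def _clamp(length: float, context: str) -> float:
    if length < 0:
        logger.info("clamped negative branch length %.6g to 0 (%s)", length, context)
        return 0.0
    return float(length)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Build an unrooted neighbor-joining tree from ``dm``.

    At each step the pair minimizing the Q criterion
    ``Q(i, j) = (k - 2) d(i, j) - r_i - r_j`` (with ``r`` the row sums over
    the ``k`` active nodes) is joined; exact ties are broken by the
    lexicographically smallest pair of node keys, where a node's key is
    the smallest leaf label beneath it.  For two taxa the result is a
    single edge of the given distance; three taxa use the three-point
    closed form.
    """
    n = dm.n
    if n < 2:
        raise ValueError("neighbor joining requires at least 2 taxa")

    taxa = dendropy.TaxonNamespace(list(dm.labels))
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: list[dendropy.Node] = []
    keys: list[str] = []
    for label in dm.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
        keys.append(label)
    d = dm.values.copy()

    while len(nodes) > 3:
        k = len(nodes)
        r = d.sum(axis=1)
        # evaluate Q on the upper triangle only: the two rounding orders of
        # -r_i - r_j can differ by one ulp, making the full matrix asymmetric
        iu, ju = np.triu_indices(k, k=1)
        qv = (k - 2) * d[iu, ju] - r[iu] - r[ju]
        best = qv.min()
        ties = np.flatnonzero(qv == best)
        i, j = min(
            ((int(iu[t]), int(ju[t])) for t in ties),
            key=lambda ij: tuple(sorted((keys[ij[0]], keys[ij[1]]))),
        )
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (k - 2))
        lj = dij - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = _clamp(li, f"join {keys[i]}")
        parent.add_child(nodes[j])
        nodes[j].edge.length = _clamp(lj, f"join {keys[j]}")
        dnew = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [m for m in range(k) if m not in (i, j)]
        d = np.vstack([d[np.ix_(keep, keep)], dnew[keep]])
        d = np.hstack([d, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[m] for m in keep] + [parent]
        keys = [keys[m] for m in keep] + [min(keys[i], keys[j])]

    root = dendropy.Node()
    if len(nodes) == 2:
        # single edge: hang both ends off a degree-2 junction
        root.add_child(nodes[0])
        nodes[0].edge.length = _clamp(d[0, 1] / 2.0, keys[0])
        root.add_child(nodes[1])
        nodes[1].edge.length = _clamp(d[0, 1] / 2.0, keys[1])
    else:
        # three-point closed form: l_a = (d_ab + d_ac - d_bc) / 2, cyclic
        la = (d[0, 1] + d[0, 2] - d[1, 2]) / 2.0
        lb = (d[0, 1] + d[1, 2] - d[0, 2]) / 2.0
        lc = (d[0, 2] + d[1, 2] - d[0, 1]) / 2.0
        for node, length, key in zip(nodes, (la, lb, lc), keys):
            root.add_child(node)
            node.edge.length = _clamp(length, key)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def root_with_outgroup(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    """Root ``tree`` at the midpoint of the outgroup's pendant edge.

    The ingroup topology is unchanged and leaf-to-leaf path lengths are
    preserved.  Returns a new rooted tree.
    """
    rooted = tree.clone(depth=1)
    leaf = None
    for nd in rooted.leaf_node_iter():
        if nd.taxon is not None and nd.taxon.label == outgroup:
            leaf = nd
            break
    if leaf is None:
        known = sorted(t.label for t in rooted.taxon_namespace)
        raise KeyError(f"outgroup {outgroup!r} is not a leaf; leaves are {known}")
    edge_len = leaf.edge.length if leaf.edge.length is not None else 0.0
    rooted.reroot_at_edge(
        leaf.edge,
        length1=edge_len / 2.0,
        length2=edge_len / 2.0,
        update_bipartitions=False,
    )
    rooted.is_rooted = True
    return rooted


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Serialize ``tree`` as Newick with branch lengths."""
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_newick(path: str | Path) -> dendropy.Tree:
    """Parse a Newick file; malformed input raises a parse error with position."""
    return dendropy.Tree.get(path=str(path), schema="newick")
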
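"""Distance matrices and neighbor-joining trees.

The neighbor-joining (NJ) implementation is the classic agglomerative
algorithm: repeatedly join the pair minimising
``Q(i,j) = (n-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k)`` with branch
lengths from the standard two-point formulas.  It is exact on additive
matrices.  Ties in the Q minimisation break on the lexicographically
lowest label pair, so the result is deterministic and independent of
input order.  Negative branch lengths are clamped to zero with the
deficit moved to the sibling edge, preserving the joined pair's path
length.

Trees are held as :class:`PhyloTree`, a thin wrapper over a dendropy
tree that adds outgroup rooting and exact-clade monophyly tests and
serialises to and from Newick.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import dendropy
import numpy as np

from haplodose.catalog import RegionAlignment
from haplodose.clock import pair_distance
from haplodose.errors import InputError, SaturationError


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of pairwise distances with leaf labels."""

    labels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise InputError("matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise InputError("distance matrix is not symmetric")
        if np.any(np.diag(m) != 0):
            raise InputError("distance matrix diagonal must be zero")
        if np.any(m < 0):
            raise InputError("negative distances")
        object.__setattr__(self, "matrix", m)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.labels.index(pair[0]), self.labels.index(pair[1])
        return float(self.matrix[i, j])


class PhyloTree:
    """A phylogenetic tree with branch lengths."""

    def __init__(self, dtree: dendropy.Tree, rooted: bool = False):
        self.dtree = dtree
        self.rooted = rooted
        self.dtree.is_rooted = rooted

    @classmethod
    def from_newick(cls, newick: str, rooted: bool = False) -> "PhyloTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls(tree, rooted)

    def to_newick(self) -> str:
        return self.dtree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    @property
    def leaf_labels(self) -> frozenset[str]:
        return frozenset(
            leaf.taxon.label for leaf in self.dtree.leaf_node_iter()
        )

    def path_distances(self) -> DistanceMatrix:
        """Leaf-to-leaf path lengths along the tree."""
        pdm = self.dtree.phylogenetic_distance_matrix()
        labels = tuple(sorted(self.leaf_labels))
        taxa = {t.label: t for t in self.dtree.taxon_namespace}
        n = len(labels)
        m = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                m[i, j] = m[j, i] = pdm.patristic_distance(
                    taxa[labels[i]], taxa[labels[j]]
                )
        return DistanceMatrix(labels, m)

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartition halves, each as its smaller leaf set
        keyed canonically (the half not containing the first label)."""
        all_leaves = self.leaf_labels
        anchor = min(all_leaves)
        out = set()
        for node in self.dtree.preorder_internal_node_iter():
            clade = frozenset(
                leaf.taxon.label for leaf in node.leaf_iter()
            )
            side = clade if anchor not in clade else all_leaves - clade
            if 1 < len(side) < len(all_leaves) - 1:
                out.add(side)
        return out


# ---------------------------------------------------------------------------
# matrix construction
# ---------------------------------------------------------------------------


def build_distance_matrix(
    alignment: RegionAlignment | Iterable[tuple[str, str]],
    model: str = "jc69",
) -> DistanceMatrix:
    """All-pairs model-corrected distances over an alignment.

    Gap/N columns are deleted pairwise.  Any saturated pair (or a pair
    with no comparable columns) aborts with an error listing the pairs —
    a tree is not attempted on an incomplete matrix.
    """
    seqs = (
        list(alignment.haplotypes)
        if isinstance(alignment, RegionAlignment)
        else list(alignment)
    )
    if len(seqs) < 3:
        raise InputError("need at least 3 sequences for a distance matrix")
    labels = tuple(h for h, _ in seqs)
    n = len(labels)
    m = np.zeros((n, n))
    bad: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            try:
                est = pair_distance(seqs[i][1], seqs[j][1], model)
            except InputError:
                bad.append((labels[i], labels[j]))
                continue
            if not est.valid:
                bad.append((labels[i], labels[j]))
                continue
            m[i, j] = m[j, i] = est.d
    if bad:
        raise SaturationError(
            f"saturated or incomparable pairs under {model}: {bad}"
        )
    return DistanceMatrix(labels, m)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Classic NJ tree from a distance matrix (n >= 3), unrooted."""
    n = len(dm.labels)
    if n < 3:
        raise InputError("neighbor joining needs at least 3 taxa")

    # each active node: (sort_key, newick_fragment); sort_key is the
    # lexicographically smallest leaf under the node, for tie-breaking
    keys = list(dm.labels)
    frags = [_quote(l) for l in dm.labels]
    d = dm.matrix.copy()

    while len(keys) > 3:
        m = len(keys)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                tie_key = tuple(sorted((keys[i], keys[j])))
                cand = (q, tie_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        # clamp negatives, moving the deficit to the sibling edge
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        new_frag = f"({frags[i]}:{li:.12g},{frags[j]}:{lj:.12g})"
        new_key = min(keys[i], keys[j])
        du = 0.5 * (d[:, i] + d[:, j] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[np.ix_(keep, keep)], du[keep]])
        d = np.hstack([d, np.append(du[keep], 0.0)[:, None]])
        keys = [keys[k] for k in keep] + [new_key]
        frags = [frags[k] for k in keep] + [new_frag]

    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    la = max((dab + dac - dbc) / 2, 0.0)
    lb = max((dab + dbc - dac) / 2, 0.0)
    lc = max((dac + dbc - dab) / 2, 0.0)
    newick = (
        f"({frags[0]}:{la:.12g},{frags[1]}:{lb:.12g},{frags[2]}:{lc:.12g});"
    )
    return PhyloTree.from_newick(newick, rooted=False)


def _quote(label: str) -> str:
    if any(ch in label for ch in " ()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# rooting and monophyly
# ---------------------------------------------------------------------------


def root_with_outgroup(tree: PhyloTree, outgroup_label: str) -> PhyloTree:
    """Root a tree at the midpoint of the outgroup's pendant edge."""
    if outgroup_label not in tree.leaf_labels:
        raise InputError(f"outgroup {outgroup_label!r} is not a leaf of the tree")
    dtree = tree.dtree.clone(depth=1)
    node = dtree.find_node_with_taxon_label(outgroup_label)
    parent = node.parent_node
    if (
        tree.rooted
        and parent is not None
        and parent is dtree.seed_node
        and len(parent.child_nodes()) == 2
    ):
        return PhyloTree(dtree, rooted=True)  # already rooted here
    length = node.edge.length or 0.0
    dtree.reroot_at_edge(node.edge, length1=length / 2, length2=length / 2)
    dtree.is_rooted = True
    return PhyloTree(dtree, rooted=True)


def is_monophyletic(tree: PhyloTree, leaf_set: Iterable[str]) -> bool:
    """True iff some clade of the rooted tree equals ``leaf_set`` exactly."""
    wanted = frozenset(leaf_set)
    if not wanted:
        raise InputError("empty leaf set")
    if not tree.rooted:
        raise InputError("monophyly is defined on a rooted tree")
    missing = wanted - tree.leaf_labels
    if missing:
        raise InputError(f"labels not in tree: {sorted(missing)}")
    if len(wanted) == 1:
        return True
    for node in tree.dtree.preorder_internal_node_iter():
        clade = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if clade == wanted:
            return True
    return False
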
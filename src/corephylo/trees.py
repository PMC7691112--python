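"""Trees, bipartitions, the tree topology score, and site-tree congruence.

Trees are :class:`dendropy.Tree` objects with branch lengths in expected
substitutions per site.  Topology comparisons treat trees as unrooted: the
unit of comparison is the *nontrivial bipartition*, the split of the leaf
set induced by removing an internal edge, with both sides containing at
least two leaves.  An unrooted binary tree on ``n`` leaves has exactly
``n - 3`` of them.

The tree topology score (TTS) between a reference and a test tree over the
same leaves is the percentage of the reference tree's nontrivial
bipartitions that also occur in the test tree.  A random-tree baseline for
the score is provided by :func:`random_topology`, which draws uniformly
from the unrooted binary labelled topologies.

Site-tree congruence: an alignment column is congruent with a tree when
every allele class can simultaneously form a connected subtree (for a
biallelic column: the allele split coincides with an edge bipartition, or
one class is a singleton).  This is equivalent to the column being
homoplasy-free, i.e. its parsimony score on the tree equals
``(number of allele states) - 1``, which is how it is computed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "NewickError",
    "LeafSetMismatchError",
    "TTSResult",
    "read_newick",
    "write_newick",
    "leaf_labels",
    "bipartitions",
    "tts",
    "random_topology",
    "site_is_congruent",
    "parsimony_scores",
]

#: nucleotide encoding shared across the package: A=0, C=1, G=2, T=3, 4=missing
NUCLEOTIDES = "ACGT"
MISSING = 4


class NewickError(ValueError):
    """Malformed Newick input (parse failure, duplicate leaf labels,
    negative branch length)."""


class LeafSetMismatchError(ValueError):
    """Two trees compared over different leaf sets."""


def read_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a tree and validate its invariants.

    Raises :class:`NewickError` naming the offending token for duplicate
    leaf labels or negative branch lengths.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted error classes
        raise NewickError(f"could not parse Newick string: {exc}") from exc
    seen: set[str] = set()
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise NewickError("tree contains an unlabelled leaf")
        label = leaf.taxon.label
        if label in seen:
            raise NewickError(f"duplicate leaf label {label!r}")
        seen.add(label)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise NewickError(
                f"negative branch length {edge.length!r} above node "
                f"{edge.head_node.taxon.label if edge.head_node.taxon else '<internal>'}"
            )
    return tree


def read_newick_file(path) -> dendropy.Tree:
    with open(path) as fh:
        return read_newick(fh.read())


def write_newick(tree: dendropy.Tree) -> str:
    """Serialise a tree to Newick, preserving branch lengths to full
    precision; internal node labels (e.g. bootstrap supports) are kept."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".17g",
    ).strip()


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _leaf_sets(tree: dendropy.Tree) -> dict:
    sets = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[node] = frozenset((node.taxon.label,))
        else:
            acc = frozenset()
            for child in node.child_nodes():
                acc |= sets[child]
            sets[node] = acc
    return sets


def bipartitions(tree: dendropy.Tree) -> frozenset[frozenset[str]]:
    """Nontrivial bipartitions of the unrooted tree.

    Each bipartition is canonicalised as the side *not* containing the
    lexicographically smallest leaf label, so equal splits compare equal
    regardless of rooting.  Trees with < 4 leaves have none.
    """
    labels = leaf_labels(tree)
    if len(labels) < 4:
        return frozenset()
    full = frozenset(labels)
    anchor = min(labels)
    sets = _leaf_sets(tree)
    out = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = sets[node]
        if len(side) < 2 or len(full) - len(side) < 2:
            continue
        out.add(full - side if anchor in side else side)
    return frozenset(out)


@dataclass(frozen=True)
class TTSResult:
    """Tree topology score: percent of the reference tree's nontrivial
    bipartitions present in the test tree."""

    score: float
    shared: int
    denominator: int

    def __post_init__(self):
        if not (0 <= self.shared <= self.denominator):
            raise ValueError("shared count outside [0, denominator]")


def tts(reference: dendropy.Tree, test: dendropy.Tree) -> TTSResult:
    """Tree topology score of ``test`` against ``reference``.

    score = 100 x |shared nontrivial bipartitions| / |reference's
    nontrivial bipartitions|.  Symmetric when both trees are fully
    resolved; an unresolved test tree can only lose shared splits.
    """
    ref_leaves = set(leaf_labels(reference))
    test_leaves = set(leaf_labels(test))
    if ref_leaves != test_leaves:
        raise LeafSetMismatchError(
            f"leaf sets differ: only in reference {sorted(ref_leaves - test_leaves)}, "
            f"only in test {sorted(test_leaves - ref_leaves)}"
        )
    ref_bips = bipartitions(reference)
    if not ref_bips:
        raise ValueError("reference tree has no nontrivial bipartitions")
    shared = len(ref_bips & bipartitions(test))
    return TTSResult(score=100.0 * shared / len(ref_bips), shared=shared, denominator=len(ref_bips))


def random_topology(labels: Iterable[str], rng_seed: int) -> dendropy.Tree:
    """Uniform random unrooted binary labelled topology, unit branch lengths.

    Built by sequential leaf insertion: starting from the 3-leaf star, each
    further leaf is attached to a uniformly chosen edge, which yields the
    uniform distribution over unrooted binary topologies.
    """
    labels = sorted(set(labels))
    if len(labels) < 4:
        raise ValueError("need at least 4 labels for a nontrivial topology")
    rng = np.random.default_rng(rng_seed)

    # nodes as nested lists; edges identified with non-root nodes
    class _N:
        __slots__ = ("label", "children", "parent")

        def __init__(self, label=None):
            self.label = label
            self.children = []
            self.parent = None

    def attach(parent, child):
        parent.children.append(child)
        child.parent = parent

    root = _N()
    edge_nodes = []
    for lab in labels[:3]:
        leaf = _N(lab)
        attach(root, leaf)
        edge_nodes.append(leaf)
    for lab in labels[3:]:
        target = edge_nodes[rng.integers(len(edge_nodes))]
        parent = target.parent
        mid = _N()
        parent.children[parent.children.index(target)] = mid
        mid.parent = parent
        attach(mid, target)
        leaf = _N(lab)
        attach(mid, leaf)
        edge_nodes.append(mid)
        edge_nodes.append(leaf)

    def to_newick(node):
        if not node.children:
            return f"{node.label}:1.0"
        inner = ",".join(to_newick(c) for c in node.children)
        return f"({inner}):1.0" if node.parent is not None else f"({inner});"

    return read_newick(to_newick(root))


def _encode_column(column: Mapping[str, str]) -> np.ndarray:
    lut = {c: i for i, c in enumerate(NUCLEOTIDES)}
    return np.array([[lut.get(str(v).upper(), MISSING) for v in column.values()]], dtype=np.uint8)


def parsimony_scores(
    tree: dendropy.Tree, matrix: np.ndarray, labels: Sequence[str]
) -> np.ndarray:
    """Minimum number of state changes (Fitch/Sankoff parsimony, unit
    costs) for each column of ``matrix`` on ``tree``.

    ``matrix`` is (n_sites, n_leaves) of nucleotide codes (4 = missing,
    contributing no cost); ``labels`` maps columns of ``matrix`` to leaf
    labels.  Vectorised dynamic program over all sites at once, exact on
    arbitrary (multifurcating) trees.
    """
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[1] != len(labels):
        raise ValueError("matrix must be (n_sites, n_leaves) matching labels")
    col_of = {lab: j for j, lab in enumerate(labels)}
    for lab in leaf_labels(tree):
        if lab not in col_of:
            raise KeyError(f"leaf {lab!r} missing from the site data")
    n_sites = matrix.shape[0]
    BIG = np.int32(1 << 20)
    costs: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            obs = matrix[:, col_of[node.taxon.label]]
            c = np.full((n_sites, 4), BIG, dtype=np.int32)
            known = obs < MISSING
            c[known, obs[known]] = 0
            c[~known, :] = 0
            costs[node] = c
        else:
            total = np.zeros((n_sites, 4), dtype=np.int32)
            for child in node.child_nodes():
                cc = costs.pop(child)
                total += np.minimum(cc, cc.min(axis=1, keepdims=True) + 1)
            costs[node] = total
    return costs[tree.seed_node].min(axis=1)


def site_is_congruent(tree: dendropy.Tree, site_column: Mapping[str, str]) -> bool:
    """Whether one alignment column is congruent with the tree.

    True iff every allele class can be a connected subtree simultaneously,
    i.e. the column's parsimony score equals (number of distinct observed
    states) - 1.  Monomorphic and singleton-only columns are trivially
    congruent.  Unknown leaf labels raise ``KeyError``.
    """
    tree_leaves = set(leaf_labels(tree))
    for lab in site_column:
        if lab not in tree_leaves:
            raise KeyError(f"label {lab!r} not among the tree's leaves")
    ordered = {lab: site_column[lab] for lab in sorted(site_column)}
    col = _encode_column(ordered)
    states = np.unique(col[col < MISSING])
    if states.size <= 1:
        return True
    score = parsimony_scores(tree, col, list(ordered))[0]
    return int(score) == states.size - 1
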
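"""Rooted-tree substrate: Newick I/O, canonical topologies, enumeration, RF distances.

All downstream statistics operate on *rooted* tree shapes over a fixed taxon
set with a designated outgroup.  A gene tree read from file (or produced by a
simulator) is reduced to its canonical :class:`Topology` by re-rooting on the
outgroup edge and ordering children lexicographically by their smallest
descendant label; two trees have the same shape iff their canonical Newick
strings are equal.  Robinson-Foulds distances are the rooted, clade-based
variant: the size of the symmetric difference of the two trees' sets of
proper ingroup clades (the outgroup leaf and the full-ingroup clade carry no
information once every tree is rooted the same way, so they are excluded).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import dendropy

logger = logging.getLogger(__name__)

__all__ = [
    "TaxonSet",
    "Topology",
    "Node",
    "GeneTree",
    "NewickError",
    "parse_newick",
    "read_newick_file",
    "write_newick_file",
    "canonicalize",
    "parse_topology",
    "topology_from_clades",
    "topology_from_clade_masks",
    "gene_tree_clade_masks",
    "bovine_taxa",
    "BOVINE_LABELS",
    "double_factorial",
    "enumerate_topologies",
    "rf_distance",
    "max_rf",
    "support_filter",
    "SupportFilterReport",
]


class NewickError(ValueError):
    """Malformed Newick input or labels inconsistent with the taxon set."""


# ---------------------------------------------------------------------------
# taxa


@dataclass(frozen=True)
class TaxonSet:
    """An ordered set of taxon labels with a designated outgroup.

    Parameters
    ----------
    labels
        Unique, non-empty taxon names (at least three).
    outgroup
        One of ``labels``; every topology is rooted on this taxon's edge.
    """

    labels: tuple[str, ...]
    outgroup: str

    def __init__(self, labels: Iterable[str], outgroup: str):
        labels = tuple(labels)
        if len(labels) < 3:
            raise ValueError("need at least 3 taxa")
        if len(set(labels)) != len(labels):
            raise ValueError("taxon labels must be unique")
        if any(not lab for lab in labels):
            raise ValueError("taxon labels must be non-empty")
        if outgroup not in labels:
            raise ValueError(f"outgroup {outgroup!r} not among labels")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "outgroup", outgroup)

    @property
    def ingroup(self) -> tuple[str, ...]:
        return tuple(l for l in self.labels if l != self.outgroup)

    @property
    def n_ingroup(self) -> int:
        return len(self.labels) - 1

    # -- bitmask helpers (leaf sets are manipulated as small integers) ------

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def mask_of(self, labels: Iterable[str]) -> int:
        m = 0
        for lab in labels:
            m |= 1 << self.index(lab)
        return m

    def labels_of(self, mask: int) -> frozenset[str]:
        return frozenset(
            lab for i, lab in enumerate(self.labels) if mask >> i & 1
        )

    @property
    def ingroup_mask(self) -> int:
        return ((1 << len(self.labels)) - 1) & ~(1 << self.index(self.outgroup))


BOVINE_LABELS = ("bison", "wisent", "yak", "taurine", "zebu", "buffalo")


def bovine_taxa() -> TaxonSet:
    """The six bovine species used throughout the examples, buffalo outgroup."""
    return TaxonSet(BOVINE_LABELS, outgroup="buffalo")


# ---------------------------------------------------------------------------
# topology


@dataclass(frozen=True)
class Topology:
    """A canonical rooted binary tree shape over a fixed taxon set.

    ``clades`` holds the proper ingroup clades (size 2 .. k-1 for k ingroup
    taxa) as frozensets of labels; the canonical Newick string is uniquely
    determined by them, so equality and hashing go through it.
    """

    taxa: TaxonSet
    clades: frozenset[frozenset[str]]
    canonical_newick: str = field(compare=False)

    def __repr__(self):
        return f"Topology({self.canonical_newick!r})"

    def clade_masks(self) -> frozenset[int]:
        return frozenset(self.taxa.mask_of(c) for c in self.clades)


def _canonical_newick_from_clades(
    taxa: TaxonSet, clades: frozenset[frozenset[str]]
) -> str:
    """Build the canonical Newick string from a nested clade set."""

    def build(members: frozenset[str]) -> str:
        if len(members) == 1:
            return next(iter(members))
        # direct children: maximal clades strictly inside `members`, plus
        # any leaf not covered by one of them
        inside = [c for c in clades if c < members]
        maximal = [
            c for c in inside if not any(c < d for d in inside if d is not c)
        ]
        covered: set[str] = set()
        for c in maximal:
            covered |= c
        children: list[frozenset[str]] = maximal + [
            frozenset([l]) for l in members - covered
        ]
        parts = sorted((build(c) for c in children), key=lambda s: min(_leaves(s)))
        return "(" + ",".join(parts) + ")"

    def _leaves(newick_fragment: str) -> list[str]:
        return (
            newick_fragment.replace("(", "")
            .replace(")", "")
            .split(",")
        )

    ingroup = frozenset(taxa.ingroup)
    parts = sorted(
        [build(ingroup), taxa.outgroup], key=lambda s: min(_leaves(s))
    )
    return "(" + ",".join(parts) + ")"


def topology_from_clades(
    taxa: TaxonSet, clades: Iterable[frozenset[str]]
) -> Topology:
    """Construct a Topology from its proper ingroup clade set.

    Raises if the clades do not describe a binary rooted tree on the ingroup
    (exactly k-2 pairwise nested-or-disjoint proper clades for k ingroup taxa).
    """
    ingroup = frozenset(taxa.ingroup)
    cl = frozenset(frozenset(c) for c in clades)
    k = len(ingroup)
    for c in cl:
        if not (2 <= len(c) <= k - 1) or not c <= ingroup:
            raise ValueError(f"invalid clade {set(c)}")
    for a in cl:
        for b in cl:
            if not (a <= b or b <= a or not (a & b)):
                raise ValueError("clades must be nested or disjoint")
    if len(cl) != k - 2:
        raise ValueError(
            f"binary rooted topology on {k} ingroup taxa needs {k - 2} proper "
            f"clades, got {len(cl)}"
        )
    return Topology(taxa, cl, _canonical_newick_from_clades(taxa, cl))


def topology_from_clade_masks(taxa: TaxonSet, masks: Iterable[int]) -> Topology:
    return topology_from_clades(taxa, (taxa.labels_of(m) for m in masks))


# ---------------------------------------------------------------------------
# gene trees


@dataclass
class Node:
    """A node of a rooted tree; leaves carry a label, edges a length/support."""

    children: list["Node"] = field(default_factory=list)
    label: Optional[str] = None
    length: Optional[float] = None
    support: Optional[float] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> Iterator["Node"]:
        if self.is_leaf:
            yield self
        else:
            for ch in self.children:
                yield from ch.leaves()

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def postorder(self) -> Iterator["Node"]:
        for ch in self.children:
            yield from ch.postorder()
        yield self

    def to_newick(self, lengths: bool = True, supports: bool = True) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                s = node.label
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if supports and node.support is not None:
                    s += format(node.support, "g")
            if lengths and node.length is not None:
                s += f":{node.length:.10g}"
            return s

        return fmt(self) + ";"


@dataclass
class GeneTree:
    """A rooted gene tree: shape plus optional branch lengths and supports.

    ``units`` tags what the branch lengths mean ("coalescent" or
    "substitutions"); ``has_polytomy`` is set by the parser when the input is
    not fully resolved (such trees are accepted for I/O but rejected by
    canonicalization and classification).
    """

    root: Node
    taxa: TaxonSet
    units: str = "none"
    has_polytomy: bool = False

    def leaf_labels(self) -> list[str]:
        return self.root.leaf_labels()

    def internal_supports(self) -> list[Optional[float]]:
        """Supports of internal nodes below the root (root itself excluded)."""
        out = []
        for node in self.root.postorder():
            if not node.is_leaf and node is not self.root:
                out.append(node.support)
        return out

    def to_newick(self, lengths: bool = True, supports: bool = True) -> str:
        return self.root.to_newick(lengths=lengths, supports=supports)

    def copy(self) -> "GeneTree":
        def cp(n: Node) -> Node:
            return Node([cp(c) for c in n.children], n.label, n.length, n.support)

        return GeneTree(cp(self.root), self.taxa, self.units, self.has_polytomy)


def _from_dendropy(dnode, taxa: TaxonSet) -> tuple[Node, bool]:
    poly = False

    def conv(nd) -> Node:
        nonlocal poly
        if nd.is_leaf():
            lab = nd.taxon.label if nd.taxon is not None else nd.label
            if lab not in taxa.labels:
                raise NewickError(f"unknown leaf label {lab!r}")
            return Node(label=lab, length=nd.edge.length)
        kids = nd.child_nodes()
        # a trifurcating root is the unrooted-Newick convention, not a
        # polytomy; it resolves when the tree is re-rooted on the outgroup
        limit = 3 if nd is dnode else 2
        if len(kids) > limit:
            poly = True
        support = None
        if nd.label is not None:
            try:
                support = float(nd.label)
            except ValueError:
                support = None
        return Node(
            children=[conv(c) for c in kids],
            length=nd.edge.length,
            support=support,
        )

    return conv(dnode), poly


def parse_newick(text: str, taxa: TaxonSet) -> GeneTree:
    """Parse one Newick string into a :class:`GeneTree`.

    Leaf labels must be a subset of ``taxa.labels`` (proper subsets are
    allowed, e.g. for triplet extraction).  Numeric internal-node labels are
    read as bootstrap supports.  A missing trailing semicolon is tolerated.
    Polytomies are accepted but flagged.
    """
    text = text.strip()
    if not text:
        raise NewickError("empty Newick string")
    if not text.endswith(";"):
        text += ";"
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickError(f"malformed Newick: {exc}") from exc
    root, poly = _from_dendropy(dtree.seed_node, taxa)
    seen = root.leaf_labels()
    if len(seen) != len(set(seen)):
        raise NewickError("duplicate leaf labels")
    units = "none" if all(n.length is None for n in root.postorder()) else "unknown"
    return GeneTree(root, taxa, units=units, has_polytomy=poly)


def read_newick_file(path, taxa: TaxonSet) -> list[GeneTree]:
    """Read one tree per non-empty line."""
    trees = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                trees.append(parse_newick(line, taxa))
            except NewickError as exc:
                raise NewickError(f"{path}:{i}: {exc}") from exc
    return trees


def write_newick_file(path, trees: Sequence[GeneTree | Topology]) -> None:
    with open(path, "w") as fh:
        for t in trees:
            if isinstance(t, Topology):
                fh.write(t.canonical_newick + ";\n")
            else:
                fh.write(t.to_newick() + "\n")


# ---------------------------------------------------------------------------
# canonicalization


def gene_tree_clade_masks(tree: GeneTree) -> frozenset[int]:
    """Proper ingroup clade bitmasks of a gene tree after re-rooting on the outgroup.

    Works for any input rooting: every non-root cluster of the tree as given
    corresponds, after re-rooting on the outgroup edge, to the cluster itself
    (if it excludes the outgroup) or to its complement (if it contains it).
    """
    taxa = tree.taxa
    ing = taxa.ingroup_mask
    full = ing | (1 << taxa.index(taxa.outgroup))

    masks: set[int] = set()

    def walk(node: Node) -> int:
        if node.is_leaf:
            return 1 << taxa.index(node.label)
        m = 0
        for ch in node.children:
            m |= walk(ch)
        if node is not tree.root:
            masks.add(m)
        return m

    got = walk(tree.root)
    if got != full:
        missing = taxa.labels_of(full & ~got)
        raise ValueError(f"tree is missing taxa: {sorted(missing)}")

    clades = set()
    for m in masks:
        c = m if not m & ~ing else ing & ~m
        if 2 <= bin(c).count("1") <= taxa.n_ingroup - 1:
            clades.add(c)
    return frozenset(clades)


def canonicalize(tree: GeneTree) -> Topology:
    """Reduce a gene tree to its canonical rooted topology.

    The tree is (implicitly) re-rooted on the outgroup edge; children are
    ordered by smallest descendant label.  Requires a binary tree containing
    every taxon of the taxon set.
    """
    if tree.has_polytomy:
        raise ValueError("cannot canonicalize a tree with polytomies")
    masks = gene_tree_clade_masks(tree)
    if len(masks) != tree.taxa.n_ingroup - 2:
        raise ValueError("tree is not binary after re-rooting")
    return topology_from_clade_masks(tree.taxa, masks)


def parse_topology(text: str, taxa: TaxonSet) -> Topology:
    """Parse a Newick string directly into its canonical Topology."""
    return canonicalize(parse_newick(text, taxa))


# ---------------------------------------------------------------------------
# enumeration


def enumerate_topologies(taxa: TaxonSet) -> list[Topology]:
    """All distinct rooted binary topologies on the ingroup, outgroup at the root.

    Exhaustive leaf-insertion generation with deduplication by canonical
    clade set; for k ingroup taxa the count is the double factorial
    (2k-3)!! (105 for k=5).
    """
    ingroup = list(taxa.ingroup)
    if len(ingroup) < 2:
        raise ValueError("need at least 2 ingroup taxa")

    # trees represented as nested tuples of labels
    def insert_everywhere(tree, leaf):
        # attach above the whole tree
        yield (tree, leaf)
        if isinstance(tree, tuple):
            a, b = tree
            for sub in insert_everywhere(a, leaf):
                yield (sub, b)
            for sub in insert_everywhere(b, leaf):
                yield (a, sub)

    shapes = [ingroup[0]]
    for leaf in ingroup[1:]:
        shapes = [s for t in shapes for s in insert_everywhere(t, leaf)]

    def clades_of(tree, acc):
        if isinstance(tree, str):
            return frozenset([tree])
        members = clades_of(tree[0], acc) | clades_of(tree[1], acc)
        acc.append(members)
        return members

    seen: dict[frozenset[frozenset[str]], None] = {}
    for shape in shapes:
        acc: list[frozenset[str]] = []
        clades_of(shape, acc)
        key = frozenset(c for c in acc if len(c) < len(ingroup))
        seen.setdefault(key, None)

    out = [topology_from_clades(taxa, key) for key in seen]
    out.sort(key=lambda t: t.canonical_newick)
    return out


def double_factorial(n: int) -> int:
    out = 1
    while n > 1:
        out *= n
        n -= 2
    return out


# ---------------------------------------------------------------------------
# RF distance


def rf_distance(a: Topology, b: Topology) -> int:
    """Rooted Robinson-Foulds distance: |clades(a) XOR clades(b)|."""
    if a.taxa != b.taxa:
        raise ValueError("topologies are over different taxon sets")
    return len(a.clades ^ b.clades)


def max_rf(taxa: TaxonSet) -> int:
    """Maximum possible rooted RF distance: 2(k-2) for k ingroup taxa."""
    return 2 * (taxa.n_ingroup - 2)


# ---------------------------------------------------------------------------
# support filtering


@dataclass
class SupportFilterReport:
    n_input: int
    n_kept: int
    n_no_support: int
    n_below_threshold: int
    threshold: float


def support_filter(
    trees: Sequence[GeneTree],
    threshold: float,
    return_report: bool = False,
):
    """Retain trees whose every internal-node support strictly exceeds ``threshold``.

    Trees lacking a support at any internal node are dropped (and counted in
    the report).  ``threshold`` is a percentage in [0, 100].
    """
    if not 0 <= threshold <= 100:
        raise ValueError("threshold must be in [0, 100]")
    kept = []
    n_missing = n_below = 0
    for t in trees:
        sups = t.internal_supports()
        if any(s is None for s in sups):
            n_missing += 1
        elif all(s > threshold for s in sups):
            kept.append(t)
        else:
            n_below += 1
    if n_missing:
        logger.info("support_filter: dropped %d trees lacking supports", n_missing)
    if return_report:
        return kept, SupportFilterReport(
            len(trees), len(kept), n_missing, n_below, threshold
        )
    return kept
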
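"""Multispecies-coalescent gene-tree simulation on a fixed species tree.

The species tree carries internal branch lengths in coalescent units
(time / 2N generations, per-branch population size folded into the length).
One lineage is sampled per species; within a branch holding k lineages,
successive exponential waiting times with rate k(k-1)/2 merge uniformly
chosen pairs until the branch is exhausted; the root branch is infinite.

Gene-tree *topologies* are summarized after re-rooting on the outgroup, so
the topology space is the (2k-3)!! rooted shapes over the k ingroup taxa.
Note that the distribution over that space depends only on the internal
branches below the ingroup root: deeper coalescences are exchangeable.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .trees import (
    GeneTree,
    Node,
    TaxonSet,
    Topology,
    parse_newick,
    topology_from_clade_masks,
)

__all__ = [
    "SpeciesTree",
    "TopologyDistribution",
    "simulate_gene_tree",
    "simulate_topology_distribution",
    "triple_topology_probs",
    "tree_rng",
]


@dataclass
class SpeciesTree:
    """A fixed rooted topology plus branch lengths in coalescent units.

    ``internal_lengths`` maps each proper ingroup clade (frozenset of labels)
    to the length of the branch above it.  ``stem_length`` is the branch
    between the ingroup root and the tree root; it does not affect the
    re-rooted topology distribution (deep coalescences are exchangeable) and
    is unidentifiable from rooted-triple data, but is kept for output branch
    lengths.  ``tip_lengths`` likewise only shape output branch lengths.
    """

    topology: Topology
    internal_lengths: dict[frozenset[str], float]
    stem_length: float = 1.0
    tip_lengths: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        expected = set(self.topology.clades)
        got = set(map(frozenset, self.internal_lengths))
        if got != expected:
            raise ValueError(
                "internal_lengths must cover exactly the proper ingroup clades"
            )
        if any(v < 0 for v in self.internal_lengths.values()) or self.stem_length < 0:
            raise ValueError("branch lengths must be non-negative")
        self.internal_lengths = {frozenset(k): float(v) for k, v in self.internal_lengths.items()}

    @property
    def taxa(self) -> TaxonSet:
        return self.topology.taxa

    def with_lengths(self, lengths: dict[frozenset[str], float]) -> "SpeciesTree":
        return SpeciesTree(self.topology, dict(lengths), self.stem_length, dict(self.tip_lengths))

    # ---- Newick I/O ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, taxa: TaxonSet) -> "SpeciesTree":
        """Read a species tree whose branch lengths are coalescent units."""
        from .trees import canonicalize

        gt = parse_newick(text, taxa)
        topo = canonicalize(gt)
        out_idx = taxa.index(taxa.outgroup)
        ing_mask = taxa.ingroup_mask
        internal: dict[frozenset[str], float] = {}
        stem = 1.0
        tips: dict[str, float] = {}

        def walk(node: Node) -> int:
            m = 0
            if node.is_leaf:
                m = 1 << taxa.index(node.label)
                if node.length is not None:
                    tips[node.label] = node.length
            else:
                for ch in node.children:
                    m |= walk(ch)
                if node.length is not None:
                    c = m if not m >> out_idx & 1 else ing_mask & ~m
                    if c == ing_mask:
                        nonlocal stem
                        stem = node.length
                    else:
                        lab = taxa.labels_of(c)
                        if lab in topo.clades:
                            internal[lab] = node.length
            return m

        walk(gt.root)
        missing = set(topo.clades) - set(internal)
        if missing:
            raise ValueError(f"species tree lacks lengths for clades {missing}")
        return cls(topo, internal, stem, tips)

    def to_newick(self) -> str:
        taxa = self.taxa

        def build(members: frozenset[str]) -> str:
            if len(members) == 1:
                (lab,) = members
                ln = self.tip_lengths.get(lab, 0.0)
                return f"{lab}:{ln:g}"
            inside = [c for c in self.topology.clades if c < members]
            maximal = [c for c in inside if not any(c < d for d in inside if d is not c)]
            covered = set().union(*maximal) if maximal else set()
            children = maximal + [frozenset([l]) for l in members - covered]
            parts = sorted((build(c) for c in children), key=_min_leaf)
            s = "(" + ",".join(parts) + ")"
            if members == frozenset(taxa.ingroup):
                return f"{s}:{self.stem_length:g}"
            return f"{s}:{self.internal_lengths[members]:g}"

        og = f"{taxa.outgroup}:{self.tip_lengths.get(taxa.outgroup, 0.0):g}"
        parts = sorted([build(frozenset(taxa.ingroup)), og], key=_min_leaf)
        return "(" + ",".join(parts) + ");"


def _min_leaf(fragment: str) -> str:
    return min(
        part.split(":")[0]
        for part in fragment.replace("(", "").replace(")", "").split(",")
    )


# ---------------------------------------------------------------------------
# compiled form for simulation


class _Compiled:
    """Species tree flattened to postorder arrays for the simulation loop."""

    __slots__ = ("entries", "n_nodes", "ing_mask", "out_bit", "k", "ages", "labels")

    def __init__(self, st: SpeciesTree):
        taxa = st.taxa
        self.ing_mask = taxa.ingroup_mask
        self.out_bit = 1 << taxa.index(taxa.outgroup)
        self.k = taxa.n_ingroup
        self.labels = taxa.labels

        # nodes: all leaves, proper clades, ingroup root, tree root
        clades = sorted(st.topology.clades, key=len)
        node_sets: list[frozenset[str]] = [frozenset([l]) for l in taxa.labels]
        node_sets += clades
        node_sets += [frozenset(taxa.ingroup), frozenset(taxa.labels)]
        index = {s: i for i, s in enumerate(node_sets)}

        def length_of(s: frozenset[str]) -> float:
            if len(s) == 1:
                (lab,) = s
                return float(st.tip_lengths.get(lab, 0.0))
            if s == frozenset(taxa.ingroup):
                return float(st.stem_length)
            if s == frozenset(taxa.labels):
                return math.inf
            return float(st.internal_lengths[s])

        def children_of(s: frozenset[str]) -> list[frozenset[str]]:
            if len(s) == 1:
                return []
            inside = [c for c in node_sets if c < s]
            return [c for c in inside if not any(c < d for d in inside if d < s)]

        # entries in index order are already postorder-compatible (children
        # are smaller sets, which sort earlier except leaves -- recompute):
        order = sorted(range(len(node_sets)), key=lambda i: len(node_sets[i]))
        self.entries = []
        ages: dict[frozenset[str], float] = {}
        for i in order:
            s = node_sets[i]
            kids = children_of(s)
            if len(s) == 1:
                ages[s] = 0.0
            else:
                ages[s] = max(ages[c] + length_of(c) for c in kids)
            mask = sum(1 << taxa.index(l) for l in s)
            self.entries.append(
                (
                    tuple(order.index(index[c]) for c in kids),
                    length_of(s),
                    mask,
                    ages[s],
                )
            )
        self.n_nodes = len(self.entries)


def _compiled(st: SpeciesTree) -> _Compiled:
    c = getattr(st, "_compiled_cache", None)
    if c is None:
        c = _Compiled(st)
        st._compiled_cache = c
    return c


def tree_rng(seed: int, index: int) -> random.Random:
    """Deterministic per-tree substream: seed and a counter, hashable across runs."""
    return random.Random(f"{seed}:{index}")


# ---------------------------------------------------------------------------
# simulation


def _sim_clade_masks(ct: _Compiled, rng: random.Random) -> frozenset[int]:
    """One MSC draw, reduced to the re-rooted proper ingroup clade masks."""
    stacks: list[Optional[list[int]]] = [None] * ct.n_nodes
    clusters: list[int] = []
    expo = rng.expovariate
    rnd = rng.randrange
    for idx, (kids, elen, mask, _age) in enumerate(ct.entries):
        if not kids:
            stacks[idx] = [mask]
            continue
        L: list[int] = []
        for kid in kids:
            L.extend(stacks[kid])
            stacks[kid] = None
        n = len(L)
        rem = elen
        while n > 1:
            dt = expo(n * (n - 1) / 2)
            if dt > rem:
                break
            rem -= dt
            i = rnd(n)
            j = rnd(n - 1)
            if j >= i:
                j += 1
            L[i] |= L[j]
            clusters.append(L[i])
            L[j] = L[n - 1]
            L.pop()
            n -= 1
        stacks[idx] = L
    ing = ct.ing_mask
    kmax = ct.k - 1
    clades = set()
    for m in clusters:
        c = m if not m & ct.out_bit else ing & ~m
        b = c.bit_count()
        if 2 <= b <= kmax:
            clades.add(c)
    return frozenset(clades)


def simulate_gene_tree(st: SpeciesTree, rng: random.Random) -> GeneTree:
    """Simulate one gene tree (with coalescent-unit branch lengths) under the MSC."""
    ct = _compiled(st)
    taxa = st.taxa
    # lineage: (Node, birth_time)
    stacks: list[Optional[list[tuple[Node, float]]]] = [None] * ct.n_nodes
    root_lineage: Optional[tuple[Node, float]] = None
    for idx, (kids, elen, mask, age) in enumerate(ct.entries):
        if not kids:
            (lab,) = (l for i, l in enumerate(taxa.labels) if mask >> i & 1)
            stacks[idx] = [(Node(label=lab), age)]
            continue
        L: list[tuple[Node, float]] = []
        for kid in kids:
            L.extend(stacks[kid])
            stacks[kid] = None
        t = age
        end = age + elen
        n = len(L)
        while n > 1:
            dt = rng.expovariate(n * (n - 1) / 2)
            if t + dt > end:
                break
            t += dt
            i = rng.randrange(n)
            j = rng.randrange(n - 1)
            if j >= i:
                j += 1
            a, ta = L[i]
            b, tb = L[j]
            a.length = t - ta
            b.length = t - tb
            L[i] = (Node(children=[a, b]), t)
            L[j] = L[n - 1]
            L.pop()
            n -= 1
        stacks[idx] = L
    (root, _t0) = stacks[ct.n_nodes - 1][0]
    root.length = None
    return GeneTree(root, taxa, units="coalescent")


@dataclass
class TopologyDistribution:
    """Counts of canonical topologies, e.g. from simulation or empirical trees."""

    counts: dict[str, int]
    total: int
    taxa: TaxonSet

    def __post_init__(self):
        if sum(self.counts.values()) != self.total:
            raise ValueError("counts must sum to total")

    def freq(self, topo: Topology | str) -> float:
        key = topo.canonical_newick if isinstance(topo, Topology) else topo
        return self.counts.get(key, 0) / self.total

    def count(self, topo: Topology | str) -> int:
        key = topo.canonical_newick if isinstance(topo, Topology) else topo
        return self.counts.get(key, 0)

    def to_vector(self, topologies: Sequence[Topology]):
        """Counts aligned to an ordered topology list (e.g. the 105-space)."""
        import numpy as np

        keys = set(self.counts)
        listed = {t.canonical_newick for t in topologies}
        if not keys <= listed:
            raise ValueError("distribution contains topologies outside the given space")
        return np.array(
            [self.counts.get(t.canonical_newick, 0) for t in topologies], dtype=float
        )

    @classmethod
    def from_topologies(cls, topos: Iterable[Topology], taxa: TaxonSet) -> "TopologyDistribution":
        counts: dict[str, int] = {}
        n = 0
        for t in topos:
            counts[t.canonical_newick] = counts.get(t.canonical_newick, 0) + 1
            n += 1
        return cls(counts, n, taxa)

    @classmethod
    def from_gene_trees(cls, trees, taxa: TaxonSet) -> "TopologyDistribution":
        from .trees import canonicalize

        return cls.from_topologies((canonicalize(t) for t in trees), taxa)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("topology\tcount\tfrequency\n")
            for key in sorted(self.counts, key=lambda k: -self.counts[k]):
                fh.write(f"{key}\t{self.counts[key]}\t{self.counts[key] / self.total:.6g}\n")


def simulate_topology_distribution(
    st: SpeciesTree, n_trees: int, seed: int
) -> TopologyDistribution:
    """Simulate ``n_trees`` gene trees and count their canonical topologies.

    Per-tree RNG substreams are derived from ``(seed, tree index)``, so the
    result is reproducible and independent of evaluation order.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    ct = _compiled(st)
    taxa = st.taxa
    mask_counts: dict[frozenset[int], int] = {}
    for i in range(n_trees):
        key = _sim_clade_masks(ct, tree_rng(seed, i))
        mask_counts[key] = mask_counts.get(key, 0) + 1
    counts = {
        topology_from_clade_masks(taxa, key).canonical_newick: c
        for key, c in mask_counts.items()
    }
    return TopologyDistribution(counts, n_trees, taxa)


def triple_topology_probs(T: float) -> tuple[float, float, float]:
    """Rooted-triple probabilities for an internal branch of T coalescent units.

    Returns (concordant, discordant, discordant) =
    (1 - (2/3)e^-T, (1/3)e^-T, (1/3)e^-T).
    """
    if T < 0:
        raise ValueError("T must be >= 0")
    e = math.exp(-T)
    return (1.0 - 2.0 / 3.0 * e, e / 3.0, e / 3.0)
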
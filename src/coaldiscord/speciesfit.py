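"""Coalescent-unit branch lengths on a fixed species topology from gene trees.

The estimator is a rooted-triple pseudo-likelihood (MP-EST style): for every
unordered ingroup triple, the counts of its three rooted resolutions among
the gene trees follow a trinomial whose concordant-class probability is
1 - (2/3)exp(-T), with T the summed length of the internal species-tree
branches separating the triple's cherry from the third taxon.  Maximizing
the product of these trinomials over the per-branch lengths gives the fit.
Terminal branch lengths are unidentifiable with one lineage per species and
are not estimated; the branch above the ingroup root never lies on an
ingroup triple path and is likewise not estimated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .msc import SpeciesTree, TopologyDistribution, triple_topology_probs
from .trees import GeneTree, TaxonSet, Topology, gene_tree_clade_masks

__all__ = [
    "TripleTable",
    "build_triple_table",
    "TripleCoalescentModel",
    "SpeciesTreeFitResult",
    "fit_branch_lengths",
]


@dataclass
class TripleTable:
    """Rooted-resolution counts for every unordered ingroup triple.

    ``counts[triple][cherry]`` is the number of gene trees in which the
    triple (a frozenset of 3 ingroup labels) resolves with ``cherry`` (a
    frozenset of 2 of them) as the most recent pair.
    """

    taxa: TaxonSet
    counts: dict[frozenset[str], dict[frozenset[str], int]]
    n_trees: int

    def triple_counts(self, triple: frozenset[str]) -> dict[frozenset[str], int]:
        return self.counts[frozenset(triple)]

    @classmethod
    def from_distribution(cls, dist: TopologyDistribution) -> "TripleTable":
        """Aggregate triple resolutions over the distinct topologies of a sample."""
        from .trees import parse_topology

        taxa = dist.taxa
        triples = _ingroup_triples(taxa)
        counts = {
            t: {frozenset(p): 0 for p in _pairs(t)} for t in triples
        }
        for key, n in dist.counts.items():
            topo = parse_topology(key, taxa)
            for t in triples:
                counts[t][_resolution(topo.clades, t)] += n
        return cls(taxa, counts, dist.total)


def _ingroup_triples(taxa: TaxonSet) -> list[frozenset[str]]:
    from itertools import combinations

    return [frozenset(c) for c in combinations(taxa.ingroup, 3)]


def _pairs(triple: frozenset[str]):
    from itertools import combinations

    return [frozenset(p) for p in combinations(sorted(triple), 2)]


def _resolution(
    clades: frozenset[frozenset[str]], triple: frozenset[str]
) -> frozenset[str]:
    """The cherry pair of ``triple`` induced by a clade set (binary tree)."""
    best: Optional[frozenset[str]] = None
    best_size = None
    for c in clades:
        inter = c & triple
        if len(inter) == 2 and (best_size is None or len(c) < best_size):
            best, best_size = inter, len(c)
    if best is None:
        # no clade separates the triple: its cherry is the pair joined at the
        # shallowest node, which for a binary rooted tree always exists unless
        # all three attach at the ingroup root -- then the two non-basal ones.
        raise ValueError(f"triple {set(triple)} unresolved by clade set")
    return frozenset(best)


def _safe_resolution(clades, triple):
    try:
        return _resolution(clades, triple)
    except ValueError:
        return None


def build_triple_table(gene_trees: Sequence[GeneTree], taxa: TaxonSet) -> TripleTable:
    """Count every ingroup triple's rooted resolution across the gene trees."""
    triples = _ingroup_triples(taxa)
    counts = {t: {frozenset(p): 0 for p in _pairs(t)} for t in triples}
    for gt in gene_trees:
        masks = gene_tree_clade_masks(gt)
        clades = frozenset(taxa.labels_of(m) for m in masks)
        for t in triples:
            res = _safe_resolution(clades, t)
            if res is not None:
                counts[t][res] += 1
    return TripleTable(taxa, counts, len(gene_trees))


# ---------------------------------------------------------------------------
# model


class TripleCoalescentModel:
    """Pseudo-likelihood model for internal branch lengths on a fixed topology.

    Parameters
    ----------
    topology
        The species topology whose internal branch lengths are estimated.
    triples
        A :class:`TripleTable` built from the gene-tree sample.
    """

    def __init__(self, topology: Topology, triples: TripleTable):
        if topology.taxa != triples.taxa:
            raise ValueError("topology and triple table use different taxa")
        self.topology = topology
        self.triples = triples
        self.edges: list[frozenset[str]] = sorted(
            topology.clades, key=lambda c: (len(c), sorted(c))
        )
        tri = _ingroup_triples(topology.taxa)
        A = np.zeros((len(tri), len(self.edges)))
        n_conc = np.zeros(len(tri))
        n_disc = np.zeros(len(tri))
        for i, t in enumerate(tri):
            cherry = _resolution(topology.clades, t)
            (third,) = t - cherry
            for j, c in enumerate(self.edges):
                if cherry <= c and third not in c:
                    A[i, j] = 1.0
            cnt = triples.triple_counts(t)
            n_conc[i] = cnt[cherry]
            n_disc[i] = sum(cnt.values()) - cnt[cherry]
        self._A, self._n_conc, self._n_disc = A, n_conc, n_disc

    @classmethod
    def from_gene_trees(cls, topology: Topology, gene_trees: Sequence[GeneTree]):
        return cls(topology, build_triple_table(gene_trees, topology.taxa))

    @classmethod
    def from_distribution(cls, topology: Topology, dist: TopologyDistribution):
        return cls(topology, TripleTable.from_distribution(dist))

    # -- likelihood --------------------------------------------------------

    def loglike(self, lengths: np.ndarray) -> float:
        T = self._A @ lengths
        u = (2.0 / 3.0) * np.exp(-T)
        return float(
            np.sum(self._n_conc * np.log1p(-u))
            + np.sum(self._n_disc * (np.log(1.0 / 3.0) - T))
        )

    def score(self, lengths: np.ndarray) -> np.ndarray:
        T = self._A @ lengths
        u = (2.0 / 3.0) * np.exp(-T)
        w = self._n_conc * u / (1.0 - u) - self._n_disc
        return self._A.T @ w

    def hessian(self, lengths: np.ndarray) -> np.ndarray:
        T = self._A @ lengths
        u = (2.0 / 3.0) * np.exp(-T)
        w = -self._n_conc * u / (1.0 - u) ** 2
        return (self._A * w[:, None]).T @ self._A

    def fit(
        self,
        cap: float = 10.0,
        start: float = 0.5,
        tol: float = 1e-8,
        stem_length: float = 1.0,
    ) -> "SpeciesTreeFitResult":
        """Maximize the pseudo-likelihood with a bounded quasi-Newton optimizer.

        Lengths are constrained to [0, cap]; ``cap`` (default 10 coalescent
        units, concordance within 1e-4 of certainty) keeps perfectly
        concordant triples from driving lengths to infinity.
        """
        if cap <= 0:
            raise ValueError("cap must be > 0")
        x0 = np.full(len(self.edges), float(start))
        res = optimize.minimize(
            lambda x: -self.loglike(x),
            x0,
            jac=lambda x: -self.score(x),
            method="L-BFGS-B",
            bounds=[(0.0, cap)] * len(self.edges),
            options={"ftol": tol, "gtol": 1e-10, "maxiter": 500},
        )
        if not res.success and "ROUNDING" not in str(res.message).upper():
            raise RuntimeError(f"branch-length optimization failed: {res.message}")
        return SpeciesTreeFitResult(self, res.x, float(-res.fun), int(res.nit), cap, stem_length)


@dataclass
class SpeciesTreeFitResult:
    """Fitted internal branch lengths (coalescent units) and diagnostics."""

    model: TripleCoalescentModel
    params: np.ndarray
    llf: float
    n_iter: int
    cap: float
    stem_length: float

    @property
    def lengths(self) -> dict[frozenset[str], float]:
        return {c: float(v) for c, v in zip(self.model.edges, self.params)}

    @property
    def species_tree(self) -> SpeciesTree:
        return SpeciesTree(self.model.topology, self.lengths, stem_length=self.stem_length)

    def bse(self) -> dict[frozenset[str], float]:
        """Asymptotic standard errors from the observed information.

        Not meaningful for lengths at the boundary (0 or the cap), where NaN
        is returned.
        """
        H = self.model.hessian(self.params)
        with np.errstate(all="ignore"):
            try:
                cov = np.linalg.inv(-H)
                se = np.sqrt(np.diag(cov))
            except np.linalg.LinAlgError:
                se = np.full(len(self.params), np.nan)
        out = {}
        for c, v, s in zip(self.model.edges, self.params, se):
            at_bound = v <= 1e-9 or v >= self.cap - 1e-9
            out[c] = float("nan") if at_bound else float(s)
        return out

    def summary(self) -> str:
        lines = [
            "Triple pseudo-likelihood branch-length fit",
            f"  topology : {self.model.topology.canonical_newick}",
            f"  gene trees: {self.triples_total}   log-pseudolikelihood: {self.llf:.3f}"
            f"   iterations: {self.n_iter}",
            "",
            f"  {'clade':<40s} {'length (CU)':>12s} {'SE':>10s}",
        ]
        ses = self.bse()
        for c in self.model.edges:
            name = "(" + ",".join(sorted(c)) + ")"
            se = ses[c]
            se_s = f"{se:10.4f}" if np.isfinite(se) else "        --"
            lines.append(f"  {name:<40s} {self.lengths[c]:12.4f} {se_s}")
        lines.append("")
        lines.append("  terminal branches and the ingroup-root branch are not")
        lines.append("  identifiable from rooted triples and are not estimated.")
        return "\n".join(lines)

    @property
    def triples_total(self) -> int:
        return self.model.triples.n_trees

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("clade\tlength_cu\tse\n")
            ses = self.bse()
            for c in self.model.edges:
                fh.write(
                    f"{','.join(sorted(c))}\t{self.lengths[c]:.6g}\t{ses[c]:.6g}\n"
                )
            fh.write(f"#loglik\t{self.llf:.6g}\t\n#iterations\t{self.n_iter}\t\n")


def fit_branch_lengths(
    topology: Topology,
    triples: TripleTable,
    cap: float = 10.0,
) -> SpeciesTree:
    """Functional wrapper: fit lengths and return the fitted SpeciesTree."""
    return TripleCoalescentModel(topology, triples).fit(cap=cap).species_tree
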
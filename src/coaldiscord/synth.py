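"""Synthetic-data generators with known ground truth.

Everything the pipeline consumes can be generated here: MSC gene trees with
an optional ghost-lineage introgression component, sequence alignments
evolved on those trees (JC69), gene-tree re-estimation with bootstrap
supports (neighbor-joining on JC-corrected distances), allele-frequency
tables from explicit population histories simulated with msprime, and
per-window mutation-count tables.

Introgression is modeled as a gene-level tree mixture: each locus follows
the introgressed species tree with probability γ and the base species tree
otherwise, and the origin of every locus is recorded.  This keeps truth
labels exact and reproduces the discriminating signature: pure ILS leaves
the two resolutions flanking any internal branch equally frequent, whereas
introgression inflates exactly the donor-adjacent topology.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .fstats import FrequencyTable
from .msc import (
    SpeciesTree,
    TopologyDistribution,
    _compiled,
    _sim_clade_masks,
    simulate_gene_tree,
    tree_rng,
)
from .trees import (
    GeneTree,
    Node,
    TaxonSet,
    Topology,
    bovine_taxa,
    topology_from_clades,
    topology_from_clade_masks,
)
from .windows import WindowTable

__all__ = [
    "bovini_preset",
    "bovine_mt_topology_preset",
    "IntrogressionSpec",
    "ghost_into_wisent",
    "introgressed_species_tree",
    "DiscordanceDataset",
    "simulate_discordance_dataset",
    "simulate_discordance_distribution",
    "evolve_alignments",
    "estimate_gene_trees",
    "four_population_demography",
    "admixture_demography",
    "simulate_frequency_table",
    "simulate_window_counts",
]

# Internal branch lengths (coalescent units) for the six-taxon preset,
# calibrated once so that the simulated topology distribution reproduces the
# reference class frequencies (focal shape ~26.5%, the two cattle-lineage
# rearrangements ~14%, the deep wisent/bison moves ~3.1% each).
_PRESET_LENGTHS = {
    frozenset(["bison", "wisent"]): 0.90,
    frozenset(["bison", "wisent", "yak"]): 0.27,
    frozenset(["taurine", "zebu"]): 1.18,
}
_PRESET_TIPS = {
    "bison": 0.5,
    "wisent": 0.5,
    "yak": 1.4,
    "taurine": 0.49,
    "zebu": 0.49,
    "buffalo": 2.67,
}


def bovini_preset(lengths: Optional[dict[frozenset[str], float]] = None) -> SpeciesTree:
    """The six-taxon nuclear species tree with calibrated coalescent lengths.

    ``lengths`` may override any internal branch (keyed by ingroup clade).
    """
    taxa = bovine_taxa()
    topo = topology_from_clades(taxa, _PRESET_LENGTHS.keys())
    L = dict(_PRESET_LENGTHS)
    if lengths:
        for k, v in lengths.items():
            k = frozenset(k)
            if k not in L:
                raise KeyError(f"unknown internal branch {set(k)}")
            L[k] = float(v)
    return SpeciesTree(topo, L, stem_length=1.0, tip_lengths=dict(_PRESET_TIPS))


def bovine_mt_topology_preset() -> Topology:
    """The mitochondrial topology: wisent joined to the taurine-zebu lineage."""
    from .discordance import BOVINE_MT_NEWICK
    from .trees import parse_topology

    return parse_topology(BOVINE_MT_NEWICK, bovine_taxa())


# ---------------------------------------------------------------------------
# introgression


@dataclass(frozen=True)
class IntrogressionSpec:
    """A gene-level introgression component.

    ``donor`` is a taxon label, a clade (iterable of labels), or the string
    "ghost" meaning an extinct unsampled lineage; a ghost donor needs
    ``ghost_sister`` -- the sampled clade the ghost was sister to, where the
    recipient's introgressed lineages therefore attach.  ``proportion`` is
    the fraction γ of loci that follow the introgressed tree, and
    ``ghost_divergence`` the length (coalescent units) of the new internal
    branch above the recipient's attachment.
    """

    recipient: str
    donor: object = "ghost"
    proportion: float = 0.0
    ghost_divergence: float = 0.5
    ghost_sister: Optional[frozenset[str]] = None

    def __post_init__(self):
        if not 0.0 <= self.proportion <= 1.0:
            raise ValueError("proportion must be in [0, 1]")
        if self.ghost_divergence < 0:
            raise ValueError("ghost_divergence must be >= 0")

    def attachment(self) -> frozenset[str]:
        if self.donor == "ghost":
            if self.ghost_sister is None:
                raise ValueError("ghost donor requires ghost_sister")
            return frozenset(self.ghost_sister)
        if isinstance(self.donor, str):
            return frozenset([self.donor])
        return frozenset(self.donor)


def ghost_into_wisent(proportion: float, ghost_divergence: float = 0.5) -> IntrogressionSpec:
    """Ghost donor from the cattle lineage into wisent (mtDNA-transfer scenario)."""
    return IntrogressionSpec(
        recipient="wisent",
        donor="ghost",
        proportion=proportion,
        ghost_divergence=ghost_divergence,
        ghost_sister=frozenset(["taurine", "zebu"]),
    )


def introgressed_species_tree(st: SpeciesTree, spec: IntrogressionSpec) -> SpeciesTree:
    """The species tree an introgressed locus follows.

    The recipient is pruned from the base tree and re-attached as sister to
    the donor clade (for a ghost donor: to the clade the ghost was sister
    to).  Lengths of untouched branches are preserved; branches merged by
    the pruning are summed; the new branch above the attachment gets
    ``ghost_divergence``.
    """
    taxa = st.taxa
    rec = spec.recipient
    if rec not in taxa.ingroup:
        raise ValueError(f"recipient {rec!r} must be an ingroup taxon")
    attach = spec.attachment()
    if rec in attach:
        raise ValueError("recipient cannot be inside the donor clade")
    if not attach <= set(taxa.ingroup):
        raise ValueError("donor clade must be within the ingroup")

    # prune recipient: drop it from every clade, merging edges that collapse
    reduced: dict[frozenset[str], float] = {}
    for c, ln in st.internal_lengths.items():
        c2 = c - {rec}
        if len(c2) >= 2:
            reduced[c2] = reduced.get(c2, 0.0) + ln

    if attach not in reduced and len(attach) >= 2:
        raise ValueError(f"attachment clade {set(attach)} not in the pruned tree")

    # the attachment splits the stem edge above the donor clade: the part
    # below the attachment point stays on the donor clade, the part above
    # (capped at ghost_divergence) becomes the new recipient+donor branch
    new_lengths: dict[frozenset[str], float] = {}
    for c, ln in reduced.items():
        if c == attach:
            if spec.ghost_divergence > ln:
                raise ValueError(
                    f"ghost_divergence {spec.ghost_divergence} exceeds the "
                    f"donor stem length {ln}: attachment would create a "
                    "negative branch"
                )
            new_lengths[c] = ln - float(spec.ghost_divergence)
        elif attach < c:
            new_lengths[c | {rec}] = ln
        else:
            new_lengths[c] = ln
    new_clade = attach | {rec}
    new_lengths[new_clade] = float(spec.ghost_divergence)

    topo = topology_from_clades(taxa, new_lengths.keys())
    return SpeciesTree(topo, new_lengths, stem_length=st.stem_length,
                       tip_lengths=dict(st.tip_lengths))


# ---------------------------------------------------------------------------
# gene-tree datasets


@dataclass
class DiscordanceDataset:
    """Gene trees plus per-locus truth labels (ILS tree vs introgressed tree)."""

    gene_trees: list[GeneTree]
    introgressed: list[bool]
    species_tree: SpeciesTree
    intro: Optional[IntrogressionSpec]
    seed: int

    @property
    def gamma_realized(self) -> float:
        return sum(self.introgressed) / len(self.introgressed)

    def truth(self) -> dict:
        return {
            "n_genes": len(self.gene_trees),
            "gamma": self.intro.proportion if self.intro else 0.0,
            "gamma_realized": self.gamma_realized,
            "recipient": self.intro.recipient if self.intro else None,
            "seed": self.seed,
            "species_tree": self.species_tree.to_newick(),
        }

    def write(self, tree_path, truth_path) -> None:
        from .trees import write_newick_file

        write_newick_file(tree_path, self.gene_trees)
        with open(truth_path, "w") as fh:
            json.dump({**self.truth(), "introgressed": self.introgressed}, fh, indent=1)


def simulate_discordance_dataset(
    st: SpeciesTree,
    n_genes: int,
    intro: Optional[IntrogressionSpec] = None,
    seed: int = 0,
) -> DiscordanceDataset:
    """Simulate gene trees, each independently following the introgressed
    species tree with probability γ and the base tree otherwise."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    gamma = intro.proportion if intro is not None else 0.0
    st_alt = introgressed_species_tree(st, intro) if intro is not None else None
    trees, labels = [], []
    for i in range(n_genes):
        rng = tree_rng(seed, i)
        is_intro = rng.random() < gamma
        trees.append(simulate_gene_tree(st_alt if is_intro else st, rng))
        labels.append(is_intro)
    return DiscordanceDataset(trees, labels, st, intro, seed)


def simulate_discordance_distribution(
    st: SpeciesTree,
    n_genes: int,
    intro: Optional[IntrogressionSpec] = None,
    seed: int = 0,
) -> tuple[TopologyDistribution, int]:
    """Topology-only fast path; returns the distribution and the introgressed count."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    gamma = intro.proportion if intro is not None else 0.0
    ct = _compiled(st)
    ct_alt = _compiled(introgressed_species_tree(st, intro)) if intro is not None else None
    taxa = st.taxa
    mask_counts: dict[frozenset[int], int] = {}
    n_intro = 0
    for i in range(n_genes):
        rng = tree_rng(seed, i)
        use_alt = rng.random() < gamma
        n_intro += use_alt
        key = _sim_clade_masks(ct_alt if use_alt else ct, rng)
        mask_counts[key] = mask_counts.get(key, 0) + 1
    counts = {
        topology_from_clade_masks(taxa, k).canonical_newick: c
        for k, c in mask_counts.items()
    }
    return TopologyDistribution(counts, n_genes, taxa), n_intro


# ---------------------------------------------------------------------------
# sequence evolution and tree re-estimation


def evolve_alignments(
    gene_trees: Sequence[GeneTree],
    length: int = 300,
    scale: float = 0.02,
    seed: int = 0,
) -> list[dict[str, str]]:
    """Evolve JC69 alignments of ``length`` sites along each gene tree.

    ``scale`` converts coalescent-unit branch lengths to expected
    substitutions per site per coalescent unit; the default of 0.02 yields
    pairwise divergences of a few percent for trees a handful of units deep,
    like third-position/fourfold-degenerate data between closely related
    species.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if scale <= 0:
        raise ValueError("scale must be > 0")
    bases = np.array(list("ACGT"))
    out = []
    for i, gt in enumerate(gene_trees):
        rng = np.random.default_rng([seed, 0x5E0, i])
        seqs: dict[str, np.ndarray] = {}

        def walk(node: Node, parent_seq: Optional[np.ndarray]):
            if parent_seq is None:
                seq = rng.integers(0, 4, size=length)
            else:
                d = (node.length or 0.0) * scale
                p_change = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
                mask = rng.random(length) < p_change
                seq = parent_seq.copy()
                n_mut = int(mask.sum())
                if n_mut:
                    seq[mask] = (seq[mask] + rng.integers(1, 4, size=n_mut)) % 4
            if node.is_leaf:
                seqs[node.label] = seq
            else:
                for ch in node.children:
                    walk(ch, seq)

        walk(gt.root, None)
        out.append({lab: "".join(bases[s]) for lab, s in seqs.items()})
    return out


def _jc_distance_matrix(pdist: np.ndarray) -> np.ndarray:
    """JC69 correction; saturated p-distances are capped (and warned about)."""
    arg = 1.0 - 4.0 * pdist / 3.0
    sat = arg <= 0.0
    if np.any(sat):
        warnings.warn(f"{int(sat.sum())} saturated pairwise distances capped")
    with np.errstate(divide="ignore", invalid="ignore"):
        d = -0.75 * np.log(np.where(sat, 1.0, arg))
    return np.where(sat, 5.0, d)


def _nj_clusters(D: np.ndarray, masks: list[int]) -> list[int]:
    """Neighbor joining on a small distance matrix; returns merged-cluster
    bitmasks (every internal cluster created by a join)."""
    D = D.copy().astype(float)
    active = list(range(len(masks)))
    masks = list(masks)
    merged: list[int] = []
    while len(active) > 2:
        n = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (n - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = divmod(int(np.argmin(Q)), n)
        ai, aj = active[i], active[j]
        # distances from the new node
        dnew = 0.5 * (D[ai, active] + D[aj, active] - D[ai, aj])
        new = len(masks)
        masks.append(masks[ai] | masks[aj])
        merged.append(masks[new])
        D = np.pad(D, ((0, 1), (0, 1)))
        for idx, a in enumerate(active):
            D[new, a] = D[a, new] = dnew[idx]
        D[new, new] = 0.0
        active = [a for a in active if a not in (ai, aj)] + [new]
    return merged


def _clade_key_from_nj(merged: list[int], taxa: TaxonSet) -> frozenset[int]:
    ing = taxa.ingroup_mask
    out_bit = 1 << taxa.index(taxa.outgroup)
    k = taxa.n_ingroup
    clades = set()
    for m in merged:
        c = m if not m & out_bit else ing & ~m
        if 2 <= c.bit_count() <= k - 1:
            clades.add(c)
    return frozenset(clades)


def _gene_tree_from_topology(
    topo: Topology, supports: Optional[dict[frozenset[str], float]] = None
) -> GeneTree:
    taxa = topo.taxa

    def build(members: frozenset[str]) -> Node:
        if len(members) == 1:
            return Node(label=next(iter(members)))
        inside = [c for c in topo.clades if c < members]
        maximal = [c for c in inside if not any(c < d for d in inside if d is not c)]
        covered = set().union(*maximal) if maximal else set()
        children = maximal + [frozenset([l]) for l in members - covered]
        node = Node(children=[build(c) for c in children])
        if supports is not None and members in supports:
            node.support = supports[members]
        return node

    ing = build(frozenset(taxa.ingroup))
    if supports is not None:
        ing.support = supports.get(frozenset(taxa.ingroup), 100.0)
    root = Node(children=[ing, Node(label=taxa.outgroup)])
    return GeneTree(root, taxa, units="none")


def estimate_gene_trees(
    alignments: Sequence[dict[str, str]],
    taxa: TaxonSet,
    n_bootstrap: int = 100,
    seed: int = 0,
) -> list[GeneTree]:
    """Estimate a tree per alignment: NJ on JC-corrected distances, with
    bootstrap supports from ``n_bootstrap`` column resamples (percent of
    replicates recovering each clade of the point-estimate tree)."""
    base_codes = {b: i for i, b in enumerate("ACGT")}
    labels = list(taxa.labels)
    leaf_masks = [1 << taxa.index(l) for l in labels]
    pairs = [(i, j) for i in range(len(labels)) for j in range(i + 1, len(labels))]
    out = []
    for a_idx, aln in enumerate(alignments):
        missing = set(labels) - set(aln)
        if missing:
            raise ValueError(f"alignment {a_idx} lacks taxa {missing}")
        L = len(next(iter(aln.values())))
        S = np.array(
            [[base_codes.get(ch, -1) for ch in aln[l]] for l in labels], dtype=np.int8
        )
        diff = np.zeros((len(pairs), L), dtype=bool)
        for pi, (i, j) in enumerate(pairs):
            diff[pi] = S[i] != S[j]

        def dist_from_weights(w: np.ndarray) -> np.ndarray:
            p = (diff @ w) / w.sum()
            D = np.zeros((len(labels), len(labels)))
            for pi, (i, j) in enumerate(pairs):
                D[i, j] = D[j, i] = p[pi]
            return _jc_distance_matrix(D)

        D0 = dist_from_weights(np.ones(L))
        merged = _nj_clusters(D0, leaf_masks)
        key = _clade_key_from_nj(merged, taxa)
        topo = topology_from_clade_masks(taxa, key)

        rng = np.random.default_rng([seed, 0xB00, a_idx])
        hits = {c: 0 for c in key}
        for _ in range(n_bootstrap):
            w = rng.multinomial(L, np.full(L, 1.0 / L)).astype(float)
            bkey = _clade_key_from_nj(_nj_clusters(dist_from_weights(w), leaf_masks), taxa)
            for c in key:
                if c in bkey:
                    hits[c] += 1
        supports = {
            taxa.labels_of(c): 100.0 * h / n_bootstrap for c, h in hits.items()
        }
        out.append(_gene_tree_from_topology(topo, supports))
    return out


# ---------------------------------------------------------------------------
# allele-frequency tables (msprime)


def four_population_demography(
    Ne: float = 10_000,
    t_ab: float = 10_000,
    t_abc: float = 20_000,
    t_abcd: float = 40_000,
):
    """History (((A,B),C),D) with no gene flow; times in generations."""
    import msprime

    dem = msprime.Demography()
    for name in ("A", "B", "C", "D", "AB", "ABC", "ABCD"):
        dem.add_population(name=name, initial_size=Ne)
    dem.add_population_split(time=t_ab, derived=["A", "B"], ancestral="AB")
    dem.add_population_split(time=t_abc, derived=["AB", "C"], ancestral="ABC")
    dem.add_population_split(time=t_abcd, derived=["ABC", "D"], ancestral="ABCD")
    return dem


def admixture_demography(
    alpha: float,
    Ne: float = 10_000,
    t_admix: float = 2_000,
    t_ab: float = 10_000,
    t_abc: float = 20_000,
    t_root: float = 40_000,
):
    """History (((A,B),C),O) plus X, an instantaneous B/C mixture.

    X receives proportion ``alpha`` of its ancestry from B and 1-alpha from
    C at ``t_admix`` generations ago, so f4(A,O;X,C)/f4(A,O;B,C) = alpha.
    """
    import msprime

    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    dem = msprime.Demography()
    for name in ("A", "B", "C", "X", "O", "AB", "ABC", "ROOT"):
        dem.add_population(name=name, initial_size=Ne)
    dem.add_admixture(
        time=t_admix, derived="X", ancestral=["C", "B"], proportions=[1 - alpha, alpha]
    )
    dem.add_population_split(time=t_ab, derived=["A", "B"], ancestral="AB")
    dem.add_population_split(time=t_abc, derived=["AB", "C"], ancestral="ABC")
    dem.add_population_split(time=t_root, derived=["ABC", "O"], ancestral="ROOT")
    return dem


def simulate_frequency_table(
    demography,
    populations: Sequence[str],
    n_snps: int = 100_000,
    n_chrom: int = 5,
    seed: int = 0,
    samples_per_pop: int = 10,
    chrom_length: float = 1e6,
    recombination_rate: float = 1e-8,
    mutation_rate: float = 2.5e-8,
) -> FrequencyTable:
    """Coalescent-sampled derived-allele frequency table.

    ``n_chrom`` independent chromosomes are simulated (ancestry + binary
    mutations) and per-population derived-allele frequencies taken from the
    sample genotypes; the first ``n_snps`` segregating sites are kept.
    Coordinates span the chromosomes so multi-Mb jackknife blocks are
    meaningful.
    """
    import msprime

    rows_chrom: list[np.ndarray] = []
    rows_pos: list[np.ndarray] = []
    rows_freq: list[np.ndarray] = []
    total = 0
    for c in range(n_chrom):
        ts = msprime.sim_ancestry(
            samples={p: samples_per_pop for p in populations},
            demography=demography,
            sequence_length=chrom_length,
            recombination_rate=recombination_rate,
            random_seed=(seed * n_chrom + c) % (2**31 - 1) + 1,
        )
        ts = msprime.sim_mutations(
            ts,
            rate=mutation_rate,
            model=msprime.BinaryMutationModel(),
            random_seed=(seed * n_chrom + c) % (2**31 - 1) + 2,
        )
        pop_cols = []
        pop_ids = {p.metadata.get("name", str(p.id)): p.id for p in ts.populations()}
        sample_sets = [
            np.array(
                [s for s in ts.samples() if ts.node(s).population == pop_ids[p]]
            )
            for p in populations
        ]
        G = ts.genotype_matrix()  # sites x samples, 0/1
        positions = np.array([s.position for s in ts.sites()], dtype=np.int64) + 1
        # collapse duplicate integer positions (multiple mutations in one bp)
        _, keep_idx = np.unique(positions, return_index=True)
        G = G[keep_idx]
        positions = positions[keep_idx]
        freqs = np.stack([G[:, ss].mean(axis=1) for ss in sample_sets], axis=1)
        seg = (freqs.max(axis=1) > 0) & (freqs.min(axis=1) < 1)
        freqs, positions = freqs[seg], positions[seg]
        rows_chrom.append(np.full(len(positions), str(c + 1), dtype=object))
        rows_pos.append(positions)
        rows_freq.append(freqs)
        total += len(positions)
    if total < n_snps:
        warnings.warn(
            f"only {total} segregating sites obtained (requested {n_snps})"
        )
    df = pd.DataFrame(
        {
            "CHROM": np.concatenate(rows_chrom),
            "POS": np.concatenate(rows_pos),
        }
    )
    allf = np.concatenate(rows_freq, axis=0)
    for i, p in enumerate(populations):
        df[p] = allf[:, i]
    if total > n_snps:
        # thin evenly so the kept sites still span every chromosome
        idx = np.unique(np.linspace(0, total - 1, n_snps).round().astype(int))
        df = df.iloc[idx].reset_index(drop=True)
    return FrequencyTable(df, tuple(populations), polarization="ancestral")


# ---------------------------------------------------------------------------
# window-count tables


def simulate_window_counts(
    n_windows: int = 3530,
    window: int = 500_000,
    prior_mean: float = 494.0,
    prior_sd: float = 117.0,
    informative_low: int = 50_000,
    informative_high: int = 500_000,
    min_informative: int = 250_000,
    contamination: float = 0.0,
    contamination_factor: float = 2.0,
    seed: int = 0,
) -> WindowTable:
    """Per-window species-specific mutation counts with known truth.

    Windows get informative-site totals uniform on [informative_low,
    informative_high]; each window's count is binomial around an expected
    value drawn from the (truncated) normal prior, scaled by its informative
    fraction.  A ``contamination`` fraction of windows (ghost-introgressed
    mimics) uses ``contamination_factor`` times the prior mean.  Windows
    under ``min_informative`` are filtered exactly like the empirical scan.
    """
    from scipy import stats

    rng = np.random.default_rng([seed, 0x51D])
    info = rng.integers(informative_low, informative_high + 1, size=n_windows)
    a = -prior_mean / prior_sd
    mu = stats.truncnorm.rvs(
        a, np.inf, loc=prior_mean, scale=prior_sd, size=n_windows, random_state=rng
    )
    is_contam = rng.random(n_windows) < contamination
    mu = np.where(is_contam, mu * contamination_factor, mu)
    p = np.clip(mu / window, 0, 1)  # per-informative-site rate at 500 kb scale
    counts = rng.binomial(info, p)
    df = pd.DataFrame(
        {
            "chrom": "1",
            "start": np.arange(n_windows, dtype=np.int64) * window,
            "end": (np.arange(n_windows, dtype=np.int64) + 1) * window,
            "informative_sites": info,
            "count": counts,
        }
    )
    from .windows import filter_windows

    kept, _ = filter_windows(df, min_informative)
    kept["scaled_count"] = kept["count"] * window / kept["informative_sites"]
    return WindowTable(
        kept,
        window,
        n_total=n_windows,
        n_removed=n_windows - len(kept),
        meta={
            "statistic": "synthetic_species_specific",
            "prior_mean": prior_mean,
            "prior_sd": prior_sd,
            "contamination": contamination,
            "seed": seed,
        },
    )
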
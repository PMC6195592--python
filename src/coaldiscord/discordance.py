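"""Gene-tree discordance summaries and the nuclear-vs-mtDNA hypothesis test.

Machinery for asking whether a sample of gene-tree topologies is explained
by incomplete lineage sorting on a reference species tree, or points to the
alternative (e.g. mitochondrial) tree:

* ΔRF — signed difference of rooted RF distances to the two reference trees;
* a literal four-class scheme over the 105 six-taxon topologies (the
  reference shape, the two cattle-lineage rearrangements, the four yak
  moves, the two wisent/bison moves including the mtDNA shape, and "other");
* a multinomial likelihood-ratio test with a parametric-bootstrap null;
* goodness-of-fit of observed topology frequencies against coalescent
  expectations (proportionality coefficient and correlation, plus
  RF-distance multisets).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .msc import SpeciesTree, TopologyDistribution, simulate_topology_distribution
from .trees import (
    GeneTree,
    TaxonSet,
    Topology,
    bovine_taxa,
    enumerate_topologies,
    parse_topology,
    rf_distance,
)

__all__ = [
    "ClassScheme",
    "bovine_class_scheme",
    "delta_rf",
    "classify",
    "summarize",
    "DiscordanceSummary",
    "estimate_topology_probs",
    "log_multinomial_likelihood",
    "lrt_nuclear_vs_mt",
    "lrt_from_probs",
    "LRTResult",
    "goodness_of_fit",
    "GofResult",
    "pair_symmetry_test",
]

CLASS_LABELS = ("I", "II", "III", "IV", "other")

# The four-class scheme over the bovine six-taxon space.  Class I is the
# nuclear reference shape; Class II rearranges the taurine-zebu lineage;
# Class III moves yak; Class IV moves wisent or bison onto the cattle
# lineage (the second Class IV shape is the mtDNA topology).
_BOVINE_CLASS_STRINGS: dict[str, tuple[str, ...]] = {
    "I": ("((((bison,wisent),yak),(taurine,zebu)),buffalo)",),
    "II": (
        "((((taurine,zebu),yak),(bison,wisent)),buffalo)",
        "((((bison,wisent),(taurine,zebu)),yak),buffalo)",
    ),
    "III": (
        "((((bison,yak),wisent),(taurine,zebu)),buffalo)",
        "((((wisent,yak),bison),(taurine,zebu)),buffalo)",
        "((((taurine,yak),zebu),(bison,wisent)),buffalo)",
        "((((zebu,yak),taurine),(bison,wisent)),buffalo)",
    ),
    "IV": (
        "((((taurine,zebu),wisent),(bison,yak)),buffalo)",  # mtDNA topology
        "((((taurine,zebu),bison),(wisent,yak)),buffalo)",
    ),
}
BOVINE_NUCLEAR_NEWICK = _BOVINE_CLASS_STRINGS["I"][0]
BOVINE_MT_NEWICK = _BOVINE_CLASS_STRINGS["IV"][0]


@dataclass
class ClassScheme:
    """Mapping of every topology in the enumerated space to a class label."""

    nuclear_ref: Topology
    mt_ref: Topology
    class_map: dict[str, str]
    class_members: dict[str, tuple[Topology, ...]] = field(default_factory=dict)

    @property
    def taxa(self) -> TaxonSet:
        return self.nuclear_ref.taxa

    def label(self, t: Topology) -> str:
        try:
            return self.class_map[t.canonical_newick]
        except KeyError:
            raise ValueError(
                f"topology {t.canonical_newick} not in the enumerated space"
            ) from None


def bovine_class_scheme(taxa: Optional[TaxonSet] = None) -> ClassScheme:
    """The literal four-class scheme, canonicalized over the 105-topology space."""
    taxa = taxa or bovine_taxa()
    members: dict[str, tuple[Topology, ...]] = {}
    class_map: dict[str, str] = {}
    for label, strings in _BOVINE_CLASS_STRINGS.items():
        topos = tuple(parse_topology(s, taxa) for s in strings)
        members[label] = topos
        for t in topos:
            class_map[t.canonical_newick] = label
    others = []
    for t in enumerate_topologies(taxa):
        if t.canonical_newick not in class_map:
            class_map[t.canonical_newick] = "other"
            others.append(t)
    members["other"] = tuple(others)
    return ClassScheme(members["I"][0], members["IV"][0], class_map, members)


def classify(t: Topology, scheme: ClassScheme) -> str:
    """Class label of a topology under the scheme (I/II/III/IV/other)."""
    return scheme.label(t)


def delta_rf(t: Topology, nuclear_ref: Topology, mt_ref: Topology) -> int:
    """RF(t, mtDNA reference) - RF(t, nuclear reference).

    Positive for topologies closer to the nuclear tree, negative for those
    closer to the mtDNA tree, zero when equally distant.
    """
    return rf_distance(t, mt_ref) - rf_distance(t, nuclear_ref)


# ---------------------------------------------------------------------------
# summaries


@dataclass
class DiscordanceSummary:
    """Per-topology, per-class, and ΔRF-sign breakdown of a tree sample."""

    distribution: TopologyDistribution
    class_counts: dict[str, int]
    delta_rf_positive: int
    delta_rf_zero: int
    delta_rf_negative: int
    scheme: ClassScheme

    @property
    def total(self) -> int:
        return self.distribution.total

    def class_freq(self, label: str) -> float:
        return self.class_counts[label] / self.total

    def delta_rf_fractions(self) -> tuple[float, float, float]:
        n = self.total
        return (
            self.delta_rf_positive / n,
            self.delta_rf_zero / n,
            self.delta_rf_negative / n,
        )

    def summary(self) -> str:
        pos, zero, neg = self.delta_rf_fractions()
        lines = [
            f"Gene-tree discordance summary ({self.total} trees)",
            f"  ΔRF > 0 (nuclear-like): {pos:7.2%}",
            f"  ΔRF = 0 (equidistant) : {zero:7.2%}",
            f"  ΔRF < 0 (mtDNA-like)  : {neg:7.2%}",
            "  class frequencies:",
        ]
        for lab in CLASS_LABELS:
            lines.append(f"    {lab:<6s} {self.class_freq(lab):7.2%}  ({self.class_counts[lab]})")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("topology\tclass\tdelta_rf\tcount\tfrequency\n")
            taxa = self.scheme.taxa
            for key, n in sorted(self.distribution.counts.items(), key=lambda kv: -kv[1]):
                t = parse_topology(key, taxa)
                d = delta_rf(t, self.scheme.nuclear_ref, self.scheme.mt_ref)
                fh.write(
                    f"{key}\t{self.scheme.label(t)}\t{d}\t{n}\t{n / self.total:.6g}\n"
                )


def summarize(
    trees: Sequence[GeneTree] | TopologyDistribution, scheme: ClassScheme
) -> DiscordanceSummary:
    """Classify a tree sample and tabulate class and ΔRF-sign frequencies."""
    if isinstance(trees, TopologyDistribution):
        dist = trees
    else:
        dist = TopologyDistribution.from_gene_trees(trees, scheme.taxa)
    class_counts = {lab: 0 for lab in CLASS_LABELS}
    pos = zero = neg = 0
    for key, n in dist.counts.items():
        t = parse_topology(key, scheme.taxa)
        class_counts[scheme.label(t)] += n
        d = delta_rf(t, scheme.nuclear_ref, scheme.mt_ref)
        if d > 0:
            pos += n
        elif d < 0:
            neg += n
        else:
            zero += n
    return DiscordanceSummary(dist, class_counts, pos, zero, neg, scheme)


# ---------------------------------------------------------------------------
# multinomial likelihood-ratio test


def estimate_topology_probs(
    st: SpeciesTree,
    topologies: Sequence[Topology],
    n_sim: int,
    seed: int,
    pseudocount: float = 0.5,
) -> np.ndarray:
    """Coalescent topology probabilities by simulation, pseudocount-regularized.

    A pseudocount (default 0.5) is added to every topology's simulated count
    before normalizing, so no probability is exactly zero and observed-but-
    never-simulated topologies keep the log-likelihood finite.
    """
    dist = simulate_topology_distribution(st, n_sim, seed)
    counts = dist.to_vector(topologies)
    counts += pseudocount
    return counts / counts.sum()


def log_multinomial_likelihood(
    x: TopologyDistribution | np.ndarray,
    p: np.ndarray,
    topologies: Optional[Sequence[Topology]] = None,
    pseudocount: float = 0.0,
) -> float:
    """Multinomial log-likelihood Σ xᵢ log pᵢ (coefficient term omitted).

    The multinomial coefficient is constant in p, so omitting it leaves all
    likelihood-ratio statistics unchanged.  With ``pseudocount`` > 0, p is
    regularized to be strictly positive before use; with pseudocount 0 and
    some xᵢ > 0 where pᵢ = 0, -inf is returned with a warning.
    """
    if isinstance(x, TopologyDistribution):
        if topologies is None:
            raise ValueError("topologies needed to align a TopologyDistribution")
        xv = x.to_vector(topologies)
    else:
        xv = np.asarray(x, dtype=float)
    p = np.asarray(p, dtype=float)
    if pseudocount > 0:
        p = p + pseudocount / len(p)
        p = p / p.sum()
    if np.any((xv > 0) & (p == 0)):
        warnings.warn("observed topology with zero probability: log-likelihood is -inf")
        return float("-inf")
    with np.errstate(divide="ignore"):
        lp = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), 0.0)
    return float(xv @ lp)


@dataclass
class LRTResult:
    """Parametric-bootstrap multinomial LRT of nuclear vs mtDNA species tree."""

    t_obs: float
    L_nuclear: float
    L_mt: float
    bootstrap_t: np.ndarray
    p_value: float
    n_boot: int
    seed: Optional[int] = None
    add_one: bool = False

    def summary(self) -> str:
        return (
            "Multinomial likelihood-ratio test (parametric bootstrap)\n"
            f"  H0: mtDNA species tree   H1: nuclear species tree\n"
            f"  log L(nuclear) = {self.L_nuclear:.3f}\n"
            f"  log L(mtDNA)   = {self.L_mt:.3f}\n"
            f"  t_obs = 2·ΔL   = {self.t_obs:.3f}\n"
            f"  bootstrap replicates: {self.n_boot}\n"
            f"  p = P(t* > t_obs) = {self.p_value:.4g}"
        )


def lrt_from_probs(
    x_counts: np.ndarray,
    p_nuclear: np.ndarray,
    p_mt: np.ndarray,
    n_boot: int,
    rng: np.random.Generator,
    add_one: bool = False,
) -> LRTResult:
    """Core LRT given precomputed probability vectors (bootstraps from p_mt)."""
    x_counts = np.asarray(x_counts, dtype=float)
    total = int(round(x_counts.sum()))
    if total < 1:
        raise ValueError("empty topology distribution")
    if np.max(p_mt) > 1 - 1e-12 or np.max(p_nuclear) > 1 - 1e-12:
        warnings.warn("degenerate probability vector (all mass on one topology)")
    log_n = np.log(p_nuclear)
    log_m = np.log(p_mt)
    L_n = float(x_counts @ log_n)
    L_m = float(x_counts @ log_m)
    t_obs = 2.0 * (L_n - L_m)
    boots = rng.multinomial(total, p_mt, size=n_boot).astype(float)
    t_star = 2.0 * (boots @ log_n - boots @ log_m)
    exceed = int(np.sum(t_star > t_obs))
    if add_one:
        p = (exceed + 1) / (n_boot + 1)
    else:
        p = exceed / n_boot
    return LRTResult(t_obs, L_n, L_m, t_star, float(p), n_boot, add_one=add_one)


def lrt_nuclear_vs_mt(
    x: TopologyDistribution,
    st_nuclear: SpeciesTree,
    st_mt: SpeciesTree,
    n_sim_probs: int = 200_000,
    n_boot: int = 1000,
    seed: int = 0,
    pseudocount: float = 0.5,
    add_one: bool = False,
) -> LRTResult:
    """Test whether observed topology frequencies favor the nuclear tree.

    Topology probabilities under each species tree are estimated by MSC
    simulation (``n_sim_probs`` trees each); the null distribution of
    t = 2(L(nuclear) - L(mtDNA)) comes from ``n_boot`` multinomial samples
    of the observed size drawn under the mtDNA probabilities.  The p-value
    is the strict proportion of bootstrap statistics above the observed one.
    """
    if x.total < 1:
        raise ValueError("empty topology distribution")
    taxa = x.taxa
    topologies = enumerate_topologies(taxa)
    p_n = estimate_topology_probs(st_nuclear, topologies, n_sim_probs, seed * 2 + 1, pseudocount)
    p_m = estimate_topology_probs(st_mt, topologies, n_sim_probs, seed * 2 + 2, pseudocount)
    x_counts = x.to_vector(topologies)
    rng = np.random.default_rng([seed, 0xB007])
    res = lrt_from_probs(x_counts, p_n, p_m, n_boot, rng, add_one=add_one)
    res.seed = seed
    return res


# ---------------------------------------------------------------------------
# goodness of fit


@dataclass
class GofResult:
    """Fit of observed topology frequencies to coalescent expectations.

    ``c`` is the slope of the least-squares line through the origin relating
    observed frequencies P̂ to expected probabilities P (c near 1 means the
    coalescent model reproduces the observed frequencies); ``pearson_r`` the
    correlation; the RF multisets compare tree-to-species-tree distances for
    observed vs simulated samples.
    """

    c: float
    pearson_r: float
    rf_observed: np.ndarray
    rf_simulated: list[np.ndarray]
    rf_values: np.ndarray

    def summary(self) -> str:
        sim_means = [
            (h * self.rf_values).sum() / h.sum() for h in self.rf_simulated
        ]
        obs_mean = (self.rf_observed * self.rf_values).sum() / self.rf_observed.sum()
        return (
            "Coalescent goodness of fit\n"
            f"  proportionality c (P̂ = cP): {self.c:.4f}\n"
            f"  Pearson r(P̂, P)           : {self.pearson_r:.4f}\n"
            f"  mean RF to species tree    : observed {obs_mean:.3f}, "
            f"simulated {np.mean(sim_means):.3f} over {len(self.rf_simulated)} replicates"
        )


def goodness_of_fit(
    x: TopologyDistribution,
    p: np.ndarray,
    st: SpeciesTree,
    n_reps: int = 1000,
    rep_size: Optional[int] = None,
    seed: int = 0,
) -> GofResult:
    """Compare observed topology frequencies with coalescent expectations.

    ``p`` must be aligned with ``enumerate_topologies(x.taxa)``.  Replicate
    RF multisets are multinomial samples of ``rep_size`` trees (default: the
    observed total) from ``p``, binned by RF distance to ``st``.
    """
    taxa = x.taxa
    topologies = enumerate_topologies(taxa)
    p = np.asarray(p, dtype=float)
    x_counts = x.to_vector(topologies)
    if x_counts.sum() == 0 or np.allclose(p, 0):
        raise ValueError("degenerate inputs")
    p_hat = x_counts / x_counts.sum()
    if np.var(p) == 0 or np.var(p_hat) == 0:
        raise ValueError("zero-variance frequencies")
    c = float((p_hat @ p) / (p @ p))
    r = float(np.corrcoef(p_hat, p)[0, 1])

    rf = np.array([rf_distance(t, st.topology) for t in topologies])
    rf_values = np.arange(0, rf.max() + 2, 2)
    obs_hist = np.array(
        [x_counts[rf == v].sum() for v in rf_values]
    )
    rep_size = rep_size or int(x_counts.sum())
    rng = np.random.default_rng([seed, 0x60F])
    sims = []
    draws = rng.multinomial(rep_size, p / p.sum(), size=n_reps)
    for row in draws:
        sims.append(np.array([row[rf == v].sum() for v in rf_values]))
    return GofResult(c, r, obs_hist, sims, rf_values)


def pair_symmetry_test(
    dist: TopologyDistribution, a: Topology, b: Topology
) -> "PairSymmetryResult":
    """Exact binomial test that two mirror topologies are equally frequent.

    Under pure ILS the two resolutions flanking a single internal branch
    have identical expected frequency; a significant imbalance (excess of
    one member) is the signature of introgression.
    """
    na, nb = dist.count(a), dist.count(b)
    n = na + nb
    if n == 0:
        raise ValueError("neither topology observed")
    test = stats.binomtest(na, n, 0.5)
    se = 0.5 * np.sqrt(n)  # binomial SD of the count under symmetry
    z = (na - n / 2) / se if se > 0 else 0.0
    return PairSymmetryResult(na, nb, float(test.pvalue), float(z))


@dataclass
class PairSymmetryResult:
    count_a: int
    count_b: int
    p_value: float
    z: float

    def summary(self) -> str:
        return (
            f"Pair symmetry test: {self.count_a} vs {self.count_b}  "
            f"z = {self.z:.3f}, two-sided p = {self.p_value:.4g}"
        )
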
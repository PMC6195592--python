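import json
import math

import numpy as np
import pytest

from coaldiscord.discordance import classify
from coaldiscord.fstats import d_statistic, f3
from coaldiscord.msc import simulate_topology_distribution
from coaldiscord.speciesfit import build_triple_table
from coaldiscord.synth import (
    IntrogressionSpec,
    admixture_demography,
    bovini_preset,
    estimate_gene_trees,
    evolve_alignments,
    four_population_demography,
    ghost_into_wisent,
    introgressed_species_tree,
    simulate_discordance_dataset,
    simulate_discordance_distribution,
    simulate_frequency_table,
    simulate_window_counts,
)
from coaldiscord.trees import canonicalize, parse_newick, support_filter

from conftest import MT_NEWICK


class TestBoviniPreset:
    def test_default_is_reference_class(self, scheme):
        st = bovini_preset()
        assert classify(st.topology, scheme) == "I"

    def test_long_branches_lock_topology(self, scheme):
        st = bovini_preset({c: 10.0 for c in bovini_preset().topology.clades})
        dist = simulate_topology_distribution(st, 3000, seed=1)
        assert dist.freq(st.topology) > 0.999

    def test_zero_branches_scramble_topology(self):
        st = bovini_preset({c: 0.0 for c in bovini_preset().topology.clades})
        dist = simulate_topology_distribution(st, 20_000, seed=2)
        # every topology reachable; the reference shape far from dominant
        assert len(dist.counts) == 105
        assert dist.freq(st.topology) < 0.1

    def test_unknown_override_rejected(self):
        with pytest.raises(KeyError):
            bovini_preset({frozenset(["bison", "zebu"]): 1.0})


class TestIntrogression:
    def test_spec_validation(self):
        with pytest.raises(ValueError):
            IntrogressionSpec(recipient="wisent", proportion=1.5)
        with pytest.raises(ValueError):
            ghost_into_wisent(0.1, ghost_divergence=-1)

    def test_ghost_tree_is_mt_topology(self, taxa, scheme):
        alt = introgressed_species_tree(bovini_preset(), ghost_into_wisent(0.1))
        assert alt.topology == scheme.mt_ref

    def test_leaf_donor_attachment(self, taxa):
        st = bovini_preset()
        spec = IntrogressionSpec(recipient="wisent", donor="yak", proportion=0.1)
        alt = introgressed_species_tree(st, spec)
        assert frozenset(["wisent", "yak"]) in alt.topology.clades

    def test_gamma_zero_matches_pure_msc(self, preset, scheme):
        dist, n_intro = simulate_discordance_distribution(preset, 5000, seed=3)
        assert n_intro == 0
        pure = simulate_topology_distribution(preset, 5000, seed=301)
        # same generative process: reference-class frequencies agree
        f1, f2 = dist.freq(scheme.nuclear_ref), pure.freq(scheme.nuclear_ref)
        se = math.sqrt(2 * 0.27 * 0.73 / 5000)
        assert abs(f1 - f2) < 3 * se

    def test_overlong_ghost_divergence_rejected(self, preset):
        with pytest.raises(ValueError, match="negative branch"):
            introgressed_species_tree(preset, ghost_into_wisent(1.0, ghost_divergence=3.0))

    def test_gamma_one_mt_topology_dominates(self, preset, scheme):
        spec = ghost_into_wisent(1.0, ghost_divergence=0.8)
        dist, n_intro = simulate_discordance_distribution(preset, 3000, intro=spec, seed=4)
        assert n_intro == 3000
        top = max(dist.counts, key=dist.counts.get)
        assert top == scheme.mt_ref.canonical_newick

    def test_small_gamma_produces_excess(self, preset, scheme):
        base, _ = simulate_discordance_distribution(preset, 60_000, seed=5)
        spiked, n_intro = simulate_discordance_distribution(
            preset, 60_000, intro=ghost_into_wisent(0.04), seed=5
        )
        assert 0 < n_intro < 60_000
        # the excess of the donor-adjacent (mtDNA) topology is about
        # gamma times the introgressed tree's concordance with it
        excess = spiked.freq(scheme.mt_ref) - base.freq(scheme.mt_ref)
        alt = introgressed_species_tree(preset, ghost_into_wisent(0.04))
        conc = simulate_topology_distribution(alt, 20_000, seed=6).freq(scheme.mt_ref)
        realized_gamma = n_intro / 60_000
        se = math.sqrt(2 * spiked.freq(scheme.mt_ref) / 60_000)
        assert excess == pytest.approx(realized_gamma * conc, abs=3 * se + 0.01)
        assert excess > 0

    def test_dataset_truth_labels(self, preset, tmp_path):
        ds = simulate_discordance_dataset(
            preset, 300, intro=ghost_into_wisent(0.2), seed=7
        )
        assert len(ds.gene_trees) == len(ds.introgressed) == 300
        assert 0.1 < ds.gamma_realized < 0.35
        ds.write(tmp_path / "t.nwk", tmp_path / "truth.json")
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert truth["gamma"] == 0.2
        assert sum(truth["introgressed"]) == sum(ds.introgressed)

    def test_determinism(self, preset):
        a = simulate_discordance_dataset(preset, 50, seed=8)
        b = simulate_discordance_dataset(preset, 50, seed=8)
        assert [t.to_newick() for t in a.gene_trees] == [t.to_newick() for t in b.gene_trees]


class TestAlignmentsAndEstimation:
    def test_strong_signal_recovers_topology(self, taxa, preset):
        ds = simulate_discordance_dataset(preset, 20, seed=9)
        alns = evolve_alignments(ds.gene_trees, length=10_000, scale=0.1, seed=9)
        est = estimate_gene_trees(alns, taxa, n_bootstrap=20, seed=9)
        hits = [canonicalize(e) == canonicalize(t) for e, t in zip(est, ds.gene_trees)]
        assert sum(hits) >= 18
        # genes whose every internal branch is long enough to leave mutations
        # must be recovered exactly
        for hit, gt in zip(hits, ds.gene_trees):
            shortest = min(
                n.length for n in gt.root.postorder()
                if not n.is_leaf and n.length is not None
            )
            if shortest >= 0.05:
                assert hit

    def test_alignment_shape_and_determinism(self, preset):
        ds = simulate_discordance_dataset(preset, 3, seed=10)
        a1 = evolve_alignments(ds.gene_trees, length=300, scale=0.02, seed=10)
        a2 = evolve_alignments(ds.gene_trees, length=300, scale=0.02, seed=10)
        assert a1 == a2
        assert all(len(s) == 300 for aln in a1 for s in aln.values())
        assert set(a1[0]) == set(preset.taxa.labels)

    def test_star_trees_get_low_supports(self, taxa):
        st = bovini_preset()
        # collapse internal branches only: terminal variation remains, so the
        # bootstrap sees data but cannot resolve any grouping
        ds = simulate_discordance_dataset(st, 10, seed=11)
        for t in ds.gene_trees:
            for n in t.root.postorder():
                if not n.is_leaf and n.length:
                    n.length = 1e-6
        alns = evolve_alignments(ds.gene_trees, length=300, scale=0.02, seed=11)
        est = estimate_gene_trees(alns, taxa, n_bootstrap=30, seed=11)
        sups = [s for t in est for s in t.internal_supports() if s is not None]
        assert np.mean(sups) < 80

    def test_support_filter_enriches_true_topology(self, taxa, preset, scheme):
        # short loci at moderate divergence: filtering on bootstrap support
        # keeps a subset that is enriched for the true (Class I) topology
        ds = simulate_discordance_dataset(preset, 150, seed=12)
        alns = evolve_alignments(ds.gene_trees, length=300, scale=0.02, seed=12)
        est = estimate_gene_trees(alns, taxa, n_bootstrap=50, seed=12)
        kept = support_filter(est, 75)
        assert 0 < len(kept) < len(est)

        def class_i_frac(trees):
            return np.mean([classify(canonicalize(t), scheme) == "I" for t in trees])

        assert class_i_frac(kept) > class_i_frac(est)


class TestNeighborJoining:
    def test_matches_biopython_on_random_matrices(self, taxa):
        # independent oracle: Biopython's NJ on the same distance matrices
        from Bio.Phylo.TreeConstruction import DistanceMatrix, DistanceTreeConstructor

        from coaldiscord.synth import _clade_key_from_nj, _nj_clusters
        from coaldiscord.trees import topology_from_clade_masks

        rng = np.random.default_rng(30)
        labels = list(taxa.labels)
        leaf_masks = [1 << taxa.index(l) for l in labels]
        constructor = DistanceTreeConstructor()
        for _ in range(15):
            # additive-ish noisy distances from random leaf depths
            depths = rng.uniform(0.05, 0.5, size=len(labels))
            D = np.add.outer(depths, depths) * (1 + rng.uniform(0, 0.2, (6, 6)))
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0.0)
            mine = topology_from_clade_masks(
                taxa, _clade_key_from_nj(_nj_clusters(D, leaf_masks), taxa)
            )
            dm = DistanceMatrix(
                labels, [[float(D[i, j]) for j in range(i + 1)] for i in range(6)]
            )
            bio = constructor.nj(dm)
            theirs = canonicalize(parse_newick(bio.format("newick"), taxa))
            assert mine == theirs


class TestFrequencyTables:
    def test_null_d_is_quiet(self):
        ft = simulate_frequency_table(
            four_population_demography(), ["A", "B", "C", "D"],
            n_snps=20_000, n_chrom=10, seed=13,
        )
        assert ft.n_sites == 20_000
        assert ft.data["CHROM"].nunique() == 10
        res = d_statistic(ft, "A", "B", "C", "D")
        assert abs(res.z) < 3

    def test_polarization_and_range(self):
        ft = simulate_frequency_table(
            four_population_demography(), ["A", "B", "C", "D"],
            n_snps=5_000, n_chrom=2, seed=14,
        )
        assert ft.polarization == "ancestral"
        vals = ft.data[["A", "B", "C", "D"]].to_numpy()
        assert vals.min() >= 0 and vals.max() <= 1

    def test_admixed_f3_detects_mixture(self):
        # strong, recent mixture: the classic negative-f3 signal
        ft = simulate_frequency_table(
            admixture_demography(alpha=0.5, t_admix=100, t_ab=40_000,
                                 t_abc=80_000, t_root=120_000),
            ["A", "B", "C", "X", "O"], n_snps=50_000, n_chrom=10, seed=15,
        )
        res = f3(ft, "X", "B", "C")
        assert res.estimate < 0
        assert res.z < -3

    def test_determinism(self):
        dem = four_population_demography()
        f1 = simulate_frequency_table(dem, ["A", "B", "C", "D"], n_snps=2000,
                                      n_chrom=2, seed=16)
        f2 = simulate_frequency_table(dem, ["A", "B", "C", "D"], n_snps=2000,
                                      n_chrom=2, seed=16)
        assert f1.data.equals(f2.data)


class TestWindowCounts:
    def test_determinism_and_truth(self):
        w1 = simulate_window_counts(n_windows=200, seed=17)
        w2 = simulate_window_counts(n_windows=200, seed=17)
        assert w1.data.equals(w2.data)
        assert w1.meta["prior_mean"] == 494.0
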
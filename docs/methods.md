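# Methods

## The question and the model

Six bovine species — American bison, wisent, yak, taurine cattle, zebu and
the water buffalo outgroup — radiated fast enough that individual loci
carry conflicting genealogies, and the mitochondrial genome supports a tree
(wisent joined to the taurine–zebu lineage) that contradicts the nuclear
consensus ((((bison,wisent),yak),(taurine,zebu)),buffalo). The package
asks, quantitatively, whether that conflict is what the multispecies
coalescent (MSC) already predicts from short internal branches, or whether
it requires gene flow — possibly from an extinct, unsampled ("ghost")
relative of the cattle lineage.

Under the MSC, gene lineages coalesce backward in time inside the branches
of the species tree. Time is measured in coalescent units (CU; one unit =
2N generations with per-branch population size folded into the branch
length). Within a branch containing k lineages, the next coalescence is
exponential with rate k(k−1)/2; the root branch is infinite. For a rooted
triple whose cherry is separated from the third taxon by an internal path
of length T, the concordant resolution has probability 1 − (2/3)e^(−T) and
each discordant resolution (1/3)e^(−T). These closed forms serve as the
simulator's oracle and as the likelihood kernel of the branch-length fit.

## Canonical topologies and ΔRF

All statistics operate on rooted shapes over the fixed taxon set: a gene
tree is re-rooted on the outgroup edge and reduced to its set of proper
ingroup clades; the canonical Newick string orders children by smallest
descendant label. Two design points matter:

* **RF is the rooted, clade-based variant.** The reference topologies are
  written rooted, and the unrooted bipartition variant would conflate
  distinct rooted classes. The outgroup leaf and the full-ingroup clade are
  excluded from the clade sets (they are shared by every re-rooted tree).
  With k = 5 ingroup taxa each tree contributes k−2 = 3 clades, the maximum
  distance is 2(k−2) = 6, and all distances are even.
* **Topology identity is clade-set identity**, so enumeration (leaf
  insertion with canonical deduplication) provably yields (2k−3)!! shapes:
  105 for the six-taxon problem.

ΔRF(t) = RF(t, mtDNA tree) − RF(t, nuclear tree); positive values mark
nuclear-like trees. The four-class scheme is generated at start-up by
canonicalizing the literal reference Newick strings (class I: the nuclear
shape; II: the two cattle-lineage rearrangements; III: the four yak moves;
IV: the two wisent/bison moves, the mtDNA shape among them; everything
else "other"), and partitions the 105-space as 1/2/4/2/96.

## What is — and is not — symmetric under ILS

The discriminating signature of ILS is exchangeability: the two resolutions
flanking a single internal branch are equally frequent. This is exact for
the class IV pair (the two deep wisent/bison moves). It is **not** exact
for the class II pair: one of those shapes is reached by a balanced deep
coalescence and the other by a caterpillar one, and the coalescent is
uniform over ranked histories, not over shapes, so their expected
frequencies differ by a few percent (≈14.3% vs ≈13.5% on the preset). For
the same reason, collapsing all internal branches to zero does *not* give a
uniform distribution over the 105 topologies; the exact distribution
follows from the hook-length count of merge orderings, and the test suite
checks the simulator against that closed form. Tests therefore assert
exact symmetry only where theory provides it, and similarity (ratio
< 1.15) for the class II pair.

## Branch-length fitting (`TripleCoalescentModel`)

Internal branch lengths on a *fixed* topology are estimated by a rooted-
triple pseudo-likelihood: for each of the C(5,3) = 10 ingroup triples the
three resolution counts are trinomial with concordance probability
1 − (2/3)e^(−T_path), T_path being the sum of internal branches between
the triple's cherry and its MRCA. The log pseudo-likelihood is maximized
with L-BFGS-B on the raw lengths, bounds [0, cap], start 0.5 CU for every
edge, ftol 1e−8. Choices worth recording:

* **cap = 10 CU** (concordance within 1e−4 of certainty) keeps perfectly
  concordant data from diverging; hitting the cap means "effectively
  infinite".
* **Bounds act on the raw scale, not a log transform**, because fitting a
  conflicting topology (the mtDNA tree) legitimately drives lengths to
  exactly zero, which a log transform cannot represent.
* **Terminal branches and the branch above the ingroup root are not
  estimated**: with one lineage per species they do not enter any ingroup
  triple probability (deep coalescences are exchangeable), so they are
  unidentifiable; the summary says so explicitly.
* Standard errors come from the analytic observed information and are
  reported as missing for boundary estimates.

## The nuclear-vs-mtDNA likelihood-ratio test

Let X be the vector of observed topology counts over the 105-space and P_j
the topology probabilities under species tree j (nuclear or mtDNA, each
with branch lengths fitted to the same data). X is multinomial given P_j;
the statistic is t = 2(L(τ_nuclear) − L(τ_mtDNA)) with L = Σ x_i log p_i
(the multinomial coefficient cancels). Because the hypotheses are
topologies, t has no χ² null; the null distribution is built from
parametric-bootstrap multinomial samples of size |X| drawn under P_mtDNA,
and p = P(t* > t_obs) with strict inequality (an add-one option that never
reports exactly zero is available, off by default).

P_j is estimated by simulation — 200,000 trees by default, scaled down in
tests — with a **pseudocount of 0.5** added to every topology count before
normalizing. Without it, a topology observed in the data but absent from a
finite simulation would send L to −∞.

Goodness of fit compares observed frequencies P̂ with expected P via the
origin-constrained least-squares coefficient c = ΣP̂P/ΣP² (c ≈ 1 means the
coalescent reproduces the observed frequencies), the Pearson correlation,
and RF-to-species-tree distance multisets; replicate multisets are
multinomial draws from P binned by distance.

## f-statistics and the block jackknife

D, f3, outgroup-f3, f4 and the f4-ratio use the frequency generalizations
of the pattern-count forms (with frequencies in {0,1} they reduce to
counting), with **no small-sample bias corrections** — the plain products
of frequency differences. Standard errors use the weighted block jackknife
(Busing's formulation) over contiguous non-overlapping 5 Mb blocks per
chromosome, last partial block kept, weights proportional to per-block
informative-site counts; for ratio statistics the whole ratio is recomputed
with each block deleted. For a statistic linear in sites the jackknife
point estimate provably equals the plain mean (asserted against an
independent re-implementation). Significance is the conventional |Z| > 3
with the two-sided normal p reported alongside. The f4-ratio warns when
the denominator f4 has |Z| < 1 and refuses an exactly zero denominator.

## Window scans and the binomial null

Windows are **non-overlapping 500 kb tiles** in 0-based half-open
coordinates (1-based input positions are converted; a step knob exists but
tiling is the default, consistent with a genome/500 kb window count). A
site is informative when every involved species has an unambiguous A/C/G/T
allele; Dxy = differences / informative sites; a site is focal-specific
when all other species share one allele and the focal allele differs.
Windows with fewer than 250 kb informative sites are dropped and counted
(retained + removed = total).

The no-introgression null for per-window specific counts draws, per
simulation, an expected count μ from Normal(mean 494, SD 117) truncated at
zero, picks a window uniformly, draws Binomial(n, μ/n) with n that
window's informative sites, and scales to 500 kb. The printed prior
parameters pin the model; where the procedure is ambiguous (one μ per
simulation vs per window; scaling by window span vs informative length)
the defaults are one μ per simulation and span scaling, both recorded in
the output metadata. Observed and simulated distributions are compared by
a two-sample KS test; "consistent" means KS p > 0.01. A 10% contamination
of windows with a doubled mean — the ghost-introgression mimic — is
reliably flagged.

## Synthetic data: what it emulates and what it does not

* **Gene trees.** The six-taxon preset uses internal lengths 0.90 CU
  (bison,wisent), 0.27 CU (bison,wisent,yak), 1.18 CU (taurine,zebu) —
  calibrated once so the simulated class frequencies land at the reference
  pattern (class I ≈ 26.5%, class IV ≈ 3.1% each); the stem and tip
  lengths (near-ultrametric, buffalo at 2.67 CU) only shape output branch
  lengths. Introgression is a **gene-level tree mixture**: each locus
  follows, with probability γ, a species tree in which the recipient is
  re-attached as sister to the donor clade (for the ghost-into-wisent
  scenario, to the taurine–zebu clade, yielding exactly the mtDNA
  topology). This keeps per-locus truth labels exact; it does not model
  continuous migration, recombination within loci, or post-hybridization
  drift.
* **Alignments.** JC69 only, default 300 bp at 0.02 substitutions/site/CU
  (a few percent pairwise divergence, like third-position data between
  close species). Gene trees are re-estimated by neighbor joining on
  JC-corrected distances with bootstrap supports from column resampling
  (default 100 replicates) — a deliberately simple, fast estimator whose
  output feeds the same support filter (> 75% at every internal node) as
  any external tree set. Saturated p-distances (≥ 3/4) are capped at 5
  substitutions/site with a warning.
* **Allele frequencies.** msprime coalescent simulations of explicit
  4–5-population demographies (default Ne = 10⁴; splits at 10, 20, 40 kgen;
  admixture pulse at 2 kgen), ten 1 Mb chromosomes, binary mutations, ten
  diploids per population; sites are thinned evenly to the requested SNP
  count so jackknife blocks span every chromosome. Real data differ in
  ascertainment, error, and linkage scale — which is why the tests check
  calibration and parameter recovery, not real-data point estimates.

Every generator is deterministic given (parameters, seed); per-tree RNG
substreams are derived from (seed, locus index) so regeneration is
bit-identical and order-independent.

## Problem sizes and numerical conventions

Simulation sizes in the test suite are scaled to what the statistics need:
topology-probability estimation uses 50k–200k trees (SE of a class
frequency < 0.2%), LRT calibration uses 200 replicates of 3306 loci with
200 bootstrap draws, the D-statistic null uses 50 replicates of 10⁵ SNPs,
and recovery runs use 10⁴ trees / 2×10⁵ SNPs. Statistical assertions use
3·SE bands where an estimator targets a known value, and chi-square
goodness-of-fit at α = 10⁻⁴ where a whole distribution is compared, to
keep fixed-seed false alarms rare without loosening the science.

Degenerate inputs are handled explicitly: polytomies are flagged on parse
and rejected by canonicalization; trees missing taxa are excluded from
summaries; zero-probability topologies only arise with the pseudocount
disabled and then return −∞ with a warning; empty windows yield missing
Dxy; a ghost divergence longer than the donor stem raises rather than
silently collapsing a branch.

## Known limitations

* The rooted-triple pseudo-likelihood is not the full MSC likelihood; it
  is consistent for branch lengths on a fixed topology but does not search
  topology space.
* The tree-mixture introgression model has no migration bands and no
  within-locus recombination; γ is a locus-level probability, not a
  population-genetic migration rate.
* NJ/JC estimation understates the uncertainty a full ML analysis would
  model; it is the package's stand-in for external tree inference, and any
  externally estimated Newick trees can be supplied instead.
* The binomial window null treats windows as exchangeable draws; it does
  not model spatial autocorrelation of mutation density along a genome.
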
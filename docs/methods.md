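# Methods

## The test

`paradiverge` asks whether the same SNPs repeatedly show unusually high
allele-frequency divergence in *phylogenetically independent* pairs of
population groups — the genomic signature expected when spatially varying
selection acts on shared standing variation in separate lineages.

Given diploid genotypes for populations assigned to ≥4 groups related by
an unrooted tree, the pipeline:

1. reduces the genotypes to per-population allele counts
   (`io_model.SnpTable`);
2. keeps SNPs that are **globally polymorphic** (segregating within the
   pooled counts of every analyzed group pair) and **intermediate
   frequency** (global minor-allele frequency strictly above 0.4), then
   draws seeded random subsets that are **unlinked** (pairwise composite
   |D| < 0.1 within 10 Mb, averaged over one large representative
   population per group) and have **matched site-frequency spectra**
   across groups (ten 5% MAF bins; any two groups' bin counts may differ
   by <100 SNPs or by ≤5% of the larger bin) (`filtering`);
3. computes the Weir–Cockerham (1984) two-deme F_ST estimator
   θ̂ = a/(a+b+c) for every SNP and every analyzed group pair, using
   observed heterozygote counts where available and 2p̂(1−p̂) otherwise
   (`divergence.weir_cockerham_fst`);
4. enumerates every **divergence comparison** — an unordered pair of
   disjoint group pairs whose tip-to-tip tree paths share no edge — and,
   at threshold t (default 0.05), intersects the two pairs' top-floor(tN)
   F_ST sets to obtain the **parallel divergent SNPs**; each such SNP is
   oriented **same**/**opposite** according to whether the sign of the
   frequency difference in the first (lexicographically ordered) pair
   matches that in the second (`divergence`);
5. tests the counts and the **orientation skew** (major-orientation
   frequency) against a fixed-margins hypergeometric null, Fisher's exact
   test, an exact binomial test, and neutral-simulation nulls (`stats`,
   `simulate.run_null_suite`).

Under neutrality the overlap K of two independent size-m divergent sets
among N SNPs is Hypergeometric(N, m, m): E[K] = m²/N ≈ N·t² (67.16 at
N = 26,864, t = 0.05) and SD[K] ≈ 7.79 (computed with the real-valued
margin m = tN, which matches the exact hypergeometric SD whenever tN is
an integer).  Orientations are i.i.d. fair coins, so the expected skew is
E[max(X, K−X)]/K with X ~ Binomial(K, ½) — 0.55 at K = 67, decaying to ½
like √(1/2πK).

## Numerical and procedural choices

- **Divergent-set size.** Exactly floor(t·N) SNPs per pair, using a
  seeded strict total order (ties in F_ST broken uniformly at random at
  panel construction).  A fixed size makes the hypergeometric null exact
  and makes rank-sector grids have fixed margins; the top-right cell of a
  20-bin sector grid is then exactly the parallel divergent count at
  t = 0.05.
- **Ranks.** Rank 1 = lowest F_ST internally; report files also emit
  `rank_from_top` (1 = highest), the convention used in genome-scan
  figures.
- **Greedy subset accretion.** Candidates are shuffled with the replicate
  seed and accepted one at a time iff the LD rule holds against every
  accepted SNP within the window and the running spectra stay compatible;
  a rejected SNP is never revisited within the replicate.  Accretion
  stops after one full pass or on reaching a target size (the analysis
  protocol draws subsets of exactly 26,864 SNPs).  An accepted subset is
  re-verified post hoc by an independent full check.
- **Composite LD** is the genotypic composite coefficient
  Δ = (1/2n)Σgᴬgᴮ − 2p̂ᴬp̂ᴮ, computable without phasing; |Δ| is
  thresholded because negative disequilibrium violates independence
  equally.  Monomorphic loci make Δ undefined (an error, not zero).
- **Two-sided tests.** Fisher's exact test is two-sided (this reproduces
  a Bonferroni-critical overlap of 91 at N = 26,864, t = 0.05, α = 0.05/15;
  one-sided tails would give ~89–90).  The binomial skew test doubles the
  upper tail and caps at 1.  Empirical simulation p-values use the
  add-one estimator (1 + #{sim ≥ obs})/(n + 1).
- **Admixture diagnostic.** For each comparison, SNPs divergent in either
  pair are removed, survivors re-ranked per pair, and the rank vectors
  correlated (Pearson on ranks ≡ Spearman); a correlation significant at
  α = 0.05/15 flags possible gene flow between the pairs.
- **Degenerate inputs.** Exact frequency ties make a SNP's orientation
  undefined; such SNPs are excluded from the skew tally and counted.
  K = 0 yields an undefined skew (None), not an exception.

## The synthetic-data generator

The generator emulates the statistical structure of a worldwide
SNP-array panel: 19 populations (343 diploids) in six groups
(PY, WA, EU, EA, OC, SA) on the tree (((PY,WA),EU),(OC,(EA,SA))), with
the largest population per group (Biaka, Mandenka, Sardinian, Han,
Papuan, Karitiana) serving as the LD reference.  Simulated raw sites are
filtered to a pool of ~110–140k globally polymorphic intermediate-
frequency SNPs from which matched-spectra subsets of 26,864 are drawn —
the scale of the emulated study.

**Site-drift mode** (default).  Each SNP draws an ancestral frequency
from the neutral 1/(p(1−p)) spectrum truncated to [0.35, 0.65]
(log-odds-uniform; the truncation concentrates simulation effort on
sites that can survive the downstream MAF > 0.4 filter) and is propagated
forward through the group tree by per-generation binomial Wright–Fisher
sampling, with bottlenecks and growth as effective-size trajectories and
migration as deterministic migrant-fraction mixing.  Demographies are
diffusion-rescaled: generations and sizes are divided by `time_scale`
(default 20) and per-generation rates multiplied by it, which preserves
per-branch drift variance t/2N while making a full-scale dataset cost
seconds.  Sites are statistically independent by construction and are
therefore placed farther apart than the LD window; the LD-pruning stage
is exercised by sequence mode and by unit fixtures instead.  Diploid
genotype counts are drawn per population under Hardy–Weinberg
proportions at the group frequency.

**Sequence mode** delegates to msprime: unlinked 100 kb regions, a
per-site mutation rate of 2×10⁻⁹, and per-region recombination rates
drawn uniformly from [0, 11.25×10⁻⁸] (configurable), with dosage
matrices attached for the representative populations so the pruning
stage sees realistic LD.

**Calibration of the standard preset.**  The preset's split times follow
the human out-of-Africa order of events; its effective sizes were
calibrated against the *pipeline's own diagnostics* rather than copied
from demographic literature, because two interactions make naive
parameters misbehave under the analysis protocol:

1. *Spectrum-matching selection.*  When the pool-level MAF spectra of the
   groups differ, the greedy matched-spectra accretion preferentially
   retains SNPs whose folded frequencies agree across groups; such SNPs
   have coupled divergence across group pairs, which inflates the neutral
   parallel count well above m²/N.
2. *Estimator-induced orientation coupling.*  The Weir–Cockerham
   normalization is dominated by the heterozygosity of the
   larger-sample group of a pair, so F_ST tails are enriched for SNPs
   whose large-sample group sits off-center; because "off-center" is
   shared across pairs through the SNP's global frequency, the
   orientations of parallel divergent SNPs become correlated and the
   neutral skew rises above the binomial expectation.

Both artifacts grow with per-group frequency spread around the
sample-weighted global frequency.  The standard preset therefore uses
effective sizes that keep per-group spread modest and nearly equal
across groups (founder bottlenecks of 950–990 diploids over 50
generations for EU, OC, SA, PY and WA-sized analogues, long-term sizes
of 8–50k), yielding near-identical pool spectra, neutral grand-mean
parallel counts within a few percent of N·t², and neutral skews close to
the binomial expectation.  These sizes are effective-model parameters
for the ascertained intermediate-frequency SNP class — not literal
demographic estimates — and the residual neutral biases (~+3–4% in the
grand mean count, ~+0.02 in skew) are an honest property of the
generator, reported as-is by the acceptance machinery.

**Alternative presets** mirror the study's robustness scenarios
qualitatively: `3tightestbottle` tightens the three tightest founder
bottlenecks to 150 diploids over 50 generations; `OC-EAmig100` adds 100
migrants per generation between OC and EA (and `OC-EAmig10` a moderate
10); `nobottle` removes all bottlenecks; `constantlow` fixes every
lineage at a constant low size (3,000) with no growth.  At matched
scale, the three extreme presets each inflate the grand-mean parallel
count relative to `standard`, reproducing the qualitative robustness
ladder; the bottleneck preset also saturates the spectrum-matching
earlier (smaller attainable subsets), which is the intended
population-specific ascertainment effect.

**Selection spiking** models parallel adaptation post hoc: chosen SNPs
get a ±shift applied to the group frequencies of a comparison's two
pairs (sign pattern fixed by the requested orientation) and their
genotype counts are re-sampled.  Spiking is applied to analyzed subsets
when testing recovery, since the spectrum-matching step otherwise
dilutes spiked sites (their shifted group frequencies fall into
under-supplied spectrum bins — itself a faithful property of the
protocol).  Because a spike moves frequencies in four of the six
groups, other comparisons that re-pair those groups with unequal shift
signs inherit part of the signal; only comparisons without such an
asymmetric re-pairing are expected to stay at null levels, and the
spiked comparison itself remains the most extreme.

**What the generator does not emulate.**  Within-group population
substructure (populations share their group's lineage frequency, so
group-level Wahlund effects are absent); genotyping error and missing
data; real SNP-array ascertainment (approximated by the truncated
ancestral spectrum plus the frequency filters); linkage in site-drift
mode.  Passing simulation tests therefore demonstrates correctness and
calibration of the statistical machinery on idealized panel-like data,
not robustness to array artifacts.

## Problem sizes used by tests and the acceptance script

Analytic checks are instant.  The neutral standard suite runs 20
independent datasets (240k raw sites → ~130k-site pools → one
26,864-SNP subset each; ~20 s per dataset).  The robustness ladder runs
8 datasets per preset at a common 6,500-SNP subset size, chosen so that
every preset (including the saturating bottleneck model) can reach the
target; the spike-recovery check uses the same scale.  These sizes are
the package's own desk-scale choices and are stated in the relevant
test docstrings.
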
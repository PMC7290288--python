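# Methods

## Data model

A mobile element insertion (MEI) call set is a loci × samples matrix of
alternate-allele dosages {0, 1, 2, missing}, one row per nonreference
insertion site, with per-locus metadata: element class (Alu, LINE-1,
SVA), subfamily label, insertion orientation, target-site-duplication
length, and the caller's 0–5 evidence tier (5 = TSD resolved on both
sides).  Insertions are treated as biallelic presence/absence
polymorphisms; the ancestral state is absence.  Coordinates are 1-based
insertion points internally; comparisons against BED-style annotation
convert to half-open 0-based at the annotation module boundary.

## Call-set intersection

Two call sets are matched positionally within ±w bp (default 25),
requiring identical chromosome and element class.  Matching is
one-to-one: candidate pairs are consumed nearest-first, ties broken by
the lower coordinate pair.  The window is inclusive (|Δpos| ≤ w).
Loci of the query set without a partner are "novel" relative to the
comparison set.

## Quality screen

1. **Caller filter.** Keep PASS records with evidence tier ≥ 5.
2. **Hardy–Weinberg screen.** For each locus, within every major
   population group, an exact conditional test: the heterozygote count
   is compared against its distribution given the allele counts
   (probabilities ∝ multinomial × 2^het), two-sided by summing all
   configurations no more probable than the observed one.  The exact
   test rather than a χ² approximation because per-group counts are
   small (25–75 diploids).  A locus is removed if it fails in *any*
   group at α/m, where m is the number of loci tested for that element
   class (Bonferroni across loci; correcting additionally across groups
   is available via a flag — the convention is genuinely ambiguous and
   the default is the less aggressive reading).  The removal report
   records the direction of each failure: systematic heterozygote
   excess is the signature of reads from two near-identical genomic
   copies collapsing onto one locus.
3. **Analysis panel.** For structure analyses: drop samples with ≥10%
   missingness, then loci with ≥10% missingness or overall minor allele
   frequency < 0.02, then greedy keep-first LD pruning within a
   500-locus sliding window so no retained pair exceeds r² = 0.2
   (composite genotype correlation, pairwise-complete).  MAF is
   computed after HWE removal.  All three stages are idempotent.

## Enrichment and orientation

Under uniform random insertion the expected count in a genome
compartment is proportional to its size in Mb:
`expected_c = round(total × size_c / total_Mb)` (half-up).  The default
compartment sizes (3′-UTR 90.75, 5′-UTR 21.02, coding 41.94, intronic
1,830.01, nongenic 1,273.63; total 3,257.35 Mb) are the build-38
RefSeq-style partition used throughout.  Enrichment/depletion is tested
two-sided with Fisher's exact test on the 2×2 table [observed,
total−observed; expected, total−expected]; since the published analyses
do not pin down the exact table construction, a direct
Binomial(total, size/total) alternative is available via
`method="binomial"`.  Printed p-value magnitudes are not a contract of
this package — expected counts and significance calls at the
Bonferroni-corrected level (5 classes per element type) are.
Overlapping annotations resolve by precedence coding > 5′-UTR > 3′-UTR
> intronic > nongenic.  Orientation bias in genes is a two-sided
one-sample z-test of the opposite-orientation proportion against
p₀ = 0.5 with null variance p₀(1−p₀)/n and no continuity correction.

## Diversity and structure

* Individual heterozygosity: heterozygous / called sites per sample.
* Private alleles: loci whose nonreference alleles are confined to one
  individual — singleton heterozygotes *and* homozygous doubletons.
* F_ST: Weir & Cockerham (1984) variance components a (among groups),
  b (among individuals within groups), c (within individuals) per
  locus, with the heterozygosity terms; multi-locus
  θ̂ = Σa / Σ(a+b+c) (ratio of sums, the "weighted" estimator that
  vcftools reports).  Negative per-locus components are retained;
  loci monomorphic across the groups analysed, or with <2 groups
  having ≥2 called samples, are skipped.  Note a finite-sample
  property: in degenerate designs where between-group variance is
  *exactly* zero (e.g. duplicated genotype columns), θ̂ is biased
  negative at order 1/(n̄−1).
* Allele-sharing distance: d(i,j) = mean over pairwise-complete loci of
  |dosage_i − dosage_j|/2, scaled to [0,1].
* Ordination: classical PCoA (Gower-centred −d²/2, eigendecomposition).
  Negative eigenvalues (non-Euclidean noise) are dropped with a logged
  warning; axis signs are fixed by making the largest-magnitude loading
  positive.  A genotype-covariance PCA would be an alternative reading
  of "PCA of the distances"; PCoA is the one implemented because the
  pipeline feeds a distance matrix into the ordination.
* Nei's standard distance on per-group allele frequencies with both
  allele classes in the sums; identity 0 (opposite fixation everywhere)
  saturates to +inf with a warning.
* Neighbor joining: Saitou–Nei with Q-matrix joins; ties broken on the
  lexicographically lowest leaf-label pair; negative branch lengths
  clamped to zero with a warning.  Exactly inverts additive matrices.

## Geography and ancestry centroids

Great-circle distances use the haversine formula with Earth radius
6,371.0088 km.  Distances into the Americas are routed as two segments
through Naukan, Chukotka (66.027222, 169.7077782) — the Beringian
corridor model.  The geographic origin of a shared-ancestry component
is summarised by the centroid of all Old World individuals (every major
group except Americas) whose component fraction strictly exceeds a
threshold (1% and 6.25% are the conventional cut points).  The centroid
is spherical — coordinates → unit vectors, mean, renormalise — because
naive lat/lon averaging fails across the antimeridian, exactly where
Siberian and Beringian samples sit.  Each passing individual counts
once; an ancestry-weighted variant is available via a flag.

The centroid is an estimator of the gradient source only when passing
individuals sample the source's neighbourhood roughly isotropically;
with strongly one-sided sampling (e.g. all samples south-west of the
source) it is biased toward the sampled side no matter how many
individuals pass.  The recovery experiments therefore use a
ring-geometry cohort (groups placed around the planted source), while
threshold-sensitivity behaviour (raising 1% → 6.25% moves the centroid
toward the high-ancestry pole) is demonstrated on the world-map cohort.

## Subfamily analysis

Aggregation: AluYe–AluYk collapse to "AluYe-k"; AluYb other than
Yb8/Yb6 to "AluYb(other)"; AluYa other than Ya5 to "AluYa(other)";
everything else, including LINE-1 labels, passes through.  A subfamily
is shared by a group when any of its loci has a carrier there; the
headline statistic is the whole-percent fraction of subfamilies present
in all seven groups.

Haplotype alignments mask the hypervariable middle A-rich region and 3′
poly(A) tail (auto-detected as A-runs ≥5 and the trailing A-run of the
consensus; explicit column sets accepted).  Effective columns =
unmasked and gap-free in every sequence; all distances and per-site
statistics use them.

**Median-joining network.**  Distinct haplotypes form the node set; the
minimum spanning network over Hamming distances (all edges tied at each
Kruskal weight level, with ε slack) is augmented by iteratively adding
median (Steiner) vectors of linked triplets — column-majority of three
sequences where a majority exists — whose connection cost is within ε
of the minimum, then pruning inferred nodes of degree < 3.  ε defaults
to 0, preserving reticulations.  Node weight is the supporting locus
count (a `min_loci` display threshold reproduces the ≥10-locus
convention of subfamily-scale figures).  A mutation on an edge is
flagged as a CpG transition when it is a transition whose consensus
context is a CG dinucleotide.

**Diversity.**  π is the mean pairwise difference per effective site,
computed by the O(S·n) allele-frequency shortcut (per column,
1 − ΣC(n_s,2)/C(n,2)); Watterson's Θ = S/(a₁·L); Tajima's D uses the
standard constants a₁,a₂,b₁,b₂,c₁,c₂,e₁,e₂ and is undefined (NaN) for
S = 0 or n < 4.  Θ is reported per site (the per-sequence alternative
is just a factor of L).

## Synthetic data

The generator's defaults are the study conditions the pipeline targets:

* **Cohort.**  296 samples in seven groups (Africa 49, West Eurasia 75,
  South Asia 49, Central Asia/Siberia 26, East Asia 46, Oceania 25,
  Americas 26); 1,200 Alu + 250 LINE-1 + 80 SVA loci by default — a
  scaled-down locus count (the real call sets run to ~14,000) chosen so
  simulation-based tests complete in seconds; estimator-recovery runs
  scale `n_loci` up explicitly.
* **Allele frequencies.**  Ancestral frequencies uniform on
  (0.05, 0.95); per-group frequencies Balding–Nichols
  Beta(p(1−F)/F, (1−p)(1−F)/F).  Either a uniform F (panmictic
  ancestor; used for F_ST recovery, headline check: F = 0.08 recovered
  within ±0.01 at 5,000 loci) or the "founder_ladder" preset:
  Africa drifts F = 0.02 from the ancestor; non-Africans share an
  out-of-Africa pulse F = 0.08 then drift individually (0.03–0.10);
  the Americas are founded *from the Central Asia/Siberia pool*
  (F = 0.12), planting the Beringian affinity.  This ladder reproduces
  the qualitative patterns the pipeline is meant to detect: an
  Africa-first heterozygosity gradient, Africa-highest singleton rates,
  PCo1 separation of Africa, Africa–Americas as the largest pairwise
  F_ST, and Americas joining Central Asia/Siberia first in the group
  tree.
* **Planted defects.**  3% of loci all-heterozygous in every sample
  (the collapsed-duplicate signature; the HWE screen must remove
  them — observed removal ≈3%, inside the expected 1–4% band, 100%
  het-excess), 30% group-private rare loci with Africa-weighted group
  assignment (planting the singleton gradient), 50% flagged novel, 1%
  missingness (skipped on planted loci so truth stays unambiguous).
* **Geography/ancestry.**  Samples jitter ~500 km around per-group
  centroids (configurable — the centroid-recovery experiment uses a
  ring around the source); the focal ancestry component decays
  exponentially (scale 2,500 km, amplitude 0.6, ×U(0.7,1.3) noise)
  with haversine distance from the source (default 54.0, 91.0);
  Americas individuals carry 0.75–0.95 of it directly.  Fractions
  normalise to 1.
* **Haplotypes.**  Families evolve from a deterministic Alu-like 281-bp
  consensus (GC-rich body, middle A-rich linker, poly(A) tail).  Star
  mode: tips hang off the founder with Poisson(μ) private mutations —
  D < 0 in ≥95% of replicates.  Coalescent mode: Kingman genealogy with
  Poisson mutations per branch — mean D over 200 replicates within
  ±0.3 of 0.  Mutations avoid masked columns, are transition-biased
  (0.7) and CpG-upweighted (×6).  `infinite_sites=True` lets each
  column mutate at most once, making data exactly tree-realizable for
  network-correctness checks; finite-sites is the default and can
  legitimately produce parallel hits.

What passing on synthetic data does *not* show: the generator has no
linkage disequilibrium between loci, no genotyping-error model beyond
the planted het-excess loci, no realistic human demography (no
migration, growth, or admixture beyond the ancestry-fraction gradient),
and haplotype families evolve independently of the genotype cohort.
Results on real call sets depend on upstream caller behaviour that is
out of scope here.

## Numerical choices

* HWE exact test in log space (gammaln); the observed-probability
  comparison uses a 1+1e−12 relative guard against ties lost to
  rounding.  Exactness verified against an exact-rational enumeration
  oracle over every configuration with ≤50 diploids (max |Δp| < 1e−9).
* Expected counts round half-up (`floor(x+0.5)`), matching printed
  tables; banker's rounding would differ at .5 boundaries.
* Monomorphic loci: HWE p = 1; F_ST skips them; Nei sums include both
  allele classes so monomorphic loci contribute identically to all
  groups.
* Degenerate inputs error loudly: empty panels, pairs sharing no called
  loci, all-zero distance matrices, no individual over the ancestry
  threshold.
* All generator randomness flows from one mandatory seed through named
  crc32-tagged substreams; same configuration ⇒ byte-identical VCF.

## Problem sizes

Default test-suite sizes: 296 × 1,530 cohort, 5,000-locus F_ST
recovery, 200 neutral + 40 star haplotype replicates (n = 30–60 tips),
~5,500–23,000 HWE oracle configurations.  The full suite runs in well
under a minute; `scripts/acceptance.py` in a few seconds.
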
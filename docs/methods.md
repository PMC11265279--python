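# Methods

This package re-implements, as a tested pipeline over synthetic data, the
analysis of a smear-ripened cheese surface virome: construction of
species-level viral operational taxonomic units (vOTUs) from assembled
contigs, count normalization, succession and persistence statistics, and
negative-binomial differential abundance. This note records the models,
the defaults and why they are set where they are, the numerical choices,
and what the synthetic experiments do and do not demonstrate.

## Pairwise scoring and the vOTU catalog

Every sequence-level decision reduces to one scalar per contig pair: the
**identity x coverage score**, with identity = matches over aligned
columns and coverage = aligned fraction of the *shorter* contig. The
shorter-contig convention makes a fragment contained in a longer genome
score high, which is the intended behaviour for species-level
dereplication, and makes the score exactly symmetric. Thresholds are
handled as fractions: species clustering at >= 0.90, dairy-catalog
matching at >= 0.30, chimera flagging when the self-alignment total
exceeds 1.10 of contig length (strict inequality in all three cases; the
catalog length filter is a strict > 2,000 bp).

The internal aligner is a light seed-and-extend: exact k-mers (k = 11,
words occurring more than 8 times per contig masked) matched on both
strands, chained per diagonal (a chain needs two seeds that do not
overlap — a single shared 12-mer produces two overlapping 11-mer seeds
and is ignored — and a gap of at most 200 bp between seeds), then
extended ungapped with an x-drop of 20; hits shorter than 100 aligned bp
are discarded. Extension is ungapped because the synthetic mutation model
is substitution-only; externally produced (gapped) alignments enter
through the PSL reader and are reduced with the same union/score rule.
When several hits cover one pair, hits are admitted greedily by match
count and kept only if at least half of each hit covers new query ground;
coverage uses the union of query blocks and identity is the
match-weighted mean over admitted hits. The self-alignment fraction sums
query-side block lengths over all self-hits including the trivial
full-length hit, so a repeat-free contig scores 1.0 and an internal
duplication pushes the total above the 1.10 chimera threshold.

Clustering is greedy longest-first: contigs sorted by decreasing length
(ties by identifier) either join the first existing representative they
score >= 0.90 against or found a new cluster. Representatives are
cluster-longest by construction and the ordering makes the partition
independent of input order. Viral selection keeps a vOTU if its
representative is rated complete/high/medium by VIBRANT or CheckV or
"full" by VirSorter2; the PhiX174 sequencing control is removed
afterwards, by label or (when a reference sequence is supplied) by
alignment at the dairy cutoff. The reported quality tier prefers CheckV
over VIBRANT (CheckV is the completeness-dedicated tool). Dairy-catalog
ties break by alphabetical phage name, and a dairy match overrides the
host-prediction (iPHoP) genus with the matched phage's verified host.

## Normalization chain

Raw counts are rarefied (multivariate hypergeometric subsampling, i.e.
exact draw-without-replacement) to the minimum per-sample depth *of the
arm being analysed* — short-term and long-term arms are rarefied
independently — then divided by vOTU length (mean coverage), total-sum
scaled to relative abundances, and filtered at a strictly-greater-than
0.005% mean relative abundance. Group-level abundance tables (phage group
x sample) are computed on the read-proportion scale, without the length
division.

## Succession statistics

Shannon diversity is reported in nats. Bray-Curtis dissimilarity,
classical PCoA (negative eigenvalues of the semi-metric are dropped),
one-factor PERMANOVA with freely permuted labels, the Spearman Mantel
test, tie-corrected Kruskal-Wallis and Spearman correlation matrices are
all implemented from their definitions; scipy/scikit-bio implementations
serve as independent cross-checks in the test suite, never as the
implementation. Permutation p-values use (1 + exceedances)/(1 +
permutations), so p = 0 cannot occur.

Trajectory clustering of the abundant vOTUs uses agglomerative complete
linkage on Euclidean distances with deterministic tie-breaking. Three
choices protect the temporal signal from noise, and are the package's own
analysis decisions:

- profiles are built on the **read-proportion scale** (rarefied counts,
  total-sum scaled) rather than the coverage scale: genome-length division
  adds almost two decades of per-vOTU level offsets that carry no temporal
  information and would dominate Euclidean distances;
- replicates are **averaged per stage before the log**: the mean of a few
  heavy-tailed replicate draws is far better behaved than the mean of
  their logs for rare vOTUs;
- the log pseudo-count is pinned at the abundance-filter value (0.005%),
  so shares below the filter's resolution map to a common detection
  floor instead of amplifying noise in the unresolvable range.

The number of trajectory clusters is chosen from the within-cluster
sum-of-squares (WSS) curve of dendrogram cuts k = 1..k_max with a
scree-style rule: keep the largest k whose log-WSS drop both exceeds a
baseline estimated from the tail of the curve (2.2x the tail median, but
at least a quarter of the largest drop) and is at least 1.3x the next
drop. On planted well-separated clusters this recovers the true count
exactly (verified for k = 2, 3, 5, 7) and returns k = 1 for unstructured
data. A plain maximum second difference of the WSS was rejected: on
multi-scale data it locks onto the single dominant split regardless of
how many clusters exist. On realistic noisy communities the chosen k
remains a noisy model-selection statistic; the end-to-end test therefore
checks its mode over ten seeded replicates rather than one draw.

## Differential abundance

The test follows the DESeq2 recipe from raw counts: median-of-ratios size
factors (reference = features positive in every sample), method-of-moments
gene-wise dispersions on normalized counts (variance computed within
groups when a design is given), shrinkage halfway toward a trend
alpha(mu) = a/mu + b, a per-feature NB log-linear model fitted by
iteratively reweighted least squares (vectorized across features), a Wald
test on the group coefficient with normal reference, Benjamini-Hochberg
correction, and the three-way call: adjusted p < 0.01, |log2FC| > 3 and
mean raw count > 1,500. A feature more abundant in the second group of
the contrast gets a positive log2FC. The trend is fitted by least squares
through per-bin medians of the gene-wise cloud (8 quantile bins on the
mean): raw least squares over features would let the enormous moment
estimates of rare features set the intercept for the whole catalog.
Deliberate simplifications relative to DESeq2: no Cox-Reid adjustment, no
Cook's-distance outlier handling, no independent filtering; the target is
calibrated inference (type-I error at nominal level, verified by
simulation) rather than bit-equality with DESeq2. The published analysis
states both an adjusted-p cutoff of 0.01 (methods) and 0.05 (results
text); the stricter 0.01 is the default and 0.05 is a configuration
switch.

## Persistence

A vOTU is present in a production year if any replicate of that year has
a count above the threshold (default 0), which makes the Venn partition
invariant to sample order and to monotone transforms of abundance. The
core virome is the intersection of the abundance-filtered set with the
present-in-all-years set. Percentages round half-up to one decimal.

## Synthetic communities

The generator is the study-conditions oracle: it emits contig sets, tool
reports, a dairy reference catalog, count tables, a correlated bacterial
genus table and plate counts, with all ground truth recorded. All
generators are pure functions of (design, seed).

Sequence level: one reference genome per vOTU (length log-uniform on
[2 kb, 150 kb]); a configurable fraction of vOTUs get 1-3 member copies
mutated at 3% per base (substitution-only, so alignment identity is
analytically predictable and full-DP identity equals per-position
identity) and some get outgroup copies at 25% (a distinct species at the
0.90 threshold); chimeras are a genome plus its own first half; plus
sub-2 kb fragments, non-viral contigs and a PhiX174-labelled decoy.

Community level: guilds with stage dynamics — stable; declining as
rate^(stage-1) (so a planted log2 fold change between the {W1,W2} and
{W4,W5} stage-group means of exactly 3 log2 rate); rising along a
logistic calibrated so that the same stage-group ratio equals the
guild's fold (a 16-fold rise is planted log2FC = +4) — with lognormal
per-vOTU weights inside each guild. Counts are sampled per replicate as
Dirichlet(theta x expected composition) followed by a multinomial with a
lognormal library size (10^5 +- 0.15 log10 by default). theta = 200 is a
free choice (no quantitative replicate-noise model is published for this
system) and sets a fairly high replicate noise: the relative SD of a
vOTU's share is roughly (200 x share)^(-1/2), i.e. ~50% for a 2% vOTU.

The default community (100 vOTUs, 5 stages x 3 replicates, 3 years x 3
replicates — the published study at roughly one-third scale) plants five
trajectory classes among the abundant vOTUs: an abundant band (stable
936/949 Lactococcus guilds plus an abundant declining P335-like guild), a
low declining guild fading below the count gate, two 16-fold rising
ripening guilds (Glutamicibacter- and Brevibacterium-hosted), a late
Pseudoalteromonas-hosted guild climbing from the detection floor only in
the final stages, and a sporadic floor band. The split of the declining
and rising roles into "abundant, differential-abundance-bearing" and
"low, trajectory-cluster-bearing" guilds is forced by two structural
facts: (a) a log2FC = -4 decliner that clears the >1,500 mean-raw-count
gate at a 10^5 library necessarily starts at the abundant band's level
and crosses it, so it cannot simultaneously be a separable trajectory
cluster; and (b) a 16-fold rise in stage-group means spans roughly
40-120x endpoint to endpoint, so abundant early-saturating risers would
dominate the late-stage composition. Guild sizes keep the stable band the
majority of the all-positive reference features, which median-of-ratios
normalization requires; violating this (checked empirically) biases every
log2FC by the rank shift of the median within the reference set.

The long-term arm reuses the genome pool: each year redraws the
post-ripening composition from a Dirichlet with concentration 2,000
(high enough that shared vOTUs fluctuate ~40% without spurious whole-year
extinctions, which would corrupt the planted persistence truth) and the
sporadic guilds are present in each year independently with probability
0.45. The bacteriome holds the LAB genus at 10^8 CFU/g while total
aerobes grow log-linearly from 10^8 to 10^10 across the five stages,
partitioned among the rising guilds' host genera plus Psychrobacter;
plate counts are the log10 totals plus Gaussian noise (0.1 log10).

## What the synthetic experiments show — and do not

Passing tests demonstrate that the pipeline recovers planted structure
under a Dirichlet-multinomial noise model with substitution-only sequence
divergence: exact species-cluster recovery, calibrated permutation and
Wald tests, >= 80% power on planted 16-fold guilds at the published
thresholds with correct signs and no false positives among stable guilds,
stage-group separation, host-phage co-abundance, and a persistent core.
They do not demonstrate robustness to real-data features the generator
omits: indels and rearrangements (the PSL path exists for externally
aligned data), chimeras other than simple internal duplication,
uneven mappability, contamination, compositional effects stronger than
the planted ones, or tool-report errors beyond the modelled iPHoP error
rate. The published study's own headline numbers (Shannon 2.6-3.4,
PERMANOVA R2, Mantel r, 331 vOTUs) depend on the deposited reads and are
not reproduced numerically; the package reproduces the *procedures* and
the printed worked examples (catalog summary fractions, year-sharing
percentages, threshold classifications) exactly.

## Problem sizes

Test-suite and acceptance runs use the desk-scale defaults: 100-vOTU
communities, ~90-200 contigs for alignment-based checks (with a 30 kb
length cap in the clustering recovery experiment), 500-2,000 replicates
for calibration nulls with 199 permutations per test, and 999
permutations for single PERMANOVA/Mantel runs.
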
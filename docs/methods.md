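# Methods

## Presence, abundance, and catalog rules

A vOTU is *present* in a sample when its breadth of coverage —
covered bases divided by contig length — is at least the presence
threshold (default 0.75). Both the breadth threshold and the minimum
contig length (5,000 bp) are treated as inclusive. Presence calling is
deterministic, idempotent, and monotone in the threshold.

TPM abundance divides each vOTU's mapped-read count by its length in
kb and scales the per-sample rates to sum to 10⁶. By default the
denominator includes **all** vOTUs with mapped reads in the sample,
because presence and abundance are distinct assessments of the same
mapping; `mask_absent=True` instead zeroes the counts of
breadth-failing vOTUs before normalization, so the 10⁶ is carried
entirely by present populations. Both behaviors are exposed because
either reading of "TPM of the detected community" is defensible; the
default is the more conservative one that does not couple the two
thresholds. A sample with no counted reads yields an all-zero column
rather than an error.

Dereplication is greedy and longest-first: sequences are visited by
decreasing length (ties by id) and join the first cluster whose
*representative* they match at both the identity (0.95) and alignment
coverage (0.80) thresholds, else found a new cluster. "Alignment
coverage" follows the shorter-sequence convention of CD-HIT-style
clustering. The procedure consumes precomputed pairwise
identity/coverage tables; computing ANI from sequences is out of
scope. The output partitions the input, and every member matches its
representative at both thresholds — properties the tests assert.

`samtools depth`-style files carry per-base depth but no read counts,
so `read_depth_file` estimates mapped reads as round(total depth /
read length) with a configurable read length (default 150 bp, typical
of Illumina short-read metagenomes). The companion writer uses the
same convention, making write/read round-trips exact. Contig lengths
must always be supplied externally (length table or FASTA): inferring
them from the deepest covered position would silently shrink contigs
with uncovered tails.

## Diversity statistics

Rarefaction draws uniformly random sample orderings (default 100) and
reports the mean cumulative number of distinct vOTUs after k samples;
the mean curve is non-decreasing and ends at the total richness.

Richness contrasts use the two-sided Mann–Whitney U test. With at
most 8 observations per group and no ties — the regime of a
four-replicate design — the exact null distribution is enumerated;
otherwise the normal approximation with tie and continuity correction
is used. Identical groups necessarily contain cross-group ties and
therefore route to the corrected approximation, which returns p = 1
for them. Pairwise contrasts across the six phenotype × compartment
cells are reported with raw p-values by default (a Holm step-down
option exists) because with a fixed, small family the raw values are
the interpretable quantity.

Bray–Curtis dissimilarity BC(x, y) = 1 − 2Σmin(xᵢ, yᵢ)/(Σx + Σy) is
computed on TPM columns. A pair of all-zero samples is undefined
under the formula; it is reported as 0 with a runtime warning rather
than an error, so degenerate simulated inputs cannot crash a
pipeline.

NMDS minimizes Kruskal stress-1 by SMACOF-style iteration: isotonic
regression of configuration distances on the rank order of the input
dissimilarities yields disparities, followed by a Guttman transform;
an update is accepted only if stress decreases, so the recorded
stress history is monotone. Defaults: 20 random restarts, tolerance
1e-6 on the stress decrement, 300 iterations — standard robust
choices for community matrices of a few dozen samples. The best
restart is returned with its convergence flag and history;
coordinates are defined only up to rotation/reflection/translation.

PERMANOVA uses Anderson's pseudo-F computed directly from the
dissimilarity matrix: SS_total = Σ_{i<j} d²ᵢⱼ/N, SS_within summed per
group, F = (SS_among/(a−1))/(SS_within/(N−a)), R² =
SS_among/SS_total. Labels are permuted freely (no strata), 999
permutations by default, p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm). An
exhaustive mode enumerates all label permutations for n ≤ 8, used as
its own oracle in the tests. Note that with extreme group separation
the attainable minimum p is limited by permutations that recreate the
observed partition, not by 1/(n_perm + 1) alone.

## The richness-conserving null model

The co-occurrence question is whether multi-sample vOTUs (≥ 2
samples) span phenotypes and compartments more or less often than
chance would produce given how rich each sample is. The null
therefore conserves **per-sample richness only**: in each replicate,
every sample is assigned a uniformly random subset of vOTU identities
(without replacement within the sample) of its observed size, drawn
from the full catalog of all observed vOTUs — including singletons,
since the ≥ 2-sample filter is applied after observation and the null
must be free to regenerate singletons. Because each sample belongs to
exactly one phenotype × compartment cell, cell-level richness is
conserved as a consequence. An alternative `per_cell` mode draws
identities without replacement across a whole cell (per-sample
richness still conserved, within-cell repeats forbidden), a stricter
cell-level reading; it is provided for sensitivity analysis, not as
the default.

Expected class proportions are defined as the **ratio of means**:
replicate-mean class counts normalized by the replicate-mean
multi-sample total. The mean of per-replicate proportions is
undefined whenever a replicate produces no multi-sample vOTU, which
happens routinely on small instances; the ratio-of-means estimator is
well defined everywhere and coincides with the per-replicate mean in
the large-instance limit. The exhaustive oracle
(`exact_null_expectations`) enumerates all Π_s C(catalog, r_s)
assignments (guarded at 10⁶) and computes the same ratio
E[count]/E[n_multi], so Monte-Carlo/oracle comparisons are exact
apples-to-apples; tests require agreement within 3 Monte-Carlo
standard errors at 10⁴ replicates.

The χ² goodness-of-fit compares observed class counts to the expected
proportions scaled to the observed total: df = #classes − 1, classes
with expected 0 and observed 0 dropped from the df, an expected 0
with observed > 0 flagged as an infinite statistic, and a warning
below expected count 5. No continuity correction is applied. 1,000
null replicates are the default — enough that the expected
proportions' Monte-Carlo error is negligible relative to the χ²
sampling noise at the catalog sizes involved.

## The synthetic-data generator

The generator emulates the structure the analysis assumes, not
sequence content: no reads, assemblies, or FASTA are produced. Each
vOTU receives an eligibility region — one phenotype with probability
`phenotype_fidelity` (default 0.8, encoding strong but imperfect
phenotype structuring), crossed with a compartment set drawn from
weights over the 7 sharing classes. The default weights echo the
broad empirical pattern of root-zone virome sharing (≈ 20% of
multi-sample vOTUs in one compartment, ≈ 72% in two with
rhizosphere+root dominating, ≈ 8% in all three) and give the
spatially non-adjacent bulk+root-only class weight 0. A vOTU then
occupies each eligible sample independently with probability
`per_sample_occupancy` (default 0.3). If a vOTU's realized
compartments collapse to exactly {bulk, root} while its drawn class
includes the rhizosphere, one eligible rhizosphere sample is forced
to occupied, so the generated ground truth never contains a
bulk+root-only vOTU unless that class is explicitly weighted — the
proximity constraint is enforced by construction, not merely in
expectation.

Magnitudes the analysis cannot anchor empirically (catalog size 769,
occupancy 0.3, depth mean 10× with negative-binomial dispersion 1,
contig lengths log-uniform on 5–60 kb) are fixed, realistic choices
for a soil-virome mapping experiment, set once; the catalog size
matches the scale at which the sharing statistics are interesting
without slowing the suite.

Coverage is constructed so presence calling is *exactly* invertible:
present pairs draw breadth uniformly on [0.75, 1] (covered bases
rounded up), absent pairs are either zero-coverage or draw breadth
uniformly on [0, 0.70] (rounded down, capped strictly below the
threshold), leaving a [0.70, 0.75) guard gap. Read counts are
overdispersed negative-binomial for present pairs and trace Poisson
for background, floored at ceil(covered/read_length) so every summary
is physically realizable as a depth profile. What passing tests on
these data show, therefore, is correctness of the downstream logic —
not robustness to the ambiguities of real mapping data (breadths
hovering at the threshold, chimeric contigs, uneven coverage), which
the generator deliberately excludes.

## Problem sizes in the test and acceptance runs

The suite exercises the default 24-sample, 769-vOTU scale for
ground-truth recovery, invariants, and the null-model power check
(1,000 replicates); oracle-equivalence checks run on 6-sample,
4-vOTU instances where exhaustive enumeration (≤ 10⁶ assignments) is
feasible at 10⁴ Monte-Carlo replicates; type-I calibration uses
1,000 simulations with 199-permutation PERMANOVA on 12 samples and
4-class multinomials of size 200. These sizes make every statistical
tolerance (3 SE, rejection rate within [0.03, 0.07]) meaningful while
keeping the full suite under a minute.

## Known limitations

* Dereplication trusts the supplied pairwise table; it does not
  verify symmetry or triangle consistency of identities.
* The NMDS stress surface is non-convex; 20 restarts make a poor
  local optimum unlikely but not impossible for pathological inputs.
* The null model conserves richness only; a null that additionally
  conserves per-vOTU occupancy frequency (degree distribution) is a
  different, stricter hypothesis and is not implemented.
* TPM inherits the usual caveat of compositional measures: columns
  are simplex-constrained, so cross-sample comparisons are relative,
  which is why ordination uses Bray–Curtis rather than Euclidean
  distance.
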
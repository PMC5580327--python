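# Methods

## Per-sample calls

A CpG is addressed by the plus-strand position of its cytosine;
coordinates are 0-based half-open throughout, and each input dialect's
converter (bedGraph 0-based, bismark coverage 1-based/percent, MOABS
ratio table) is exact. Strand-split calls at adjacent positions p/p+1
are combined by default (coverage-summed, coverage-weighted ratio);
this is safe without a reference CpG map because two plus-strand CpG
cytosines can never occupy adjacent positions. Ratios are stored as
fractions.

A **UMC** requires methylation ratio ≤ 0.10 (inclusive) and coverage
≥ 4 reads (inclusive). A **UMR** is a maximal run of consecutive
*callable* CpGs (coverage ≥ 4) in which every member's ratio is ≤ 0.10,
reported when the run has ≥ 4 members and mean ratio strictly < 0.10.
"Consecutive" counts callable CpGs only: a site below the coverage
floor has no ratio estimate and can neither extend nor break a run.
There is no genomic gap limit by default; `max_gap` adds one. The
region spans first member position to last member position + 2,
covering the final dinucleotide. Because all members are ≤ 0.10, the
mean filter can only reject a run in which every member is exactly
0.10, so maximal runs and maximal qualifying windows coincide — the
test suite exploits this by checking the caller against a
window-enumeration oracle.

## Conservation score and the Chebyshev outlier model

Candidates are positions that are a UMC in ≥ 1 of the N samples,
outside the union of **all** samples' UMRs (using the union guarantees
the sparsity of an scUMC in every methylome and makes scUMC/conserved-UMR
sets disjoint by construction), and not at a SNP position. The score
S = 100·(Σsᵢ)/N uses the total sample count N as denominator — a sample
in which the CpG is uncovered contributes 0 — with an optional
`callable_only` mode that divides by the per-CpG callable count
instead.

The model takes m = mean and v = *population* standard deviation of all
candidate scores (at N ≈ 31 the sample/population distinction is
negligible). For tail probability p, k = √(1/p) and the cutoff is
m + kv, applied one-sided as printed; the credibility test runs on the
integer scale, presence count ≥ n_min = ⌈(m + kv)·N/100⌉ clipped to
[1, N]. The integer and score forms of the test provably coincide
whenever m + kv ≤ 100; when a heavy tail of highly conserved candidates
pushes the score cutoff past 100 (possible on small simulated genomes
where planted features are a few percent of all candidates), the
clipped integer form still admits fully shared CpGs, which is the
intended "conserved in at least n_min samples" semantics. Defaults:
p = 0.01 (k = 10) for credible calls; the illustrative k = 4.5
(p ≈ 0.049) is available through `chebyshev_p`. Credible CpGs within
300 bp (inclusive, measured between cytosine positions) merge by single
linkage into scUMC regions; a merge never bridges an excluded UMR, so
region-level disjointness from the UMR union is a construction
guarantee, not a post-filter. Non-conserved UMCs are candidates below
the lenient cutoff m + √(1/0.95)·v that are not credible; credible and
non-conserved sets are disjoint subsets of the candidates, with an
intermediate band between the two thresholds belonging to neither.

Conserved UMRs: all samples' UMRs are merged (≥ 1 bp overlap or
book-ended) into non-redundant regions; presence counts are recomputed
for every CpG inside each region — without UMR or SNP exclusion, since
the exclusions define the *candidate* path only (SNP filtering here is
available as an option) — and a region qualifies when its best CpG
reaches n_min.

## Shuffle FDR for the minimal run length

The null methylome permutes (ratio, coverage) pairs jointly and
uniformly over all positions, destroying spatial correlation while
preserving the marginal distribution and, because the pair moves
together, the callability structure. Observed and null methylomes are
segmented identically with the run rule at min_cpg = 1, and
FDR(c) = mean null count of runs with ≥ c CpGs / observed count, over
`n_shuffles` (default 10) seeded shuffles. Cutoffs with zero observed
runs are reported as undefined and excluded from the search for c_min,
the smallest c with FDR ≤ α (default 0.05). FDR(1) can exceed 1 on
structured data: clustering concentrates low CpGs into fewer runs than
the shuffled null produces; the estimate is reported unclamped.

## The simulator

`SimConfig` defaults *are* the bundled study conditions: N = 31 samples
on one 200-kb chromosome; geometric inter-CpG gaps with mean 10 bp
(~20,000 CpGs); background ratios Beta(8, 2) (mean 0.8, matching the
highly methylated 70–80% bulk of a real methylome, with
P(ratio ≤ 0.1) ≈ 3·10⁻⁷ so background UMCs are negligible); coverage
Poisson(30) drawn independently of methylation, with sites under 4
reads retained in the output for the caller to filter; 20 planted
8-CpG UMRs low in every sample; 50 planted conserved UMCs, each low in
j ~ Uniform{10..31} samples and high elsewhere, pairwise > 300 bp from
any other planted feature; stochastic sample-specific UMCs at rate
ρ = 0.0047 per CpG per sample; 30 SNP positions left as ordinary CpGs
in the tables so the SNP filter has work to do. Planted-low ratios are
drawn Uniform(0, 0.08) — guaranteed below threshold, so recovery
measures the pipeline, not the draw — and coverage ≥ 4 is forced at
truth positions.

Two deliberate departures from genome realism are worth stating. The
CpG map is ~10× denser than the genome-wide average: with 50 planted
conserved CpGs fixed, the Chebyshev fit is only meaningful when they
are a small fraction of all candidates, which at desk scale requires a
few thousand stochastic candidates and hence a dense map. And the rate
ρ is calibrated so that ~93% of *stochastic* candidates appear in
exactly one sample (Nρ ≈ 0.146 gives λe^(−λ)/(1−e^(−λ)) ≈ 0.93);
including the planted features the overall sample-specific fraction is
~91%. Consequently the fitted n_min lands near 28 of 31 here rather
than the ~10 a population of millions of real candidates yields — the
cutoff is data-adaptive by design, and the recovery guarantees are
stated relative to the fitted n_min. The simulator also does not model
sequence context (CpG islands), read-level noise, or coverage-methylation
correlation; passing tests demonstrate correctness of the inference
machinery under the stated regime, not performance on real WGBS data.

## Annotation statistics

Expected overlap for enrichment comes from uniform length-preserving
placement of each feature within its own chromosome (no mappability or
blacklist masking), seeded; log2(obs/exp) is NaN-flagged when the null
never overlaps. CpG density is count × 100 / region length, counting a
CpG at p inside [start, end). TSS distances are midpoint-to-point with
ties toward the smaller coordinate; "distal" means strictly > 3000 bp.
Profiles average per-feature in-bin means over features; empty bins are
NaN, never zero. The two-group specificity rule (the exact published
criterion being unavailable) is configurable: a group counts as
under-methylated when ≥ `min_frac` (default all) of its covered samples
have member-CpG mean ≤ `low` (0.10); a region is group-specific when
the other group's mean is ≥ `high` (0.30), shared when both groups are
low, ambiguous otherwise or when a group has no covered member CpG.

## Numerical choices and limitations

n_min uses ⌈x − 10⁻⁹⌉ to absorb float error when (m + kv)·N/100 is an
exact integer. All randomness flows through `numpy.random.default_rng`
seeds; shuffle seeds for the FDR derive from one `SeedSequence`. The
problem sizes above (200-kb genome, 10–200 Monte-Carlo shuffles, ≤ 200
oracle instances per operation) were chosen so the whole suite runs in
well under a minute while keeping every statistical band sharp.
Known limitations: no HMM segmentation or LMR/canyon variants; no
imputation of uncovered CpGs; the VCF reader consumes positions only;
enrichment nulls ignore mappability; lineage-specific labels depend on
thresholds that should be tuned per dataset.
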
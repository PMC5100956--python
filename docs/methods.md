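# Methods

This note records the model, the numerical choices, and the synthetic study
conditions the package's tests and acceptance script operate under.

## Deterministic theory

A single admixture pulse introduces the haplotype N₁S₁ at frequency p₀ into
a resident population fixed for N₂S₂.  N₁ is neutral; S₁ costs its
heterozygous carrier s (homozygous S₁ carriers are rare at small p₀ and are
ignored — there is no dominance parameter).  With recombination at meiosis
followed by viability selection on offspring, the frequency of N₁ still
linked to S₁ decays by (1−r)(1−s) per generation, while a fraction r
escapes each generation onto the resident background at no further cost.
Summing the geometric escape series gives the autosomal retention factor

    f_A(r, s, t) = ( s(1−r) λᵗ + r ) / ( s(1−r) + r ),   λ = (1−s)(1−r),

whose t → ∞ limit r / (1 − (1−s)(1−r)) is the gene flow factor of
genetic-barrier theory.  `recursion_oracle(mode="autosome")` iterates the
underlying two-haplotype recursion directly; the closed form and the
iteration agree to < 1e−12 over the full validation grid, and the package
treats the iteration as the oracle for the algebra.

X chromosome.  The non-PAR X does not recombine in males, and an X-linked
allele spends 2/3 of its time in females.  The closed form used for
inference is f_A with r replaced by (2/3)r — exactly the solution of the
single-pool transmission recursion at that effective recombination
fraction.  The package also implements the explicit two-sex recursion
(female/male pools, recombination in female meiosis only, hemizygous male
selection 1−s).  The 2/3 weighting is the leading-eigenvalue approximation
of that 2×2 transmission system; the subdominant mode decays like (−1/2)ᵗ
but the eigenvalue itself differs from 1 − (2/3)r(1−s)·(…) at O(r²), so
the two descriptions drift apart multiplicatively over t generations.  At
r = 0.01 and t = 2000 the deviation is ~6×10⁻⁵ in f (measured max over the
validation grid); tests assert agreement at 1e−3 for the two-sex
cross-check and at 1e−8 for the matching single-pool recursion.

Nearest-exon mixture.  Each exonic base independently harbors a deleterious
allele with probability μ, so an exon of length l carries one with
probability ≈ μl (clamped into [0, 1); the model regime is μl ≪ 1, and a
saturated exon simply absorbs all remaining weight).  The selected site sits
at the exon midpoint (floor((start+end)/2) of the merged interval).  Within
a window of 1 cM (10 cM supported) around each SNP, exons are ordered by
genetic distance — ties broken toward the lower physical coordinate — and
only the nearest selected site acts:

    g_ℓ = Σᵢ μlᵢ Πⱼ<ᵢ(1−μlⱼ) f(rᵢ, s, t) + Πⱼ(1−μlⱼ).

Genetic distance converts to recombination fraction linearly, r = d/100
capped at 1/2; over ≤ 10 cM windows a map function would change r by < 1%.

## Inference

RSS(p₀, s, μ) = Σℓ (p_{n,ℓ} − p₀ g_ℓ)² is minimized over a coarse 13×13
log-spaced grid (defaults s ∈ [1e−5, 4e−3], μ ∈ [1e−6, 1e−3]) followed by a
26×26 refinement spanning one coarse cell either side of the coarse
optimum; the refinement grid always contains the coarse optimum itself, so
an on-grid truth is an exact fixed point of the pipeline on noiseless data.
p₀ is profiled out analytically (Σ p_n g / Σ g², clamped to [0, 1]).  Grid
ties resolve toward smaller s, then smaller μ.  An optional
variance-weighted RSS (weights 1/(p̂(1−p̂)) with p̂ the model mean from the
unweighted p₀) is available as a robustness variant; it applies to the
full-data surface only, and the blockwise bootstrap always resamples the
unweighted sufficient statistics.

The per-SNP windows depend only on geometry and are built once per fit;
the grid scan runs in a fused numba kernel that holds each SNP's per-s
retention factors and per-μ weights in L1-resident buffers (entry arrays in
float32, all accumulation in float64; the float32 path changes g by < 1e−6
relative, far below the drift noise the fit operates on).

Uncertainty: each chromosome is tiled from its first SNP into right-open
5-cM blocks (partial terminal blocks kept, empty interior tiles kept as
resampling units).  Per block and per fine-grid cell the sums Σ p_n g, Σ g²
and Σ p_n² are stored; a bootstrap genome resamples blocks with replacement
within each chromosome (original counts preserved), reassembles the RSS
surface by linearity, and re-optimizes.  CIs are 2.5/97.5 percentiles of
1000 replicates (200 in the desk-scale tests).  The identity resample
reproduces the full-data fit exactly.

Model fit diagnostic: the genome is cut into 1-cM segments (0.5–2 cM
supported), segments are ranked by exonic-base count (exons assigned by
midpoint) and grouped into ten equal-count bins — bins made entirely of
zero-exon segments collapse into one — and mean observed vs predicted
frequencies are compared per bin, along with the segment-level Pearson
correlation.

## Wright–Fisher split simulation

Per site, independently: gamma DFE (shape 0.184, mean |s| = 0.03 — the
standard point estimate for new deleterious amino-acid changes; draws above
0.5 are truncated so homozygote fitness 1−2s stays non-negative), additive
selection (fitnesses 1, 1−s, 1−2s), one-way mutation wild-type→deleterious
at rate u per copy, binomial resampling of 2Nₑ copies.  Standing variation
comes from a burn-in of 10·Nₑ_recipient generations in an ancestral
population of the recipient's size (an analytic standing-variation draw is
not offered: with irreversible mutation the deleterious-site frequency
distribution has no proper stationary form).  After the split the donor
evolves at Nₑ = 1000 and the recipient at Nₑ = 10,000 for 20,000
generations; an optional recipient bottleneck (studied durations 10–1000
generations, size 1861 in the tests) replaces the final generations before
contact.  Fixation is exact 0/1 in the finite population.

Mutation rate.  u is per simulated *site* and defaults to 1e−6 per copy per
generation, i.e. a site stands for a ~100-bp functional element at a
nuclear rate of ~1e−8 per bp.  This keeps the number of fixation events at
desk scale (10⁴ sites) large enough to measure the donor/recipient
asymmetry; consequently the absolute population-specific fixed fractions
are per-element, not per-bp, and are compared only as donor-vs-recipient
contrasts, never as absolute densities.

## Synthetic study conditions

The generator's defaults define the conditions every recovery and coverage
result refers to: 22 chromosomes × 50 cM at an average 1 cM/Mb, map knots
every 5 Mb with lognormal (σ = 0.3) interval rates rescaled to the
chromosome total; exons by a renewal process (min 50 bp plus an exponential
tail, mean 400 bp; exponential gaps, mean 20 kb — about 2% exonic, in the
range of a merged coding annotation); SNPs on a jittered 22-kb grid
(~50,000 genome-wide); truth at the magnitudes of the published European
autosomal estimates (p₀ = 0.0338, s = 4.12×10⁻⁴, μ = 8.1×10⁻⁵, t = 2000).

Noise.  The default "drift" model draws each call from a beta distribution
with the model mean and variance m(1−m)(1 − (1 − 1/(2Nₑ))ᵗ), Nₑ = 10⁴,
t = 2000 — the neutral drift variance around the deterministic expectation
(selection's effect on the variance is ignored, and draws are independent
across SNPs).  A binomial(n) sampling mode and an exact (noise-free) mode
exist; a "mechanistic" generator that places real selected sites at rate μ
per exonic base and propagates each SNP through the retention factor of its
nearest selected site is used in a handful of tests to confirm the mixture
expectation.

What passing does and does not show.  Synthetic genomes have independent
per-SNP noise, exchangeable exon placement, and a single true s; real data
have spatially correlated drift noise along haplotypes, clustered exons,
a distribution of selection coefficients, and call-estimation error.
Recovery and coverage on the synthetic conditions therefore validate the
estimator's correctness and calibration under its own assumptions, not the
published point estimates themselves — those require the original call
tables, map and annotation (see the README's external-validation recipe).

## Degenerate inputs and edge rules

- f(r=0, s=0) ≡ 1 at finite t; the equilibrium form is undefined there and
  raises.
- t = ∞ (math.inf) is an accepted sentinel routing every formula to its
  equilibrium limit.
- Frequencies outside [0, 1] in a call table, negative distances, and
  out-of-range (r, s, μ, p₀) raise ValueError; map positions beyond the
  mapped range clamp to the boundary cM value.
- Overlapping or book-ended exon records merge on load; call positions are
  1-based on disk, 0-based internally; BED is half-open as usual.
- Bootstrap requires ≥ 2 replicates; a chromosome's blocks tile from its
  first SNP, and a SNP exactly on a block boundary belongs to the
  right-open interval starting there.

## Known limitations

- Only the nearest selected exon acts on each SNP; a multiplicative
  multi-site extension would lower g near dense exon clusters and is left
  as a hook.
- A single genome-wide s (no DFE in the inference; the simulator has one).
- The X fit shares one s between heterozygous females and hemizygous males.
- The drift-noise generator is unlinked; blockwise bootstrap intervals on
  synthetic data are therefore, if anything, conservative.
- The donor population's own segregating variation (deleterious alleles not
  fixed at contact) is outside the inference model; the simulator shows the
  fixed-difference configuration dominates at these demographies.
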
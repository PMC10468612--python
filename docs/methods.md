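# Methods

This note documents the models, estimators, numerical choices and known
limitations of the package. Notation: L diagnostic loci; dosage g ∈ {0,1,2}
counts *O. ophryticus* alleles; p̄, q̄ = 1 − p̄ are mean focal-allele
frequencies; w is cline width in km (inverse of the maximum slope); c the
cline centre on the transect.

## Marker QC

Hardy–Weinberg tests are exact and one-sided. Conditional on the allele
counts in a sample of n diploids, the number of heterozygotes h follows
Levene's distribution, P(h) ∝ 2^h / [((n_A−h)/2)! h! ((n_a−h)/2)!] over the
h of matching parity. We enumerate the full support with exact rational
arithmetic and report deficit p = P(h ≤ obs) and excess p = P(h ≥ obs);
monomorphic samples are flagged untestable rather than given a p-value. At
the sample sizes typical of transect studies (n ≤ ~30 per locality) the
enumeration is instantaneous and involves no approximation.

Multiple testing uses a per-test threshold α/N. N defaults to the panel's
marker count (correction across markers within each population's batch);
correcting across populations instead is available via the
`n_markers_correction` argument, since the convention differs between
studies. A marker is excluded when it shows corrected-significant deficit in
at least `min_sig_pops` populations (default 2 — one population can be a
local artifact such as a null allele or family structure; two independent
populations indicate a marker problem). The threshold is configurable.

Linkage disequilibrium between two markers is tested genotypically: the
log-likelihood-ratio G statistic of the per-locality 3×3 genotype tables,
summed over localities, against a null that permutes one marker's genotypes
within localities (stratification prevents mixture-induced, Wahlund-type
associations from masquerading as physical linkage — in a hybrid-zone
dataset nearly everything is associated if you pool across the zone).
Default 1000 permutations; p = (#null ≥ obs + 1)/(n_perm + 1); a seed is
required and results are bit-reproducible.

## Hybrid index and transect

The individual hybrid index is Σg / (2 × #called loci), missing loci
excluded from numerator and denominator. The locality index pools alleles
over individuals (weighting individuals by call count) rather than
averaging individual indices, because the cline likelihood consumes allele
counts; with light missingness the two definitions agree to the second
decimal.

The two-dimensional locality map becomes a one-dimensional transect via the
0.5 contour of the interpolated hybrid-index surface. The surface uses the
C1-smooth Clough–Tocher interpolant on the Delaunay triangulation of
locality positions (piecewise-linear interpolation is available as
`method="linear"`, but a linear surface threads its level set through
triangulation slivers wherever localities form near-collinear chains —
exactly the geometry of transect sampling — and pinches the transect near
the zone centre; a smooth interpolant, like the Akima splines traditionally
used for these isolines, does not). The contour is extracted by marching
squares on a 0.01° grid, restricted to the convex hull of the data (no
extrapolated isoline), optionally clipped to a user polygon such as a
species range, and the longest connected component is kept. Signed distance
is the minimum great-circle distance (Earth radius 6371.0 km) to the
contour densified to ≤ 100 m steps, negative where the interpolated hybrid
index is below the contour level. On the packaged fixture the distances are
stable to < 0.5 km between 0.01° and 0.005° grids; a 0.02° grid is too
coarse to resolve the isoline's curvature near the zone centre and is not
recommended.

## Geographic clines

The frequency model is the standard tension-zone cline: a central sigmoid
f(x) = (1 + tanh(2(x−c)/w))/2 rescaled to [pmin, pmax]. On a tailed side,
beyond a distance δ from the centre, f is replaced by an exponential that
matches the sigmoid's value at the junction and decays with a slope equal
to τ times the sigmoid slope there (τ ∈ [0,1]; τ = 1 is slope-continuous,
smaller τ gives the long shallow shoulders of neutral introgression). Five
tail variants (none / left / right / mirror / both) × three scalings
(fixed 0/1, observed extreme frequencies, free) give 15 models with
K = 2 + 2·(tail blocks) + (2 if free).

The likelihood is binomial over localities, Σ k_i ln p(x_i) + (n_i − k_i)
ln(1 − p(x_i)), with p clamped to [1e−6, 1 − 1e−6]; the additive binomial
coefficient is omitted, so printed log-likelihoods are comparable within
this package only (it cancels from all likelihood ratios and AICc
differences). Haploid data (mtDNA) enter with n_i = haplotype sample size.

Maximisation is multi-start Nelder–Mead (default 12 starts: one informed
start at the locality nearest frequency 0.5, the rest drawn uniformly
within bounds) inside uniform bounds: c within the transect span ± half a
span, w ∈ (0.01 km, 2·span], δ ∈ [0, span], τ ∈ [0, 1], pmin ≤ pmax in
[0, 1]. Support limits come from Metropolis MCMC started at the ML point
(default 3 chains × 20,000 steps, 10% burn-in, proposal scales tuned during
burn-in toward 20–40% acceptance, flat priors on the bounds): the reported
interval per parameter is the range of sampled points within two
log-likelihood units of the maximum, the convention of hybrid-zone
software, labelled "95% CI" in outputs to match field usage. On test data
these limits agree with dense-grid profile-likelihood limits to well within
10%. Chain-mean disagreement beyond a quarter of a parameter's range flags
the fit as unconverged.

Model selection: AICc = −2logL + 2K + 2K(K+1)/(n−K−1), undefined (error)
when n ≤ K + 1. All 15 variants are fitted with ML; the MCMC runs on the
selected model only by default (`mcmc_on="all"` forces it everywhere) — the
ranking depends only on the ML fits, so this changes no decision, only the
cost. Within 2 AICc units of the minimum the tie breaks toward fewer
parameters. Failed variants are returned as flagged entries, never abort
the set.

Degenerate regime to be aware of: when the observed frequencies jump from
0 to 1 between adjacent localities with nothing intermediate (the mtDNA
data here), every width below the sampling gap fits equally well and the
ML width is effectively "small, bounded above by the gap" — the support
interval, not the point estimate, is the meaningful quantity.

## Tension-zone estimators

At the zone centre, admixture generates covariance among ancestry dosages
across loci. With F_IS = 0 (diagnostic loci are fixed in the parental
populations and within-locus excess is handled upstream by the HWE screen;
the decomposition is configurable through the estimator's inputs), the
hybrid-index variance satisfies Var(HI) = p̄q̄[1/(2L) + (L−1)/(2L)·D′],
inverted for D′. This D′ is the total (composite) standardised association,
the quantity a Burrows-type pairwise genotype-covariance estimator
Cov(g_l, g_m)/(2p̄q̄) measures; the two agree within sampling error and the
tests check it. Negative estimates (sampling noise around small true D′)
are floored at 0 with a warning rather than propagated into an imaginary σ.

Then σ = w√(rD′) with mean recombination r = 0.5 (unlinked markers),
neutral width after T generations = σ√(2πT), effective selection
s* = 8σ²/w², and generations-to-cross = w/σ. Defaults: contact at the
Holocene onset 12,000 years ago, 5-year generations, T = 2,400. The width
entering s* is the hybrid-index cline width by default; a mean per-marker
width can be passed instead (`s_star_width`) — the two conventions differ
by up to a factor ~2 in s* and published values do not always state which
was used, so the choice is explicit here.

The pipeline restricts the LD estimate to localities within w/2 of the
fitted centre (configurable) and, by default, to post-metamorphic
individuals — larvae have not yet dispersed, and σ is a lifetime dispersal
parameter. Panels with no life-stage annotation use all individuals.

## Ancestry triangle

Per-locus class probabilities P(g=2) = S − H/2, P(g=1) = H,
P(g=0) = 1 − S − H/2 on the triangle 0 ≤ S ≤ 1, 0 ≤ H ≤ 2·min(S, 1−S).
The MLE is found by grid search (step 0.005) plus Nelder–Mead refinement;
probabilities are floored at 1e−9 so corner optima never yield −∞, and
likelihood ties break toward smaller H. The batch summary counts
individuals within 0.05 of a parental corner (a reporting convention, not
an inference).

## Niche overlap

Variables are decorrelated greedily: while any pair exceeds |Pearson r| ≥
0.7 over background cells, the member of the worst pair with the larger
mean absolute correlation is dropped (deterministic order). PCA runs on the
standardized background cloud; occurrences are projected through their
nearest raster cell.

Occupancy on the PC1–PC2 grid (default 100×100 spanning the background's
range): Gaussian kernel density of occurrence scores with per-axis
bandwidth σ·n^(−1/6), divided by background availability measured as the
per-cell count of background cells. A smoothed background *density* in the
divisor is numerically treacherous — it spans many orders of magnitude near
the edge of the cloud and a density ratio there concentrates occupancy mass
in a handful of cells; counts bound the divisor from below (floored at the
1st percentile of positive counts) and correspond to the environmental
prevalence used by the standard ordination-overlap workflow. Cells with no
background are zeroed and the grid renormalised to sum 1.

Schoener's D = 1 − ½Σ|z₁ − z₂|. The similarity test relocates the focal
species' corrected occupancy by a random toroidal translation within its
background mask (n_reps default 100, seeded, add-one p-value), in each
direction separately. The geographic projection classifies each map cell by
whether its environmental position falls inside the cells holding the top
95% of each species' occupancy mass (quantile configurable).

## Synthetic data

`simulate_zone` draws, per locality at transect position x, a latent
ancestry q per individual from a Beta with mean p(x) (the true cline,
or an explicit per-locality frequency vector) and variance ρ·p(1−p), then
genotypes Binomial(2, q) per locus and mtDNA Bernoulli from a separate,
steeper cline (mirroring the near-zero mitochondrial widths of real
tension zones). The configuration exposes the variance at p = 0.5
(`ancestry_variance` = ρ/4, must be < 0.25). This construction targets the
estimators directly: the induced zone-centre admixture LD is
D′ = ρ(2L−1)/(L−1) (`rho_for_dprime` inverts this), and ρ = 0 gives
independent loci. Localities are placed along an east–west line with a
small uniform latitude jitter (±0.05° default) — real transect sampling is
never perfectly collinear, and the surface interpolation requires a 2D
point cloud. What this generator does *not* emulate: genuine spatial
pedigrees, selection, linkage maps, or locus-specific introgression — so
passing recovery tests demonstrates estimator correctness under the model's
own assumptions, not robustness to their violation.

`simulate_admixed_swarm` draws genotypes from the triangle model at given
(S, H). `simulate_climate_landscape` builds environmental layers that share
one dominant latent gradient (a low-order spatial trend plus
Gaussian-filtered noise; each layer loads 0.85 on it with independent
smooth residuals — the structure of real bioclimatic stacks, whose leading
ordination axis recovers the dominant gradient) and samples occurrences
with probability proportional to a Gaussian suitability along that
gradient, so the separation of two species' niches is known by
construction. With fully independent layers the separating variable can
load mainly on discarded PC axes and distinct niches fold together in the
ordination plane; the shared-gradient design avoids testing that artifact.

## Pipeline and problem sizes

The pipeline runs QC → hybrid index → transect → cline → tension zone
(plus optional triangle and niche arms) from one configuration mapping,
echoes the configuration into the output directory, and writes per-stage
tables plus a JSON summary; reruns with the same configuration are
byte-identical. "Table mode" covers locality-level-only inputs: individual
stages are skipped with explicit notices and cline data are reconstructed
as k = round(HI·2N), n = 2N (mtDNA haploid). The test and acceptance runs
use 42-locality fits with 6,000–8,000-step chains and recovery suites of
50 replicates at 9–20 localities — sizes chosen so the full suite completes
in a few minutes while leaving the estimators' sampling error well inside
the asserted tolerances.

## Known limitations

* The isoline depends on the interpolant; published isolines drawn and
  hand-trimmed in a GIS cannot be reproduced vertex-for-vertex. Downstream
  cline parameters absorb this at the few-percent level on the packaged
  fixture.
* Support limits are two-log-likelihood-unit envelopes from finite MCMC
  samples; very flat likelihoods (step-like data) make the width's lower
  limit run to the bound.
* D′-based dispersal assumes unlinked diagnostic loci, F_IS ≈ 0 and a
  stationary zone; violations bias σ.
* The niche arm measures overlap in a two-axis ordination; separation
  carried by discarded axes is invisible, and kernel/grid choices move D by
  a few hundredths.
* No forward-time spatial simulation, no genomic clines, no stepped-cline
  joint likelihood.
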
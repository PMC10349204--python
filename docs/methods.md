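# Methods

This note records the models implemented in `seaflow`, the conventions and
defaults that matter for reproducing numbers, and the choices made where a
published description leaves the mechanism open.

## Seascape and geometry

All geometry is spherical (haversine, R = 6371 km). Degree–metre
conversions use the local metric: one degree of longitude spans
111.19 cos(φ) km at latitude φ.

**Buffer grouping.** Two sites belong to the same population iff their
circular buffers (default radius 10 km) overlap, i.e. their great-circle
separation is below 2 × buffer radius; populations are connected components
of this overlap graph. For circular buffers the distance test is exactly
equivalent to polygon intersection, so no geometry library is needed.
Population labels (`G1`, `G2`, …) are assigned by each component's
alphabetically smallest site id, making the grouping invariant to input
order. Centroids are arithmetic means of member coordinates.

**Filtering.** Individuals with more than 6 missing alleles (10% of a
32-locus diploid panel) are dropped first; populations left with fewer than
10 individuals are dropped second. The operation reports counts at both
steps and is idempotent.

**Water distance.** The marine habitat is rasterized as the sea cells of
the gridded landmask; distances are Dijkstra shortest paths over an
8-neighbour graph (16-neighbour optional) with great-circle step costs, so
diagonal steps cost √2 times an orthogonal step up to grid anisotropy.
Centroids on land snap to the nearest sea cell within two cells; farther
than that is an error, as is a disconnected pair. Because path costs are
true distances, the result can never undercut the geodesic by more than one
cell diagonal of discretization.

## Lagrangian transport

Advection is 4th-order Runge–Kutta (Euler available) on velocities
interpolated bilinearly in space and linearly in time; the default step is
Δt = 600 s, chosen well below the grid-crossing time of the default fields
(an unstated integration step in the tooling this mirrors). Turbulent
diffusion adds an independent Gaussian kick per horizontal axis with
standard deviation √(2KΔt), converted to degrees at the particle's
latitude. Presets K = 36.5 and 12.3 m² s⁻¹ correspond to 0.08° and 0.04°
source-current grids; the scaling formula that produced them is not
reimplemented — they ship as named constants.

**No stranding.** If a move would land a particle on a land cell the
diffusion kick is resampled (≤ 10 tries), then the advection-only position
is used if it is at sea, else the particle holds position. Rejection
resampling was chosen over reflection because only the constraint, not the
mechanism, is specified in the source material; the choice is recorded here
because it slightly steepens near-shore concentration gradients.
Out-of-domain positions are clamped to the boundary and counted in the
run diagnostics.

**Release design.** Release points are sampled with replacement from sea
cells whose distance to the nearest member site lies in
[buffer + offshore, + one cell width] — by default 12–(12 + cell) km, so no
particle starts ashore. Each point releases a fixed number of particles per
day at a uniformly random time within the day. The tracking horizon helper
computes mean hatch time + 2 SD (33 + 2×15 = 63 days), covering ~97.5% of
hatching-time variation. One seeded RNG stream per population makes runs
bit-reproducible; stream seeds combine the plan seed with a CRC of the
population label, keeping results independent of population iteration
order.

## Connectivity

**TSIB.** A trajectory record is "in buffer" of a population when it lies
within the buffer radius of any member site. Residence is counted per
record: (number of in-buffer records) × record interval (default 0.5 h).
This convention automatically grants a particle observed inside a buffer at
a single time point half an hour of residence — the minimum resolvable
visit. Self-retention (diagonal) is computed and stored but excluded from
all pair-level normalization.

**Relative probability.** Each directed pair's TSIB is divided by the total
over all ordered pairs i ≠ j. The symmetric dataset first sums the two
directions per pair (preserving real asymmetries in the total, unlike an
average) and is then normalized by its own total — symmetric and asymmetric
matrices are *not* renormalizations of each other.

**Network OC.** Pairs without direct transport are scored on the graph of
positive edges with weights −ln p: the minimum-total-weight path maximizes
the product of edge probabilities (exp(−Σw) = Πp), and OC divides that
product by the number of intermediate populations on the path. The divisor
is floored at 1 so a direct edge keeps OC = p; whether the original
procedure counted intermediates or all path nodes is ambiguous, so
`divisor="path_nodes"` is exposed as an alternative. OC is square-root
transformed (for normality) at export; the flag records the transform so raw
probabilities stay available. Dijkstra tie-breaking among equal-product
paths is arbitrary; with continuous inputs ties have probability zero, and
the exhaustive-enumeration oracle in the tests resolves ties to the fewest
intermediates.

## Population-genetic estimators

Missing data are handled by per-locus pairwise deletion throughout.

**Diversity.** Ho is the mean observed heterozygote proportion over loci;
He uses the unbiased factor 2n/(2n−1). Allelic richness is rarefied to
g genes (default: twice the smallest per-population per-locus sample),
AR = Σₐ [1 − C(N−Nₐ, g)/C(N, g)], averaged over loci. Monomorphic loci give
He = 0, AR = 1.

**HWE.** Monte-Carlo rather than asymptotic χ²: with many rare alleles at
highly polymorphic microsatellites the χ² asymptotics fail. The statistic
is the χ² of genotype counts against expectations from sample allele
frequencies; the null re-pairs the pooled alleles at random (default 9,999
permutations), p = (hits + 1)/(n + 1).

**Differentiation (pairwise, k = 2).** Per locus, with ñ the harmonic mean
sample size and Ho the mean observed heterozygosity:

    Hs = ñ/(ñ−1) · (1 − mean_pop Σ p² − Ho/2ñ)
    Ht = 1 − Σ p̄² + Hs/(ñk) − Ho/(2ñk)

(the sample-size-corrected estimators; a raw-frequency option exists because
the correction moves third decimals and should be explicit). Multilocus
G_ST = (H̄t − H̄s)/H̄t from arithmetic means across loci; Hedrick's
G′_ST = G_ST (k−1+H̄s)/((k−1)(1−H̄s)). Jost's D is computed per locus and
combined by harmonic mean, the convention of the estimator's reference
implementation; when any per-locus D is non-positive the harmonic mean is
undefined and the implementation falls back to the arithmetic mean with a
warning (an explicit `jost_combine="arithmetic"` option is available).
R_ST accumulates allele-size variance components (one-way ANOVA with alleles
as units) across loci and takes σ²_between/(σ²_between+σ²_within), so it is
the only metric sensitive to allele-size relabeling — the property the
stepwise mutation model motivates. Estimates may be slightly negative in
undifferentiated data; raw values are reported (a clamped view exists) so
downstream matrix correlations are not biased. Linearization is x/(1−x);
x = 1 maps to +inf with a warning naming the pair.

**AMOVA.** Five levels: among regions, among populations within regions,
among locations within populations, among individuals within locations,
within individuals. Distances between alleles are 0/1 mismatches by default
(`allele_size` gives squared repeat-count differences). Sums of squares use
the identity SS(group) = Σ_{i<j} d²ᵢⱼ/n; variance components solve the
nested ANOVA expected-mean-square equations with unbalanced-design
coefficients (for each SS level, the coefficient of a deeper component is
the difference of size-weighted squared subgroup sums between the level and
its parent). Components are estimated per locus and summed; a level with a
single group has zero degrees of freedom and is reported as undefined.
φ at level m is σ²_m over the sum of components from m downward; the
within-individual row reports 1 − σ²_e/σ²_total. Significance permutes the
exchangeable unit one level down within its parent (populations among
regions; locations among populations — or individuals, when every
population has a single location, since permuting whole locations would
merely relabel; individuals among locations; alleles among individuals),
999 permutations by default, p = (hits+1)/(n+1).

## Flow statistics

**Mantel / partial Mantel.** r is the Pearson correlation of lower-triangle
vectors; the null jointly permutes rows and columns of one matrix (the
partial variant permutes the raw matrix and re-residualizes). p-values are
one-sided with caller-supplied direction — positive for distance effects,
negative for connectivity — because the underlying hypotheses are signed;
two-sided is available. The 95% CI is a percentile bootstrap over pair
indices (1,000 resamples); the CI method is a package choice, as the
original's is undocumented.

**Directional (vector-permutation) variant.** Matrices are flattened to
their n(n−1) off-diagonal entries in fixed row-major order (diagonals
excluded) and the null permutes the entries of one vector. This
deliberately breaks row/column exchangeability — it is what makes the test
applicable to directional migration matrices — and is implemented exactly
as described, with the row/column-permutation alternative available through
the symmetric functions. On symmetric inputs every unordered pair appears
twice in the vectors, so r equals the symmetric Mantel r; the implementation
computes it from the lower triangle in that case so the agreement is exact
to the last bit.

**MLPE.** For pair q = (i, j), C[q,q] = 1 and C[q,r] = ρ when q and r share
exactly one population. The likelihood is Gaussian GLS, profiled over ρ on
[0, 0.499] (the positive-definiteness bound: the share-graph's smallest
eigenvalue is −2) with Brent/golden-section search to 1e−6; β and σ² have
closed forms given ρ. k counts βs + σ² + ρ;
AICc = −2lnL + 2k + 2k(k+1)/(n−k−1); Akaike weights exp(−Δ/2) normalized,
models within 2 AICc flagged equally likely. CIs and p-values are Wald
(information-matrix) based. ML (not REML) is used, so ρ̂ carries the usual
small-sample downward bias — visible as mean ρ̂ ≈ 0.27–0.29 when the truth
is 0.3 at 15 populations.

**Asymmetry flag.** Migration convention: m[i][j] is the fraction of
population i derived from population j per generation (the convention of
Bayesian assignment estimators; reversing it flips every directional
conclusion). A pair is asymmetric when both directional CIs (m ± 1.96 SD)
exclude zero and do not overlap each other.

**Transforms.** Water distance enters regressions log10-transformed,
migration rates fourth-root transformed, OC square-root transformed;
predictors are centred and scaled with the scaling recorded in the pair
frame so coefficients are comparable across models.

## Synthetic data

The generator defines the study conditions for every test.

**Seascape.** ψ(x, y, t) = A sin(πf(x,t)) sin(πy) with
f = a(t)x² + b(t)x, a(t) = ε sin(2πt/T + φ), b(t) = 1 − 2ε sin(2πt/T + φ)
(ε = 0.25): the classic time-wobbled double gyre, with φ a seeded random
seasonal phase. u, v
are central differences of ψ under a constant metres-per-degree metric at
the domain's central latitude, so the same central-difference divergence
operator annihilates the field to machine precision — the discretization
and the conservation check share their stencil by construction. A
configurable fraction of southern rows is land with zero velocity; the
seasonal cycle wraps periodically in time.

**Genotypes.** Forward-time, non-overlapping generations, constant
population size — adequate for parameter recovery, not demographic realism.
Each offspring draws its parent population from its row of the migration
matrix (migration acts on offspring; the row remainder is
self-recruitment), then selfs with probability s (both gametes from one
parent) or outcrosses between two distinct parents. Every transmitted
allele mutates ±1 repeat with the stepwise probability, reflecting at state
1 — strict stepwise because R_ST assumes it. Founders draw allele sizes
uniformly from 10–30 repeats, a realistic microsatellite range. The default
selfing rate 0.95 is a configuration choice for a primarily self-fertilizing
species — no measured rate is available to pin it — and the defaults
(2–17 populations, 32 loci, mutation 5e−4–1e−3) bracket the regimes the
tests exercise. A `SyntheticTruth` record stores the migration matrix,
rates, and seed, sufficient to regenerate bit-identically.

What the generator does **not** emulate: linkage, null alleles and scoring
error, overlapping generations, seasonal reproduction, population-size
variation, and real bathymetry/tides in the currents. Passing tests
therefore demonstrate the *statistical machinery* — estimator algebra, test
calibration, parameter recovery, sign recovery under current-driven
migration — not field realism.

## Desk-scale problem sizes

The validation suite and `scripts/acceptance.py` run everything at sizes
chosen to finish in minutes on one core while leaving Monte-Carlo error
well inside the asserted tolerances: tracking runs use 5–6 populations on
~60×32–72×40 grids with 8–20 release points, 1–2 particles/day over 5–10
days, tracked 10–15 days; diffusion physics uses 10⁵ kicks; test
calibration 200 replicates × 199 permutations; MLPE recovery 100 fits of 15
populations; the end-to-end sign-recovery experiment 25 genotype replicates
(24 loci, 80 diploids, 120 generations) on one shared tracking run. The
full-design arithmetic (620.5 million particles, 63-day horizon, 12 km
offset) is checked in closed form — the helpers compute it; nothing at that
scale is simulated.

## Known limitations

- 2-D surface transport only: no vertical movement, behaviour, mortality,
  or age-dependent viability of propagules.
- The MLPE working correlation treats all shared-population pairs
  identically; no spatial autocorrelation beyond that structure.
- The AMOVA permutation schemes follow the standard one-level-down
  convention; exactness is only guaranteed under exchangeability at that
  level.
- Harmonic-mean combination of Jost's D is undefined with non-positive
  per-locus estimates; the arithmetic fallback makes near-zero
  differentiation comparable across metrics but mixes conventions at the
  boundary (flagged by a warning).
- NetCDF output uses the NetCDF-3 (scipy) backend; files are readable by
  any NetCDF tool but without NetCDF-4 compression.
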
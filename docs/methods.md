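# Methods

This note documents the models and numerical choices behind
`rosetteqtl`: what each stage computes, which knobs matter, what the
synthetic data does and does not emulate, and where the design was
genuinely open.

## 1. Raster morphometry

All measurements start from a binary mask and a physical scale
`mm_per_px`. The region is reduced to its largest 8-connected component
(smaller components are discarded with a warning).

**Area and perimeter.** Area is the foreground pixel count times
`mm_per_px²`. The perimeter is the polyline length of the 0.5-level
contour of the Gaussian-smoothed mask (σ = 1 px). A raw binary contour
or chain code systematically overestimates smooth perimeters by 3–6%
(the staircase effect), which would push the roundness of a disk to
~0.90 instead of 1; the sub-pixel contour brings the disk to RND = 0.99
and keeps perimeters within 0.5% of exact vector values on the synthetic
rosettes.

**Convex hull.** The hull is taken over the *corner* points of boundary
pixels, not pixel centers. The hull of pixel centers is a subset of the
pixel region and makes `AreaConvexHull < Area` for convex shapes, which
would push Compactness above 1; corners guarantee
`AreaConvexHull ≥ Area` exactly. The price is a ~half-pixel dilation of
the hull, ~0.3% on hull area at 1024 px.

**RMS (rotational mass symmetry).** The comparison circle has the same
area as the convex hull (equivalently Area/Compactness) and is centred
on the plant centroid. Because circle and hull then have equal area, the
hull-only and circle-only pieces are equal and the index reduces to
1 − AreaIntersection/AreaConvexHull ∈ [0, 1]: 0 for a centred round
hull, → 1 for strongly eccentric or offset shapes. Intersections are
computed by polygon clipping against a 1024-gon circle.

**Skeleton.** The skeleton drives SOL (squared skeleton length over
area) and the leaf-tip polygon behind ISO, and is the numerically
hardest quantity. The implementation:

1. re-binarizes the mask from a Gaussian boundary model (σ = 2 px) —
   raw masks carry 1–2 px boundary roughness (worse after resampling or
   rotation) whose medial-axis spurs no pruning rule can separate from
   real limbs; regularization moves the true boundary by < 0.2 px while
   pushing roughness below a pixel. Structures narrower than ~4 px are
   below this scale and contribute no skeleton.
2. computes the exact Euclidean medial axis (`skimage.medial_axis`,
   tie-breaking pinned for determinism) and converts it to a pixel
   graph; chains are measured as Douglas–Peucker-simplified polylines
   (tolerance 1 px), removing the oblique-staircase length bias.
3. prunes endpoint branches by **maximal-disc salience**: branch length
   plus endpoint inscribed radius minus junction inscribed radius.
   Boundary-noise branches score ≈ 0 *however long they are* (their
   length is exactly offset by the inscribed-disc growth), so the cutoff
   is a small constant (3 px), not a fraction of the shape size.
   Salience credit accumulates across nested junctions, so cascaded
   pruning never removes more than the cutoff's worth of real structure.
   Under this rule the medial web of a disk collapses to a point
   (SOL ≈ 0) while a rectangle keeps its corner diagonals.
4. extends each terminal branch to the true medial terminus by marching
   along the branch direction through the distance field while
   g(ℓ) = D + ℓ still climbs; past the medial endpoint the nearest
   boundary is the cap tip itself and g plateaus. This recovers the cap
   erosion that discrete thinning always incurs.

On 20 random synthetic rosettes at 1024 px the raster skeleton length
agrees with the exact medial axis of the vector geometry to ≤ 3%
(SOL ≤ 5%), and the skeleton endpoints land on the blades' medial
termini, making the ISO tip polygon match its vector counterpart to
≤ 2%.

**Moments and ECC.** Major/minor axes are 4·√eigenvalue of the second
central moment matrix of pixel centers (the ellipse with identical
second moments); ECC = √(1 − (Minor/Major)²).

**Tip polygon / ISO.** Skeleton endpoints ordered by angle about the
centroid; with fewer than 3 endpoints (disks, blobs) the convex hull is
used instead, so ISO falls back to RCH.

## 2. Synthetic rosettes (the morphometry oracle)

A synthetic rosette is a central disk plus `n_leaves` leaves at
multiples of the divergence angle (golden angle 137.5° by default),
each a petiole rectangle plus an elliptical blade. Two geometric
details make the construction *exactly* measurable:

- the blade is embedded over the petiole end (the petiole's corners lie
  strictly inside the ellipse) and the petiole anchors just inside the
  disk edge. Butt-joined primitives meet tangentially and open sliver
  notches of sub-pixel width that hold > 1% of the vector perimeter —
  unresolvable at any raster scale; embedded junctions are transversal.
- the random spec sampler rejects draws whose leaves approach within
  0.3 mm of each other, and sizes the central disk to cover all petiole
  near-crossings. Only mutually disjoint leaves have closed-form
  skeletons (one radial branch per leaf, ending short of the blade tip
  by b²/a for blade semi-axes a ≥ b) and tip polygons.

The vector oracle evaluates all nine descriptors on the exact polygon
union (ellipses at 1024-gon resolution): areas/perimeters by polygon
arithmetic, second moments by the shoelace moment formulas, hull by
exact convex hull, circle overlap by polygon clipping, skeleton by the
medial-axis formulas above (with an optional salience truncation that
mirrors the raster pruning rule). Rasterization marks a pixel foreground
iff its centre lies inside the exact primitive union, so the mask is a
pure function of (spec, seed).

What the generator does **not** emulate: overlapping leaves (real
rosettes overlap heavily at later ages; the generator unions them if a
user requests it, but the oracle is then invalid for skeleton-derived
quantities), serrated leaf margins, petiole curvature, and segmentation
artifacts. Passing the oracle suite therefore demonstrates metrological
correctness of the descriptor implementations, not robustness to
segmentation noise in real images.

## 3. MAGIC population simulator

The crossing funnel is not replayed generation by generation — the scan
only consumes founder mosaics, and no funnel parameters are available —
so each line × chromosome is an equivalent Markov mosaic: a
Poisson-distributed number of breakpoints (default mean 3 per
chromosome, a free parameter of the simulator, not an estimate of the
real population) at uniform cM positions, with an independent uniform
founder per segment. Founder panels are biallelic with per-marker
allele frequencies uniform in (0.2, 0.5) on an equally spaced cM map
(1 cM ≈ 250 kb). SNP calls copy the segment founder's allele with a
symmetric flip at rate ε = 0.01 (genotyping error; the source data's
error rate is unpublished).

Phenotypes follow the same law the heritability estimator assumes —
y_ij = μ + effect[founder at causal marker] + line_i + noise_ij — with
optional rescaling of the founder effects so the QTL explains a target
fraction of total variance (computed against the realised founder
distribution of the simulated lines, and reported back alongside the
table).

## 4. Phenotype statistics

Replicates are averaged per (line, DAS); all downstream analysis uses
line means. Pearson correlations are computed per DAS on the means
(raw, per-DAS — whether to pool standardization across days was open;
per-day raw correlation is the direct reading of "correlation across
averages at each DAS").

**Heritability.** One-way random-effects REML, profiled in the variance
ratio λ = Vg/Ve (the closed-form residual variance given λ leaves a 1-D
bounded minimization; boundary solutions truncate Vg at 0). For
balanced data this coincides with the ANOVA estimator when that is
positive — the balanced method-of-moments identity is used as a test
oracle, and `statsmodels` MixedLM as an independent cross-check on
unbalanced data. H² = Vg/(Vg+Ve) ∈ [0, 1] by construction. At 485
lines × 3 replicates the mean bias over a Vg/Ve grid of {0.25, 1, 4} is
below 0.05.

**Morphospace.** PCA of the correlation matrix of the nine descriptors
over line-averaged rows pooled across all DAS (per-DAS fitting is
available by subsetting the input). All nine components are retained,
so the transform is orthogonal and line–line distances are preserved in
the standardized space. Signs are fixed by making each component's
largest-magnitude loading positive, so loadings are reproducible across
platforms.

## 5. Founder-probability scan

**HMM.** Per chromosome, hidden founder state over 19 founders; forward–
backward with per-step rescaling. Emissions: 1−ε on allele match, ε on
mismatch, 1 on missing; lines with > 20% missing calls are dropped with
a warning. Transitions: switch probability from Haldane's map function
on the inter-marker distance, rescaled so the expected number of
switches per chromosome equals a mosaic-density parameter (default 3,
matching the simulator's default breakpoint rate; the scan is
insensitive to moderate mismatch in this parameter). The posterior is
validated against exhaustive path enumeration on small instances.

**Per-marker test.** The founder-probability design is rank-reduced by
SVD (rows sum to one, so the intercept is inside the span and the
founder term has rank − 1 numerator degrees of freedom); p-values from
the F distribution; variance explained is the model R². Effect
estimates are raw pseudo-inverse founder means shrunk toward their
probability-mass-weighted average with founder-specific precisions
(between-founder variance estimated by moments and truncated at zero) —
an empirical-Bayes summary standing in for a full hierarchical
random-effects sampler, whose priors are not published; a sampler could
be slotted in behind the same `ScanResult` interface. Precomputed
per-marker orthonormal bases make a 500-permutation threshold for a
200-line × 100-marker scan take ~0.1 s.

**Thresholds.** Per-trait permutation of the phenotype vector;
genome-wide threshold = type-7 (linear-interpolation) empirical
(1 − α) quantile of the per-permutation maximum logP. No additional
correction is applied across trait × DAS combinations — each trait
carries its own permutation threshold; a genome-wide-across-traits
correction would be stricter. The fixed logP ≥ 3.5 convention can be
passed as a plain float wherever a `Threshold` is accepted; both are
reported by the pipeline.

Null calibration holds by construction (the observed maximum is
exchangeable with the permuted maxima): measured genome-wide type-I
error is 0.05 ± 0.03 at α = 0.05 over 200 simulated null traits. Note
that *per-trait genome-wide p-value histograms* are not uniform-looking
under linkage — adjacent markers share founder mosaics — so marginal
calibration is asserted per marker across traits, and family-wise
calibration through the permutation threshold.

## 6. QTL post-processing

Peaks are maximal runs of contiguous threshold-passing markers within a
chromosome (runs never bridge a sub-threshold marker — the strictest
reading); the peak is the run's largest logP, ties to the lowest
position. The redundancy filter walks days in ascending order and,
within a day, descriptors in table order (PRA, PL, Compactness, RMS,
SOL, RND, RCH, ISO, ECC) then PC1..PC9, keeping a record only if its
peak marker was not kept before. Locus identity is the exact peak
marker by default; a base-pair window is available
(`window_bp`) since "same locus" is otherwise under-specified. The
filter is idempotent and the per-day / per-variable / per-chromosome
count tables partition the filtered set, so their totals agree by
construction. Nearest genes come from a GFF3 annotation (1-based
inclusive; distance 0 inside a gene, else distance to the nearer end;
ties to the lower start coordinate).

## 7. Pipeline, determinism, problem sizes

One global seed fans out to per-stage seeds through
`SeedSequence(entropy=(seed, stage_index))`, so stages are reproducible
in isolation. Every output file is SHA-256-hashed into `manifest.json`;
a rerun with the same configuration reproduces the hashes bit for bit
(medial-axis tie-breaking is explicitly pinned — it is randomized by
default in scikit-image).

Default problem sizes are chosen so the full synthetic pipeline runs in
seconds and the validation suite in about a minute on one core: 200
lines × 3 chromosomes × 60 markers for the demonstration pipeline; 20
rosettes at 1024 px for oracle checks; 485 × 3 for heritability
recovery (the study scale); 200 null traits × 500 permutations at 200
lines × 100 markers for calibration; 50 populations of 400 lines for
power. These sizes are statements of the validated regime, and all are
configurable.

## 8. Known limitations

- Descriptor accuracy is validated against ideal geometry; segmentation
  noise in real masks enters all descriptors, most strongly SOL/ISO.
  The Gaussian boundary regularization suppresses roughness up to ~2 px;
  coarser artifacts (holes, touching neighbour plants) must be cleaned
  upstream.
- Masks are assumed to contain a single plant; multiple components are
  resolved by size, which fails if a neighbour is larger.
- The scan assumes an unstructured population (no kinship correction),
  appropriate for MAGIC designs but not for natural accessions.
- The HMM models a haploid (fully inbred) genome; residual
  heterozygosity is not represented.
- Printed-precision CSV round-trips are exact for float64, but scans of
  perfectly collinear founder columns rely on SVD rank decisions at
  relative tolerance 1e-9.
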
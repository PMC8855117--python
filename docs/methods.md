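# Methods

This note records the models, conventions and numerical choices behind
`astromorph`, in the order the pipeline runs them.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Reconstructions and sampling

Cells are rooted trees of measured nodes (position in μm, radius, integer
type tag) exchanged as SWC.  Validation enumerates every structural defect
(duplicate ids, missing/multiple roots, orphaned or forward-referenced
parents, self-cycles, non-positive radii) rather than failing on the first.

Histological processing compresses the section axis; the correction
multiplies every recorded z by a factor (default 1.75) and touches nothing
else.  The literature reports the factor but not the direction of
application; multiplying recorded z (i.e. restoring pre-processing
thickness) is this package's choice and composes cleanly
(factor a then b ≡ factor a·b).

Stereological sampling places square probes (default 50 μm side) on the
lattice `offset + spacing·(i, j)` (default spacing 900 μm) clipped to the
region contour.  Lattice-point inclusion and probe-box membership are both
half-open (`[low, high)`, realised by an ε-nudge for arbitrary polygons) so
adjacent tiles can never claim the same point.  A probe containing no soma
falls back to the nearest soma outside it, measured to the box, with ties
broken by lowest cell id; each soma is selected at most once.  With a
uniformly random offset in `[0, spacing)²` the expected probe count is
area/spacing², making the design systematic-random.

## Morphometry

Segments run from the soma or a branch point to the next branch point or
terminal; centrifugal order starts at 1 for primaries.  The soma (root) is
never a branch point.  Per-cell features and their conventions:

* **Lengths** — summed inter-node Euclidean distances.  Tortuosity is the
  mean per-segment arc/chord ratio (zero-chord segments are excluded with a
  warning); the aggregation (mean) is a package choice.
* **Frustum surface/volume** — every edge is a conical frustum defined by
  its endpoint radii (lateral area π(r₁+r₂)·slant, volume
  πh(r₁²+r₁r₂+r₂²)/3).  The soma is not added as a sphere.
  `branch_surface_area` is the tree total divided by the number of
  primaries.
* **Planar angle** — mean over branch points of the angle between the
  direction vectors to the first node of each daughter; multifurcations
  average over daughter pairs; cells without branch points report NaN (never
  0).
* **Vertex analysis** — branch points classified by terminal daughters:
  ≥ 2 → Va, exactly 1 → Vb, 0 → Vc (the ≥ rule extends the binary
  definition to multifurcations).
* **Convex hulls** — 2-D metrics from the XY (section-plane) projection,
  3-D from the full cloud, both via Qhull; degenerate inputs report 0 with a
  flag.  The 2-D metrics are *defined* in the section plane and are
  therefore invariant to in-plane rotations only; all other features are
  full Euclidean invariants (verified to 1e-6 relative).
* **Fractal dimension** — box counting on the arbor resampled to points at
  most min(scale)/4 apart.  The cloud is first centred and rotated to its
  principal axes with third-moment sign canonicalisation, which makes the
  count independent of the cell's pose; scales default to 6 dyadic halvings
  of half the largest extent (> one decade).  The slope of log N vs
  log(1/s) is clamped to [0, 3].
* **Complexity** — `(Σ terminal orders + #terminals) × (total length /
  #primaries)`, in μm; strictly increasing in total length at fixed
  topology, and scaling as length under uniform spatial scaling.

The feature list has 19 entries; any named subset can be carried through the
pipeline.

## Morphotype discovery

**Screening.** The multimodality index is the classical bimodality
coefficient computed with bias-corrected sample skewness and *excess*
kurtosis, so its landmarks sit at 1/3 (normal), 5/9 (uniform) and 1
(symmetric two-point); the retention threshold is a strict `MMI > 0.55`.
The excess-kurtosis reading is a package choice: it is the convention under
which 0.55 separates the uniform from the normal.

**Transform.** Retained features are log₁₀-transformed (log₁₀(x+1) for
features containing zeros, flagged) and scaled to unit sample variance —
the "variance-shrunk logarithmised" preparation, pinned down here as
log then unit-variance scaling.

**Clustering.** Ward's minimum-variance agglomeration on Euclidean
distances (SciPy linkage; heights √(2n₁n₂/(n₁+n₂))·‖c₁−c₂‖).  The cluster
count k ∈ [2, 6] is chosen where the merge-height profile jumps most.  The
default criterion is the *ratio* of the first between-cluster merge to the
last within-cluster merge rather than their absolute difference: for four
or more roughly evenly spaced clusters the absolute gap is provably
maximised at k = 2 (the final merge height grows with the merged cluster
sizes), so a gap rule cannot recover k = 4; the ratio rule agrees with the
gap rule on well-separated 2- and 3-cluster structures and recovers the
generated k on the default 3- and 4-class populations.  `criterion="gap"`
and an explicit k override remain available.  Clusters are relabelled
1..k by decreasing mean complexity (Type 1 = most complex).

**Discriminant validation.** Forward stepwise entry by partial-F p-value
(enter the smallest-p variable while p < α = 0.05; no removal step), then
the canonical eigenproblem B v = λ W v on the entered variables.  Reported:
eigenvalues, percent variance, Wilks's Λⱼ = Π_{i≥j} 1/(1+λᵢ) with Bartlett
χ² p-values, the pooled within-group structure matrix, and a resubstitution
confusion table from nearest-centroid classification in canonical space
(Euclidean there = Mahalanobis in feature space).  A singular within-group
scatter falls back to a small ridge (1e-8·tr(W)/p) with a warning.

**Representatives and density peaks.** Each cluster's "average cell"
minimises the summed Euclidean distance to its cluster mates (ties →
lowest cell id).  Mode counting uses a Gaussian KDE on a 512-point grid
with peaks defined as interior maxima of prominence > 5% of the maximum.
The default bandwidth is a two-stage rule: a Silverman-bandwidth pass
locates candidate modes, then the bandwidth is recomputed from the pooled
*within-mode* standard deviation (×1.5).  Plain Silverman scales with the
overall spread and demonstrably merges even widely separated modes of a
4-component mixture; the two-stage rule counts 1–4 modes correctly across
the generator's settings while still reporting a single mode for unimodal
and skewed null samples.  `'silverman'` and absolute bandwidths remain
available.

## Permutation inference

Distance matrices are Euclidean on log₁₀(x+1), unit-variance-scaled
features.  PERMANOVA partitions the Gower-centred inner-product matrix
G = −½ J D² J:

* one factor — classical pseudo-F with free permutation of group labels
  (vectorised over permutations);
* two factors — type-III sums of squares from full-vs-reduced hat-matrix
  comparisons with sum-to-zero contrasts, pseudo-F per main effect and
  interaction, and p-values by permutation of the reduced-model residual
  matrix (Freedman–Lane); `scheme="free"` is available.

PERMDISP embeds the distance matrix by principal coordinates (negative
eigenvalues handled by Anderson's signed-square correction), computes each
member's distance to its group centroid, takes the one-way ANOVA F on those
distances, and permutes their group labels; pairwise pseudo-t tables use
the same construction per pair.  The crossed species × type dispersion
analysis treats each species–type cell as one group (dispersion is defined
for a single grouping; this is an interpretation and is labelled as such).

All permutation p-values use (count ≥ observed + 1)/(n_perm + 1) — never
exactly 0 — with the seed recorded next to every p.  The univariate
allele-size comparison uses unrestricted raw permutation, the two-factor
morphometric design the residual scheme; default 9,999 permutations.
Pairwise p-values are reported raw and Sidak-adjusted (1−(1−p)^m).  The
univariate GLM battery reports one-way F, pooled-variance pairwise t tests
with Sidak adjustment, and Cohen's d on the pooled SD (undefined → NaN).

## Microsatellite statistics

He uses the unbiased correction (2n/(2n−1))(1−Σp²) on 2n gene copies.  The
Hardy–Weinberg Monte-Carlo test re-pairs the observed gene copies into
random diploids; its statistic is heterozygosity-based at per-allele
resolution (summed |observed − expected| heterozygote count per allele)
because the total heterozygote count takes too few values to yield an
approximately uniform permutation null.  FST is Weir–Cockerham θ summed
over alleles; RST is the among-population component of allele-size variance
from one-way variance components (no standardisation, so values are
comparable across runs of this package only).  Pairwise p-values permute
individuals between the two populations.  FST is invariant to relabeling
and to affine changes of the size ladder; RST is size-based and is not.

The association analysis pairs each individual's mean allele size (the
individual-level pairing is a package choice) with its species' migratory
distance: Spearman ρ with midrank ties and a permutation p (two-sided on
|ρ|), plus the ordinary least-squares correlation R.

## Synthetic data

The astrocyte generator grows primaries from the soma in random directions;
each segment integrates its direction with per-step Gaussian wiggle and, up
to a maximum centrifugal order, ends in a symmetric bifurcation with a
fixed probability.  It is a minimal stochastic branching process chosen for
analyzability (terminal counts and segment numbers have closed-form
expectations), not biological realism: no self-avoidance, tiling, leaflets
or imaging noise.  `n_primary` is an exact count, not a Poisson mean, so
closed-form examples are exact.

The default class ladders share a near-saturated bifurcation probability
(0.9) — which concentrates terminal counts and keeps within-class
log-complexity spread near 0.1–0.2 — and step maximum order, primary count
and segment length between classes so that consecutive class means of
log₁₀ complexity (and hull volume) are roughly 1.1–1.8 apart: clearly
multimodal, approximately evenly spaced modes, emulating mixed morphotype
populations.  These settings were fixed from the closed-form expectations
above.  Passing the pipeline on this generator shows the machinery recovers
structure of this kind; it does not certify performance on real arbors,
whose classes are less separated and whose features are noisier.

Genotypes are drawn in Hardy–Weinberg proportions from a discretised normal
on the 168–204 bp, 2 bp ladder.  The default four-species specification
uses the study's sample sizes (12–14 individuals) and a 4 bp step in mean
allele size between species ordered by migratory distance with a 2 bp SD;
a flat variant (all species identical) serves as the null.  Sections are
rectangles with Poisson-scattered somata.

All randomness flows from a single root seed via `numpy.random.SeedSequence`
spawning; the pipeline derives per-stage seeds the same way, which is why a
fixed seed reproduces byte-identical reports.

## Problem sizes and defaults

The shipped analyses use 40 cells per class (120–160 cells per population),
999–9,999 permutations, and 100-seed calibration loops where rates are
asserted; these sizes give stable rates while keeping any single run in
seconds to a few minutes on one CPU.  Defaults throughout are the study's
stated parameters: z-factor 1.75, MMI threshold 0.55, α 0.05, 9,999
permutations, probe 50 μm / spacing 900 μm.

## Known limitations

* Morphotype recovery is demonstrated on well-separated synthetic classes;
  overlapping real populations may require the k override or the `gap`
  criterion.
* The discriminant confusion table is resubstitution, not cross-validated,
  and therefore optimistic by construction.
* RST is unstandardised; HWE and differentiation tests are single-locus.
* The box-counting dimension is a finite-scale estimate; its absolute value
  depends on the scale range, which is why the same dyadic convention is
  applied to every cell.
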
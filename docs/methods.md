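# Methods

This note documents the models, statistics and numerical choices behind
`plaquespace`, what the synthetic generator does and does not emulate, and
the known limitations.

## The synthetic tissue model

The generator is the package's testbed: it produces data with the same
schema as a Baysor-segmented Xenium run and with planted structure that
every downstream stage should recover.

**Geometry.** A sample is a disc of radius `tissue_radius_um` (default
1000 µm) with concentric annular subregions at fixed radial fractions:
lumen [0, 0.20], necrotic core [0.20, 0.45], fibrous cap [0.45, 0.60],
intima [0.60, 0.80], media [0.80, 1.00].  Controls lack the necrotic core
and fibrous cap; their intima spans [0.20, 0.80], matching the anatomy of a
non-diseased artery wall.  Polygons are 64-gon approximations of circles;
annular regions carry a true interior ring.  Because areas are computed
from the emitted vertices by the shoelace formula, area checks are exact
rather than πr² approximations.

**Cells.** Each cell draws a substate (default catalogue: endothelium near
the lumen, two macrophage substates spanning core and cap, modulated and
contractile VSMCs in intima and media), is placed uniformly-by-area within
its substate's radial band (optional Gaussian radial jitter), and receives
a lognormal area (median 150 µm², σ = 0.35 in log space — the scale of
segmented cells in plaque tissue), a Beta(12, 2) average assignment
confidence (mode ≈ 0.92, a well-segmented sample), Beta(40, 1.5)
`max_cluster_frac` and lognormal `lifespan`, so a realistic minority of
cells fails each QC filter.

**Counts and transcripts.** Counts are negative binomial with mean =
(gene-program mean) × (cell area / mean area) and a single shared
dispersion (default 2.0).  Each substate has eight marker genes at mean 3
counts per average cell, a shared housekeeping block at 1, and background
at 0.05 — the sparsity regime of a targeted in situ panel.  The transcript
table is the exact expansion of the count matrix (positions scattered
around the centroid at half the cell radius), so transcript/count
conservation is exact by construction.  Noise transcripts are scattered
uniformly over the disc at rate `noise_transcript_rate` (default 10%),
carry confidence 0 and no cell id.  Q-scores are Uniform(20, 40) with a
5% Uniform(10, 20) low-quality fraction, independent of noise status.

**Determinism.** One global seed; sample k draws from a child generator
seeded by (seed, k), so any sample can be regenerated alone.  Cohort
metadata (condition, a binary covariate) uses a separate child stream.

**What it does not emulate.** No gene–gene correlation beyond the shared
program structure; no optical artefacts, doublet geometry or segmentation
errors (QC fields are drawn, not caused); no thrombi; noise is spatially
uniform whereas real noise concentrates in acellular regions.  Passing the
planted-recovery tests therefore shows the *algorithms* are correct and
calibrated, not that real plaque data is this easy.

## QC and segmentation selection

Thresholds follow the upstream pipeline's conventions and are all
overridable: transcripts need Q ≥ 20, and assigned transcripts
additionally confidence > 0.5 (strict, so 0.5 is removed); cells need
≥ 10 non-zero genes, confidence ≥ 0.75, `max_cluster_frac` ≥ 0.9 and
`lifespan` ≥ 50 (removals are strictly "lower than", so threshold-equal
cells are kept).  Per-criterion attrition is logged; criteria overlap, so
the removed total is the union, not the sum.

AUC₀.₇₅ fits a Gaussian KDE (Scott's rule, bandwidth per candidate) to the
per-cell confidences, evaluates it on a 512-point grid over
[min − 3h, max + 3h], and reports the trapezoid mass on [0.75, 1] divided
by the total grid mass, so the score is a proportion and candidates with
different supports are comparable.  Whether to renormalize the KDE is a
genuine free choice; the proportion form was chosen because it bounds the
score in [0, 1].  Zero-variance inputs short-circuit: 1 if the constant is
≥ 0.75, else 0.  Selection takes the arg-max with lexicographic
tie-breaking (logged).  Consequence of Scott's rule: the score is only
approximately invariant to duplicating every observation (the bandwidth
shrinks with n); the test suite checks invariance to within 0.02.

## Subregion geometry

Coordinates are real-valued µm throughout.  Polygons are treated as closed
sets (boundary points are inside) — the conservative choice for thin
regions.  Where digitized regions overlap, assignment priority follows
anatomical containment: lumen > thrombus > necrotic core > fibrous cap >
intima > media.  "Whole sample area" for normalized region areas is the
sum of annotated region areas (un-annotated space is excluded); the lumen
is included by default with an `include_lumen` flag.  Noise accounting
bins every transcript by its own coordinates and reports both the
within-region noise ratio noise/(noise+assigned) and each region's share
of total sample noise; an `unassigned` row keeps the counts conserving.

## Morphological clustering and association tests

Substate fractions are percentages within sample (or sample × region),
with thrombus-resident cells excluded by default.  Ward linkage on
Euclidean distances of the raw percentage rows (no column z-scoring by
default; fractions share a scale); the cluster count k is the analyst's
call, defaulting to 4.  Numeric associations use OLS with the two-sided
t-test on the slope; categorical ones use the two-sided rank-sum test
(exact for small tie-free samples via scipy's policy).  A linear mixed
model for repeated measures per patient is deliberately not provided; the
OLS fallback is documented as such.  All families are corrected with
Benjamini–Hochberg step-up (via statsmodels), order-preserving and capped
at 1.

## Neighbourhood enrichment

The radius graph uses a closed ball (distance ≤ 100 µm); 100 µm is the
default because smaller radii leave cells with no neighbours and larger
ones blur sample-specific composition into every neighbourhood.  The focal
cell is excluded from its own neighbourhood counts (self-inclusion would
add a constant per substate).  Neighbourhood vectors enter clustering as
raw counts (optionally log1p); identical vectors are collapsed before the
exact Euclidean 15-NN graph is built, because indistinguishable cells must
co-cluster and Leiden would otherwise partition an arbitrarily tie-broken
graph.  Leiden (RB-modularity, python-igraph/leidenalg, fixed seed,
2 iterations) runs on the unique-vector graph; resolution is therefore
calibrated against that graph — 0.2 recovers three well-separated planted
domains; the default 1.0 suits finer structure.

The enrichment score counts unique undirected edges per unordered substate
pair, including same-substate pairs, within the cluster-restricted graph;
scores over all pairs sum to the within-cluster edge count (a conservation
law checked on every instance).  The null shuffles labels within samples —
shuffling across samples would violate exchangeability because samples
differ in composition.  p-values use the add-one Monte-Carlo rule with
*strict* exceedance counts (l = #{null < obs}, r = #{null > obs}); the
two-sided p is min(2·p_left, 2·p_right) capped at 1.  Agresti–Coull
intervals (ñ = N + z², p̃ = (x + z²/2)/ñ) for the left and right tail
proportions are combined endpoint-wise by the same min-rule and capped.
BH runs jointly across all (cluster, pair) tests by default (a
per-cluster option exists); significance is FDR < 0.05.  Null scores are
streamed — only the exceedance counters are held, bounding memory at
N = 10,000 over many pairs — and each permutation derives a child RNG from
(seed, permutation index), so results are reproducible and
order-independent.  At N = 500 the realized null rejection rate of
p_two ≤ 0.05 measures 0.049 over 200 null cohorts (see
`scripts/acceptance.py`), i.e. the strict-count two-sided rule is
well calibrated at the edge densities the generator produces; with very
discrete scores (tiny clusters) it can be mildly anti-conservative in the
tails, which is inherent to the strict-count form.

## Local spatial statistics

Both statistics z-standardize with the population SD (divide by n), the
convention under which the hand-checkable 4-cell example gives I_i = 1
exactly.  Moran: row-standardized 30-NN weights; ties in distance resolve
to the lower cell index; cells in samples with fewer than k others use all
available.  Getis-Ord: binary 2500 µm distance-band weights, plain G (the
focal cell is excluded from numerator and denominator); the denominator is
permutation-invariant, which the implementation exploits.  Both use the
classical conditional permutation scheme: the focal value is held fixed
and the remaining values are sampled without replacement into the
neighbour positions (one shared position matrix per call, one shuffled
"others" list per cell).  Moran p-values are one-sided upper-tail
(positive local association, the colocalization question); Getis-Ord
p-values are two-sided — the asymmetry is deliberate and mirrors how the
two analyses are conventionally reported.  These p-values use inclusive
counting (#{null ≥ obs} + 1)/(N + 1), the standard valid form for
continuous statistics.  BH is applied per (variable-pair, sample) family.
Quadrants (HH/HL/LH/LL) come from the signs of z_x and the lag; hot/cold
requires significance plus G above/below its null mean.  A cell whose
denominator is zero (the only positive value in the sample) gets a missing
statistic with a warning.

## Layering

Min-max normalization is per gene within sample — the only reading that
makes gene values comparable across cells; constant genes map to 0 so
profiles stay finite.  Profile z-scores are per gene across substates
(population SD, constants → 0); top-variance gene ranking breaks ties by
gene name.  Lumen distance is the Euclidean distance to the nearest lumen
polygon (0 inside; nearest fragment if the lumen is split), normalized by
the per-sample maximum raw distance (an alternative tissue-radius
denominator is a natural flag to add); the 0.25 cap *filters* to the
subluminal zone rather than truncating values.  Layering order is the
ascending ranking of per-substate medians over included cells.

## Problem sizes and verification

The test suite checks every operation against an independent oracle
(O(n²) brute force, exhaustive enumeration, hand formulas, fan
triangulation, winding numbers, a hand-written BH step-up) and verifies
calibration and power on planted data: 100 random instances for the
enrichment score, exhaustive 4-cell enumeration plus N = 10,000
Monte-Carlo for the p-values, 200 null cohorts (N = 500) for type-I error,
2 × 2000 cells for domain recovery (ARI ≥ 0.8 required, ≈ 0.93 observed),
20 seeds × 16 samples for archetype recovery (ARI ≥ 0.9 required, 1.0
observed), 200 simulations for Moran null uniformity, 50 seeds each for
hotspot and layering power.  These sizes make the whole suite run in well
under a minute per module; they are scaled-down study conditions, and all
thresholds were fixed by the planted effect sizes, not tuned to outcomes.

## Known limitations

- The neighbourhood-cluster count depends on the Leiden resolution, which
  has no universal default; analyses should report it.
- The enrichment test conditions on the observed clustering; p-values do
  not account for having chosen the clusters from the same data (as is
  standard for this kind of post-clustering test).
- OLS association ignores patient-level repeated measures.
- KNN weight ties are broken by index, which is deterministic but
  arbitrary on exactly-gridded coordinates.
- The generator's QC fields are independent draws, so QC attrition rates
  are realistic in magnitude but carry no structure (e.g. no
  area–confidence correlation).
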
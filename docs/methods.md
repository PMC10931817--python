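# Methods

This note documents the models, algorithms and numerical choices behind
`ihcsynapse`: what each stage computes, which parameters matter, what the
synthetic generator does and does not emulate, and where the design was
genuinely open.

## 1. Problem setting

Afferent ribbon synapses of cochlear inner hair cells (IHCs) are
quantified from three-channel confocal stacks: a presynaptic ribbon
channel (CtBP2-like), a postsynaptic receptor-patch channel (GluR2-like)
and a hair-cell body channel. A functional synapse is defined
object-wise: a presynaptic component and a postsynaptic component that
overlap or at least touch in 3D. Scientific questions concern synapse
counts per IHC, their split between the modiolar and pillar halves of the
cell, and gradients in (normalized) element volumes — compared between
age groups and between tonotopic locations (1, 2 and 16 kHz; 2.51, 3.8
and 8.13 mm from the apex — shipped as configuration constants, the
underlying frequency-place map is out of scope).

All geometry is computed in physical units. Arrays use (z, y, x) axis
order; the default voxel spacing is 0.3 × 0.08 × 0.08 µm (z, y, x) — the
x–y value is the midpoint of the 0.07–0.10 µm/px acquisition range, the
z-step the standard 0.3 µm (0.5 µm supported via metadata/override).

## 2. Detection

**Threshold.** The original analyses of this kind used interactive,
observer-dependent thresholds, which are not recoverable; the package
defaults to an automatic, reproducible rule and exposes overrides. The
default is a robust background model: threshold = median + k·1.4826·MAD
of the whole channel (k = 6). Puncta occupy ~10⁻⁴ of a stack's voxels,
so balanced-histogram methods misbehave: Otsu in particular bisects the
*background* mode when the foreground mass is negligible, flooding the
mask. Otsu remains available (and correct for balanced two-level images),
as do triangle, quantile and fixed thresholds. The resolved threshold per
stack and channel is recorded in the provenance block. Downstream median
normalization is designed to absorb residual threshold liberality.

**Components.** 3D connected components under 26-connectivity (default;
6/18 available), minimum size 5 voxels (≈ 0.0096 µm³ at the default
spacing). Volume = voxel count × voxel volume. Centroids are unweighted
voxel-coordinate means (µm); intensity weighting is available as an
option — the choice is arbitrary for compact bright spots and unweighted
centroids are reproducible across intensity scalings.

**Splitting.** Merged elements (two ribbons or patches fused by a
bridge) are split automatically, replacing interactive splitting: the
component's Euclidean distance transform, computed with anisotropic
sampling in µm and lightly smoothed, is searched for local maxima; maxima
closer than `split_min_separation_um` (default 0.6 µm, about one ribbon
diameter) are suppressed in order of depth. Two or more surviving maxima
trigger a marker-controlled watershed constrained to the component.
Fragments below the minimum size give their marker up and the watershed
is rerun, so every fragment passes the size filter while the fragment
union always equals the input voxel set (conservation is asserted).

**Distractor filter.** An optional maximum component volume
(`max_volume_um3`, default 1.5 µm³ in the packaged pipeline config)
rejects broad-spectrum autofluorescent aggregates (lipofuscin in aged
tissue), whose volumes sit well above the synaptic range. The filter runs
*after* splitting so merged synaptic elements are first separated.

## 3. Colocalization

The gap between two components is 0 if their voxel sets intersect or are
26-adjacent — on a voxel grid, zero Euclidean distance between binarised
regions is exactly shared-face/edge/corner adjacency — otherwise the
minimum pairwise distance between member voxel centres in µm. Matching is
one-to-one over all candidate pairs with gap ≤ `max_gap_um` (default 0),
greedy in ascending gap with ties broken by smaller pre id then post id:
deterministic, and no ribbon is counted against two patches. Unmatched
puncta are reported as orphans. At gap 0 with locally disjoint contact
geometry, greedy matching attains maximum cardinality (checked against a
Hopcroft–Karp oracle in the tests). `max_gap_um` is exposed for
sensitivity analyses.

## 4. Cell frames, normalized position, side

Cells enter as label masks (drawn externally for real data; generated for
synthetic data). The top→bottom axis **t** is the principal axis of the
mask's voxel cloud; the apex→base axis **a** is the row-direction hint
(direction through neighbouring cell centroids) orthogonalised against
**t**; the modiolar→pillar axis **m** completes the orthonormal triad.
Signs cannot be inferred from a bare mask, so two hints orient the frame:
a basal direction (which end is synapse-dense) and a modiolar direction
(`modiolar_direction`, required for real stacks, generator metadata for
synthetic ones). Extents are mask spans along the axes; the origin sits
at the apex/modiolar/top corner so frame coordinates run 0→1.

Pair centres (volume-weighted mean of the pre and post centroids by
default; pre-only/post-only selectable) are normalized by the extents and
clamped to [0, 1] (clamping is logged). Side: modiolar iff u_mp < 0.5;
exactly 0.5 → pillar, a fixed, documented tie-break on a
probability-zero event. Pairs are assigned to the cell whose normalized
ellipsoidal metric they minimise; pairs farther than 1 µm outside every
cell are dropped and logged.

## 5. Volume normalization and correlation

Within one stack and one channel, each colocalized element's volume is
divided by the median volume of *colocalized* elements of that channel in
that stack (non-colocalized puncta neither contribute to the median nor
receive normalized volumes). The normalization cohort is the whole stack,
not the single cell — matching the motivation of removing per-stack
observer/threshold scale. Medians of even-length sets are the mean of the
central order statistics. By construction the per-stack per-channel
median of normalized volumes is 1 (asserted after every run), and the
normalization is invariant to any global rescaling of volumes within a
stack. Absolute volumes are exported for transparency but no cross-stack
absolute comparison is offered.

Pre/post volume association is summarised as Spearman's rho with
two-sided p, pooled and per age × location × side subgroup (≥ 3 pairs,
non-constant input required).

## 6. Cohort statistics

Synapses and cells within an animal are not independent samples, and
locations/sides within an animal form a repeated-measures design. The
statistics stage therefore consumes exactly one row per animal × location
× side — per-animal **means** of per-cell counts and per-animal
**medians** of normalized volumes (volumes are strongly right-skewed, so
the median is the appropriate central tendency) — and raises a
pseudoreplication error if finer-grained rows reach it.

The ANOVA is the classical mixed-design (split-plot) analysis, computed
from orthonormal within-subject contrasts: the between factor (age) is
tested against subjects-within-groups (for two groups this F is exactly
the squared two-sample t on per-animal means); each within term
(location, side, location×side and their interactions with age) is tested
against its own subject-interaction stratum. Under the generator's
compound-symmetric error structure these F tests are exact; null
calibration of the age effect is verified by simulation (type-I error
within [0.03, 0.07] at α = 0.05). A mixed-effects likelihood approach was
considered and rejected: the available implementation's Wald tests lack
small-sample degree-of-freedom corrections and are anti-conservative at
study-sized cohorts (6–8 animals per group). Degrees of freedom are
reported as produced by this decomposition; no attempt is made to match
any particular commercial package's conventions. Unequal group sizes are
handled with weighted grand means (complete within-subject data is
required; missing cells raise a design error listing them). Post-hoc
pairwise comparisons are Welch t-tests on per-animal values with
Bonferroni correction (Holm or none selectable).

## 7. The synthetic cochlea

The generator exists because the study's raw stacks are not deposited; it
produces ground-truth-annotated specimens on which every stage is
measurable.

**Geometry.** A row of ellipsoidal IHCs along x (apex→base), long axis
along y (top→bottom), modiolar→pillar along z, semi-axes 3.5 × 12 × 3.6
µm (z, y, x) with ±4 % per-cell jitter, pitch 8.4 µm. Masks are exact
voxelised ellipsoids; analytic frames accompany them.

**Counts.** Per cell and side, counts are Poisson around the profile
expectations, scaled by a per-animal lognormal frailty (log-sd 0.12,
mean 1) shared across that animal's locations and sides — the simplest
hierarchical model producing realistic animal-level variance and the
repeated-measures correlation the statistics stage relies on.

**Placement.** Synapse sites sit on the cell surface within the
basolateral band (u_tb ∈ [0.68, 0.93]) and the assigned side band
(u_mp ∈ [0.08, 0.44] modiolar, mirrored for pillar — margins keep planted
side labels unambiguous), with a hard-core minimum separation of 1.2 µm
between sites of one cell. The hard core is biologically motivated
(active zones do not overlap) and numerically important: pure Poisson
placement at ~20 synapses/cell merges a third of neighbouring puncta,
which no splitting heuristic reliably undoes. The presynaptic centre sits
0.20 µm inside the membrane, the postsynaptic centre 0.05 µm outside, so
true pairs always colocalize at gap 0.

**Volumes.** Lognormal per channel and side (log-sd 0.5, floor
0.03 µm³), medians 0.16/0.11 µm³ (pre, modiolar/pillar) and
0.30/0.21 µm³ (post) — a right-skewed law with the modiolar>pillar
gradient. The pre/post rank correlation (target Spearman 0.6) is induced
by a Gaussian copula with normal-scores correlation 2·sin(π·ρ_s/6).

**Rendering.** Each element becomes a solid ellipsoidal kernel at
constant amplitude (250 photons over background 2), blurred with an
anisotropic Gaussian PSF of post-deconvolution quality (σ = 0.13 µm
axial, 0.05 µm lateral — the generator emulates deconvolved stacks, per
the acquisition workflow), then Poisson photon noise. Kernels are
pre-shrunk *laterally* by 1.7 σ so the blurred, thresholded extent tracks
the true volume (1.7 σ is where a blurred edge falls to the default
detection floor); the axial grid (0.3 µm) is too coarse to shrink without
destroying the monotonicity of measured volume in true volume, so
measured volumes carry a modest (~1.4×), rank-preserving inflation.
Sub-voxel kernels are clamped to one voxel with a warning. Lipofuscin
distractors (aged profiles: rate 0.5/cell, lognormal volumes median
5 µm³, floor 2 µm³ — above the synaptic range) are rendered into all
three channels at 70 % amplitude; quiet-aged tissue carries
autofluorescent age pigment that quenching only attenuates, young tissue
is modelled clean.

**Determinism.** One master seed; per-group, per-animal and per-stack
substreams are spawned with `numpy.random.SeedSequence` (collision-safe
and reproducible stack-by-stack). Identical seed + profile ⇒ bit-identical
truth tables and stacks.

**Packaged profiles.** 16 kHz per-side expectations are the printed group
means (young 13.7/8.3; aged 7.7/9.4). The apical locations' per-side
means are not printed anywhere; the packaged values (young 1 kHz 22.6,
2 kHz 20.2; aged 19.7, 14.8, split evenly across sides where no side
effect was reported) were fixed once so the three-location grand means
equal the published 21.6 (young) and 17.2 (aged) synapses/IHC in
expectation, with a mild, non-significant-sized reduction at 1 kHz and a
larger one at 2 kHz.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: spectral crosstalk, refractive aberrations,
deconvolution artifacts, staining heterogeneity, irregular cell shapes,
partial cells at stack borders, and observer variability in delineation.
Recovery results on synthetic cohorts validate the *pipeline logic*
(detection, pairing, classification, aggregation, inference), not the
biological imaging chain.

## 8. Problem sizes

Simulation-based checks use desk-scale cohorts chosen to keep Monte-Carlo
error small relative to the quantities recovered: the acceptance script
simulates 12 animals × 3 locations × 8 cells per age group for the grand
means and 12 animals × 12 cells for the 16 kHz per-side means; the test
suite uses 8 × 10 at 16 kHz and 6 × 8 per location for grand means, with
recovery asserted within 2 Monte-Carlo standard errors estimated from the
per-animal spread. Statistical calibration (1000 null replicates, 200
power replicates) runs on the count model directly — the battery consumes
only per-animal tables, so rendering images would add nothing but time.

## 9. Known limitations

- Measured volumes are thresholded voxel counts: sub-resolution elements
  saturate at the PSF floor, and the ~1.4× inflation noted above cancels
  in normalized volumes but not in raw exports.
- The split-plot F tests assume sphericity (exact under the generator's
  compound symmetry); no Greenhouse–Geisser correction is applied.
- The greedy matcher guarantees maximum cardinality only at gap 0 with
  locally sparse contacts; at large `max_gap_um` it is a heuristic.
- Frames derive from mask PCA; strongly bent or truncated cells would
  need externally supplied frames.
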
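# Methods

This note documents the models behind `blastospat`, the parameter choices
that matter, what the synthetic generator does and does not emulate, and the
numerical conventions a user relying on the outputs should know.

## The synthetic embryo

The generator is the package's source of ground truth: every analysis stage
is validated by recovering quantities the generator planted.

**Geometry.** A mounted embryo surface (dorsal or ventral view) is modelled
as the upper cap of an ellipsoid seen in the image plane — no cartographic
unrolling, because the analyses operate on raw image-plane coordinates of
mounted views. Nuclei sit on the cap's height field: shallow at the field
centre, receding toward the borders, with ~0.35 μm placement jitter. Lateral
calibration is fixed at 0.5205 μm/px and the axial step at 1.5 μm (the two
printed pixel↔μm conversions of the protocol disagree in the fourth digit;
0.5205 matches the 100 × 100 px ↔ 52.05 μm conversion exactly and is used
everywhere).

**Nuclear placement.** Nuclei follow an inhomogeneous hard-core point
process: dart throwing against the preset's density field
`d(u, v) = (base + bump·exp(−(v/w)²) + stripe(u)) · (1 − 0.3(2u−1)²)`
in nuclei per 100 μm², where `u` is normalized A/P position and `v` the D/V
arc position from the midline of the view. The expected count is the
intensity integral; a draw that cannot be placed within 10× as many
proposals raises a generation error naming the preset. Two exclusion rules
apply: a 2.5 μm hard-core floor (approximate internuclear spacing, a
documented constant) and non-interpenetration of the rendered nuclei —
centres stay at least `0.95·(r_i + r_j)` apart, since nuclei are solid
bodies. Without the second rule nuclei of radius ~2.1 μm could overlap by
~1.7 μm, which no segmentation (and no embryo) permits.

**Density magnitudes.** Absolute per-region counts are not tabulated
anywhere usable, so preset densities are calibrated only qualitatively. The
chosen range (≈1.5–3.4 per 100 μm² from poles to the wild-type late dorsal
midline) is anchored to the heatmap display stretch of 0.002–0.0105 points
per px², which converts to 0.7–3.9 nuclei per 100 μm² at 0.5205 μm/px. Only
orderings are contractual: midline > poles for the late wild-type dorsal
field, flat fields for `gd7`, weakened dorsal maxima for `fra`/`gukh`.

**Nuclear rendering.** Each nucleus is a 3D Gaussian blob with lateral
σ = radius/2 (radius ~2.1 ± 0.12 μm) and axial σ elongated 2.5-fold:
blastoderm nuclei at cellularization are columnar, roughly 2.5× longer along
the apical–basal axis than wide, and the published filter sizes (a 5-voxel
median at a 1.5 μm z-step) presume that shape — isotropic blobs are thinner
than the median window and get erased. Photometry is 12-bit-scaled
(background 60, nuclear amplitude 1100 ± 80 counts) with Poisson shot noise
plus Gaussian read noise (SD 15); the post-segmentation object-intensity
floor of 40–100 only makes sense against a 12-bit scale. All rendering
constants are module-level and overridable.

**Membranes.** Apical cell fields are Voronoi tessellations of
variable-radius hard-core seeds: per-cell target areas are drawn lognormal
(CV 0.22) around the preset's `(side, stage)` mean, seeds are dart-thrown
with spacing proportional to the local target radius (packing factor 0.67,
safely below the random-sequential-adsorption jamming limit), and one Lloyd
iteration makes the tessellation near-centroidal. The realized area CV
(~0.15) is therefore somewhat below the nominal lognormal CV — tessellation
and relaxation regularize the scatter; only the mean area is contractual
(recovered within 3%). The field mean equals the target by construction
(N = field area / target; Voronoi cells partition the field). Edges are
drawn as anti-aliased ridges, blurred (σ 0.8 px) and carried to the same
Poisson + read-noise model. Junctional gaps emulate *fra*-like adherens
defects: each edge pixel is dropped with the preset's `membrane_gap_prob`
and drops are dilated into contiguous gaps, which is what produces fused,
jagged cells and the mutant circularity decrease.

Stage scaling: ventral areas are stage-constant; dorsal areas constrict
from the ventral-sized early value to the preset's late value through their
geometric mean at mid-stage. The wild-type late anchors are 40 μm² ventral
and 26.4 μm² dorsal (ratio 0.66, i.e. dorsal 34% smaller); `fra` and `gukh`
dorsal areas are 1.26× and 1.40× the wild-type dorsal value.

**Cross-sections.** Nuclei tile an annulus (radius 60 μm) at evenly spaced
arc positions with 15% spacing jitter, rendered as flat-intensity disks so
that a fixed-area ROI well inside a nucleus measures its intensity exactly.
Each nuclear intensity is the preset's DL or pMAD Gaussian gradient
evaluated at the nucleus' arc position, times `1 + 0.05·ε` by default.

**Expression time courses.** Planted genes are the reference receptor
profile times a lognormal positive scale plus relative Gaussian noise;
decoys are independent smooth random profiles (5 interpolated knots).
Because the similarity metric correlates log(1+x) profiles, a noiseless
planted gene scores ≈100 but not exactly 100 (log1p is not exactly
scale-equivariant); the generator uses expression values ≫ 1 so the
deviation stays below 0.5 points. Annotations (keyword sets, D/V-asymmetry
flags) are assigned from the truth labels, with a 15% rate of
relevant-looking keywords among decoys so the filters do real work.

**Seeds.** A single integer seed expands to per-component streams via
`np.random.default_rng([seed, stream_id])` with documented stream ids;
identical (preset, seed) pairs are bit-identical. The pipeline derives
per-embryo seeds by hashing `(seed, genotype, side, index)` and reducing
below 2³¹.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: PSF anisotropy and depth-dependent attenuation,
mitotic or damaged nuclei, yolk autofluorescence, membrane vesicles and
sub-apical signal, drift/bleaching in time-lapse, and segmentation-relevant
staining variability between embryos. Recovery results on synthetic data
bound the algorithmic error, not the biological measurement error.

## Nuclear segmentation

Preprocessing follows the published chain, in order: slice subsetting, 3D
median (cubic neighbourhood, radius 2 voxels), 3D Gaussian (σ 1 voxel),
unsharp mask `U = (I − w·G_r(I))/(1 − w)` clipped to the input range
(dorsal r = 1.4, w = 0.7; ventral 1.2, 0.6), an optional 3D maximum filter
(radius 1, dorsal only — it genuinely helps dense fields by re-inflating
median-thinned nuclei), and a final per-slice 3×3 sharpen convolution.
Radii are interpreted per-axis in voxels with no z-anisotropy compensation,
matching how the original settings were applied.

Segmentation samples 100 evenly spaced thresholds between a 2-class
(k-means) intensity split and the stack maximum — the "k-means" threshold
method is mapped to seeding the threshold range from that split, an
approximation documented here — and builds the component tree of
26-connected components across thresholds. Object selection: for each
object, take the largest component with volume in `[volume_min,
volume_max]` (15–190 μm³ dorsal, 15–200 μm³ ventral) *that still contains a
single object*. A component formed by the merge of two components that each
already support a valid object is never selectable. The more literal rule —
maximize volume within bounds along every root-to-leaf branch regardless of
merges — collapses touching nuclei into one record whenever their merged
component stays under the volume ceiling; at blastoderm densities that
empirically caps recall near 70–75%, far outside the 90–100% validation
band the protocol itself reports, so the merge-excluded rule (which is also
how spot-tracking segmenters behave) is the implemented algorithm. Ties
between equal-volume candidates resolve to the lower threshold (larger
support, stabler centroids) automatically, since selection takes the first
in-bounds component walking from the root.

Records carry intensity-weighted centroids in μm (voxel indices 0-based,
centres at `(index + 0.5)·voxel size`), volumes, mean intensities and the
segmented voxel set; a post-filter mean-intensity floor (default 40)
removes background-level objects. Marker redirection re-measures the same
voxel sets in a second channel. Validation matches detections to truth
one-to-one by Hungarian assignment on centroid distance with pairs beyond
the tolerance (default 2 μm) unmatched.

## Density mapping and hot spots

Registration fits a least-squares similarity transform (Umeyama closed
form; scale, rotation, translation — no shear, no reflection) over the four
landmarks (poles and lateral-most points). Reflections and collinear
landmark sets raise; the RMS residual is reported since four points
over-determine the transform.

Density rasters use the GIS-standard quartic kernel
`K(d) = 3/(πR²)·(1 − (d/R)²)²` summed over points at cell centres, masked
to the dissolved union of point buffers (aggregation distance 30 raster
units, treated as a tool-internal config value). The default bandwidth is
the rule-of-thumb `0.9·min(SD, IQR/1.34)·n^(−1/5)` of the point spread —
the source protocol never states its bandwidth, so it is explicit
configuration here. Kernel mass is conserved to within 1% provided the
bandwidth spans several raster cells. The display stretch (0.002–0.0105)
and contour interval (0.0005) are honored as rendering configuration, not
physics. Averaging requires identical grids and intersects masks.

Gi* uses binary fixed-distance-band weights with mandatory self-inclusion,
the population SD of counts, and the standard 1995 variance term; all-equal
counts yield z = 0 with a warning. Grid edge 20 and bands 50 (dorsal) / 120
(ventral) are the documented defaults, distances measured
centroid-to-centroid in raster units. Confidence classes (90/95/99%,
two-sided normal) are reported raw; a Benjamini–Hochberg switch exists but
defaults off, matching the tool behaviour the classes come from. Under
complete spatial randomness about 5–8% of cells reach the 95% tier — the
classes are descriptive, not family-wise error-controlled.

## ROI statistics

The midline ROI is 156.14 × 52.04 μm (300 × 100 px) centred on the
projected surface centroid; inclusion is half-open on the maximum edges so
disjoint tilings partition points exactly. Both rank tests report two-tailed
`p = 2·min(P(T ≤ t), P(T ≥ t))`, capped at 1 (conventions differ; this one
is symmetric and conservative). Mann–Whitney: exact null distribution by
rank-sum dynamic programming when the pooled sample is tie-free (feasible
far beyond n₁ = n₂ = 20), by direct enumeration with midranks when ties are
present and `C(n₁+n₂, n₁) ≤ 10⁶`, else the tie- and continuity-corrected
normal approximation. Wilcoxon: zero differences dropped, exact distribution
by DP over doubled midranks for n ≤ 20, else the corrected approximation.

## Morphometry

Membrane images are segmented by watershed on the smoothed (σ 1 px),
morphologically closed (radius 2 px — seals small junctional gaps) ridge
image, seeded from its regional minima; border-touching basins are
discarded. Basin boundaries become sub-pixel polygons via marching squares
at the 0.5 level with a 5-point circular moving average to suppress
staircase bias — without smoothing, pixelated perimeters overestimate by up
to ~8% and circularity of a true circle reads ~0.85; with it, a discretized
circle measures 1.00 ± 0.02. Area is the shoelace area of the smoothed
polygon; circularity is 4πA/P². The red/green circularity split used for
display defaults to 0.8 (unstated in the source; configurable). Time-lapse
tracking matches cells frame-to-frame by nearest centroid within a
tolerance (default 3 μm) — adequate for slowly constricting fields, not for
rearranging tissue. Group comparisons report `100·(1 − mean_a/mean_b)`;
negative values read as "percent larger".

## Gradient quantification

Profiles take the n nuclei nearest the relevant midline (defaults: 30
ventral-most for DL with ~10 μm² ROIs, 18 dorsal-most for pMAD with
10.4 μm² ROIs), ordered by arc position, measuring the mean in a fixed-area
disk inside each nucleus. Gaussian fits use Levenberg–Marquardt on
`a + b·exp(−(x−c)²/2σ²)` initialized from moments (baseline = min,
amplitude = max − min, centre = argmax, σ = FWHM/2.355); non-convergence
returns the initialization flagged unconverged. Broad gradients (σ ≳ 0.5 in
arc units) need the full arc in view to separate amplitude from baseline —
fitting only the peak region biases amplitude low. Normalization maps
profiles through the *fitted* baseline and amplitude, `(I − a)/b`, so a
single outlier nucleus cannot set the scale; the upstream normalization
recipe this substitutes for is not restated in the source, and min–max on
fitted parameters is the documented contract. It is idempotent and
invariant under affine intensity maps. E-CAD-style comparisons use ordinary
least squares; transects interpolate bilinearly along a segment.

## Expression screen

Similarity defaults to 100 × Pearson correlation of log(1+x) profiles. The
printed similarity percentages the screen narrative quotes (93.66, 89.84)
come from an undocumented metric; Pearson on log profiles is chosen because
those values live in the high-correlation regime, and the metric is
pluggable (`cosine`, normalized `euclidean`) and recorded in output
metadata. Ranking is descending with stable ties broken by gene id;
constant profiles are unscoreable and skipped. Keyword and D/V-asymmetry
filters are input annotations (the original D/V lookup against an external
image database is out of scope); filtering never changes scores, so
score-then-filter equals filter-then-score for retained genes.

## Packing model

A regular hexagon losing the fraction s of its area scales all linear
dimensions by √(1−s); one constricting row therefore displaces
`f_v = 1 − √(1−s)` of an unshrunk (ventral) diameter, `f_d = f_v/√(1−s)` of
a shrunk (dorsal) one, and `round(1/f_v)` rows pull a full ventral
diameter. Which linear dimension is "the diameter" is immaterial under
uniform scaling. At s = 0.34 the closed form gives f_v = 0.1876 and
f_d = 0.2310 (the narrative rounds these to ~20% and ~24%) and 5 rows.
Rounding is to the nearest integer ("roughly"); a ceiling option exists.

## Problem sizes and runtime

Synthetic stacks default to 220 × 220 px × 12 slices (~115 × 115 × 18 μm,
250–310 nuclei), membrane fields to 260 × 260 px (450–700 cells), section
annuli to 40–60 nuclei, screens to 101 genes × 30 stages — sizes chosen so
each validation exercises realistic densities while a full test run and the
acceptance script each finish in about a minute on one CPU. At these sizes
the dorsal segmentation recall is 99–100% and ventral 99%+ (the residual
misses are field-border nuclei whose rendered bodies are clipped), and
end-to-end morphometry recovers the 34% dorsal/ventral and 26% fra/wild-type
area contrasts within ~1.5 percentage points.

## Known limitations

- The iterative-threshold segmenter assumes blob-like nuclei separable by
  intensity; densely fused chains beyond pairwise contacts, and nuclei dim
  enough to sit below the k-means split, are not recovered.
- The similarity registration cannot express the non-rigid deformation
  between embryos; residuals are logged but not modelled.
- Gi* confidence classes carry no multiplicity correction by default.
- The circularity measure inherits a small (≤2%) discretization bias that
  depends on cell size in pixels.
- The nearest-centroid tracker has no occlusion or division handling.
- All validation is against the synthetic model; see the generator section
  for the real-data effects it omits.
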
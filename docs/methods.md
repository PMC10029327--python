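# Methods

This note records the models, conventions and numerical choices behind
`sasmorph`, in the order the pipeline runs them. Axis order is `(z, y, x)`
with the nerve axis along z; all lengths are micrometres and voxels are
isotropic.

## Synthetic phantom

The phantom emulates the geometry of an optic-nerve segment inside its
subarachnoid sheath: a solid nerve cylinder (radius 34 µm by default), a
CSF annulus, and a dura shell (inner radius 64 µm, thickness 28 µm),
bridged by capsule-shaped trabeculae (cylinders with hemispherical caps,
endpoints sampled on the nerve and dura surfaces with angular and axial
jitter) and by thickened radial half-plane septa. Optional confounders
reproduce the nuisance signals the real chain must survive: additive
Gaussian noise, independent smooth (quadratic) per-tile background
fields, and thin bright filaments crossing the CSF that mimic
fixation-induced artifacts — deliberately thinner than the thinnest
trabecula so a scale-selective filter can separate them.

Every primitive has a closed-form signed distance, so solid volume and
lateral areas are recorded analytically before voxelization. Grayscale
values come from evaluating primitive membership at voxel centres, with
2× per-axis supersampling on voxels the surface cuts; this produces the
sub-voxel partial-volume ramps that the level-set volumetry exploits.
Intensity polarity is solid-high / CSF-low, with an inversion flag.

Default grid 96 × 200 × 200 at 1 µm voxels. The defaults were chosen so
that (i) the CSF annulus is the largest interior component of the
segmentation complement, (ii) the dura shell survives the macro opening
(shell thickness > 2 × opening radius), and (iii) trabeculae of 4–8 µm
radius are resolvable (≥ 2 voxels) and fit the annulus. Trabecular number
density is not a biologically calibrated quantity here; twelve trabeculae
give good test coverage without crowding.

What the phantom does **not** emulate: X-ray physics (ring artifacts,
beam hardening, detector noise models), anatomical curvature of the
nerve, the heterogeneous velum/pillar morphology of real specimens, or
specimen-scale fields of view. Passing phantom tests therefore
demonstrates correctness of the algorithms under controlled geometry, not
performance on specimen data.

The two-chamber mask (two spheres of 150 and 300 µm diameter joined by a
narrow channel, 5 µm voxels, centres snapped to voxel centres) is a
purpose-built fixture for the fluid-space census.

## Tile registration and stitching

Registration is translation-only, matching a tile-grid acquisition.
For a tile pair the overlap under the nominal shift is cropped, high-pass
filtered (subtraction of a Gaussian blur at σ = extent/8, suppressing the
lowest-frequency octave so background gradients cannot dominate), Hann
windowed, and phase-correlated. The integer peak is searched only within
± `search_halfwidth` (default 8) voxels of the nominal shift; sub-voxel
refinement is a separable 3-point parabolic fit per axis, clamped to
± 0.5 voxel. Ties between equal peaks break toward the smaller shift
magnitude, then lexicographically. Confidence is the normalized
correlation peak in [0, 1]. Overlaps under 10 voxels per axis or with
zero variance are rejected.

Global offsets solve the overdetermined linear system
`offset[b] − offset[a] = shift_ab` per axis by least squares, rows
optionally weighted by confidence, tile 0 pinned at the origin; a
disconnected adjacency graph is an error naming the unreachable tiles.
Note the solution is defined up to the pinned gauge: after a perturbed
measurement the per-tile error is best judged up to a common translation.

Stitching estimates one quadratic (10-term) background per tile by least
squares on subsampled overlap differences — in overlaps the structural
signal cancels, so tile differences observe background differences
exactly. The common volume-wide field is unidentifiable from differences;
the gauge is fixed by pinning tile 0 and re-centring coefficients on the
tile-ensemble mean, so estimated backgrounds are unbiased relative to
their average. Background-corrected tiles are blended with separable
cosine ramps sized to half the smallest overlap; fractional offsets are
honoured by trilinear resampling, and coarse tiles are trilinearly
upsampled to the fine grid before blending. Where one tile contributes,
the output is that tile minus its estimated background. Consequently the
stitched volume equals the source up to (a) noise and (b) one smooth
volume-wide field — which the enhancement stage removes anyway; seam
discontinuities are measured as the largest voxel-to-voxel jump of the
(stitched − source) difference.

## Enhancement

The filter bank lives in Fourier space: radial windows are Meyer-style
cos² crossfade bumps on log₂ radius (unit-spaced centres partition unity
on the annulus between the lowest and highest ring; the top ring extends
to the Nyquist corners), and angular windows are raised-cosine wedges
about axes placed by a deterministic golden-angle spiral on the
hemisphere, mirrored for conjugate symmetry, normalized to sum to one at
every frequency, and symmetrized across the Nyquist bins of even grids.
The wedge width equals the nearest-axis spacing, so each axis direction
is seen by exactly one wedge — a pure sinusoid along an axis at a ring
centre is an eigenfunction of its band. With all gains at one the bank
reproduces band-limited input to machine precision.

Defaults: 4 octaves × 11 directions per octave, gains 0 on the lowest
ring (background removal), 0.25 on the highest (filament-artifact
damping), 1 between — all config-exposed. The desk-scale pipeline uses 7
octaves so that the passband reaches low enough for the nerve trunk and
dura (tens of voxels across) to keep their interior signal and threshold
as solid bodies; which ring carries "background" is a function of the
field of view, not of the method.

Preprocessing: mean subtraction, optional global quadratic bias-field
detrend (default on), and reflect padding by 5% per axis to limit
periodic wraparound. The detrend exists because at desk scale a
volume-spanning background gradient and a nerve that fills a third of the
field of view overlap spectrally; no radial gain profile can cancel one
and keep the other. Block-wise filtering is available for volumes that do
not fit in memory; the block margin must be at least 2^(octaves+1) voxels
or the call fails rather than produce block seams — and even at the
minimum margin the reconstruction near block boundaries is approximate at
the few-percent level, so whole-volume filtering is preferred when
possible.

## Segmentation

A hard threshold (default: Otsu on the enhanced histogram) gives the raw
solid foreground; no smoothing is applied. Compartments follow with
26-connected foreground / 6-connected background conventions and
Euclidean-ball morphology realized through distance transforms (two EDT
passes per operation, so large radii cost the same as small ones):

1. enclosed cavities (background components not reaching the domain
   boundary) are filled;
2. the **macro anatomy** is a closing (default 2 voxels, consolidation)
   followed by an opening wide enough to erase trabecular-scale structure
   (pipeline default 1.25 × the largest expected trabecular radius). The
   **ON** is the macro component holding the largest inscribed ball — the
   nerve trunk is the thickest structure even when the dura shell has
   more voxels;
3. the **CSF** is the largest 26-connected component of the complement;
   optionally components touching the lateral (y, x) faces are excluded
   first, for fields of view that include the space outside the dura;
4. the **SAS microstructure** is the raw foreground inside the
   morphological closing of the CSF (default closing radius 3 × the
   largest expected trabecular radius), minus the CSF. The envelope takes
   precedence over the macro mask where the two overlap: the blunt
   opening spills onto trabecula attachment fillets, and those voxels
   belong to the microstructure. Digitization leaves a sparse envelope
   skin (a fraction of a percent of CSF voxels) on the concave dura wall
   classified as microstructure; tightening the envelope erosion removes
   it but costs more true trabecula voxels than it saves, so the skin is
   accepted and shows up only below the reporting precision.

`remove_microstructure` produces the counterfactual segmentation —
microstructure voxels merged into the CSF, ON untouched — conserving the
CSF + SAS voxel count exactly. Sector exclusion zeroes all masks inside
an angular sector about the nerve axis (principal second-moment axis of
the ON mask, reference direction config-supplied) and records the angle
for renormalization by 360/(360 − θ).

## Signed distance, volumetry, meshing

φ = (EDT to background) − ½ voxel on the foreground and the negated
mirror outside, in µm: the interface sits half a voxel between opposing
labels, a single foreground voxel has φ = +0.5 voxel. Distances are exact
Euclidean (no chamfer approximation) because the thickness definition
downstream needs Euclidean balls. φ is 1-Lipschitz over voxel pairs up to
a bounded sub-voxel excess of (2√2 − 1 − √3) ≈ 0.096 voxel at diagonal
interface crossings — the price of the half-voxel shift, verified tight
by exhaustive search.

Volume: Σ U_ε(φ)·h³ with U_ε the piecewise-linear ramp (0 below −ε, 1
above +ε), ε defaulting to one voxel — the minimal first-order-consistent
mollifier. On a digitized 20-voxel ball this is accurate to a few tenths
of a percent and the error at least halves when the voxel size halves.

Surface: marching cubes (Lewiner variant, topologically consistent
resolution of saddle ambiguities through the trilinear interpolant) on φ
at level 0, vertices linearly interpolated, in µm. A Gaussian of
σ = 0.7 voxel regularizes the voxel-quantization ripple of the discrete
EDT before meshing: being linear it leaves planar interfaces exact, while
on curved closed forms (spheres, trabecular-scale capsules) it removes a
5–10% ripple-induced area inflation, leaving ~1% accuracy. Triangles of
area ≤ 1e−12 µm² are dropped; single-sign fields yield an empty mesh with
a warning; meshes clipped by the domain boundary carry no closing caps,
so only true interface area is counted. Mirror images of a mask can mesh
slightly differently at ambiguous cells (sub-0.1% area effect) — an
inherent marching-cubes property.

## Thickness, separation, census

Local thickness at voxel v is the diameter of the largest inscribed ball
containing v. The inscribed-ball radius at centre c is EDT(c) − ½ voxel,
consistent with the interface convention above: a single voxel has
thickness one voxel, an axis-aligned slab of t voxels measures exactly t,
and every voxel satisfies thickness ≥ 2·EDT − 1. Thickness is evaluated
at voxel centres on the discrete mask; no sub-voxel interface refinement
is applied (the definition is ball-based). On oblique digitized cylinders
this measures the ball actually inscribed in the voxelized solid, which
sits up to ~1 voxel below the continuum diameter.

The fast path computes the squared EDT exactly (integer arithmetic from
the feature transform), prunes every candidate whose ball is contained in
a 26-neighbour's ball (containment √O + √A ≤ √B tested exactly in
integers), sorts survivors by radius, and paints their balls (numba JIT
with a numpy fallback; coverage tested exactly in integers as
16·O ≤ (4(A−O) − 1)²). Because pruning removes only redundant balls, the
result is *identical* — not approximately equal — to the brute-force
oracle that evaluates the definition over all centre/voxel pairs; the
oracle refuses grids above 64³.

Separation is thickness of the CSF mask. Density functions are
volume-weighted histograms (each voxel one voxel volume) normalized to
unit integral; the reporting default bin width is 2 µm. The
intertrabecular-space census thresholds the separation field (the
published threshold of 130 µm is the default), suppresses maxima
shallower than an h-maxima depth (default 2 voxels), and partitions by
watershed on the negated separation; each space reports the diameter of
its largest inscribed ball (not a volume-equivalent diameter — consistent
with the inscribed-ball semantics), its claimed CSF volume, and its seed
voxel. Halving the h-depth can only refine, never merge, spaces.

## Reporting

`compile_report` applies sector exclusion first, measures the CSF
volume/area on the measured and counterfactual segmentations, multiplies
areas and volumes by the renormalization factor, and derives the
amplification factor (measured / microstructure-free area, > 1 whenever
microstructure exists) and volume fraction ((V_nm − V_m)/V_nm). Interface
area is reported both in total and excluding the dura-facing boundary
(triangles whose nearest non-CSF voxel lies in the macro-minus-ON mask),
since published totals do not disambiguate the outer wall. Values are
kept at full precision and presented at two decimals with
half-away-from-zero rounding. The reference measurements for the two
published nerve segments ship as data for arithmetic consistency checks;
note their volume columns give fractions of 36.5% and 36.4% while the
accompanying prose rounds both to 35% — the computed value is emitted.

## Problem sizes

The validation suite runs phantoms of 96 × 200 × 200 voxels (pipeline and
morphometry), 64 × 144 × 144 (stitching), 24³–50³ (oracle and closed-form
checks), and the census fixture at 5 µm voxels; these sizes exercise
every code path at full algorithmic fidelity while keeping a complete run
in the minutes range on a single CPU. Scaling beyond memory is available
only through block-wise enhancement and chunked stores; a full
out-of-core pipeline is out of scope.

## Known limitations

- Registration is translation-only; rotations or deformations are not
  modelled.
- Background models (stitching and detrend) are quadratic; higher-order
  or non-polynomial bias fields leave residuals.
- The stitched volume is defined up to one volume-wide smooth field
  (inherent to difference-only observations).
- Block-wise enhancement is approximate near block boundaries even at the
  enforced minimum margin.
- The segmentation can over-collect a sparse one-voxel skin at concave
  walls into the microstructure (sub-percent effect, below reporting
  precision).
- Microstructure is not subclassified into trabeculae vs septa vs
  pillars.
- Thickness on oblique thin structures underestimates the continuum
  diameter by up to about one voxel (digitization, not algorithmic
  error).
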
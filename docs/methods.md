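# Methods

`cowtrack` extracts the topology of the circle of Willis (CoW) from
bright-lumen angiographic volumes (TOF-MRA-like contrast) as a labelled
graph: nine named bifurcations connected by seven artery segments —
left/right ACA-A1, the AcoA, left/right PCA-P1, and left/right PcoA —
each classified as normally developed or hypo-/aplastic (hypoplasia:
diameter < 1.0 mm; no distinction is made between hypo- and aplasia).
The central idea is an anatomical prior: a *complete* CoW is always
assumed, every segment is reconstructed as a minimal-cost path between
its two bifurcation landmarks on a 0.5 mm Cartesian grid, and a
downstream classifier decides which reconstructions correspond to
developed arteries.

## Orientation fields on the sphere

At a point x, local artery orientation is represented as a scalar field
on the unit sphere, discretized on an icosphere (default subdivision
level 3, 642 vertices; level is configurable and several validation
studies use level 2, 162 vertices, see "Problem sizes"). Image
intensities within radius r of x are projected onto the sphere: the
value at vertex direction v is the mean of trilinearly interpolated
intensities at k equidistant radii (j/k)·r, j = 1..k (default k = 8).
Patches at scales {1, 2, 5, 7, 10} mm are processed in parallel;
per-scale fields are z-scored across vertices, shifted non-negative, and
fused by a vertex-wise maximum, making the response approximately
scale-invariant: the scale that matches the artery calibre dominates.
Because the representation lives on the sphere, rotating the artery
rotates the response (checked for 90° grid rotations in the tests).

Two well-separated (≥ 60°) mesh-local maxima of the fused field give the
unsigned direction pair (d1, d2); the L1-normalized field's normalized
Shannon entropy

    H(f) = −(1/ln |V|) Σ_v f(v) ln f(v) ∈ [0, 1]

quantifies confidence. A zero response normalizes to the uniform
distribution, so "no signal" yields H = 1 exactly; a one-hot field gives
H = 0. Inside an artery lumen the field is sharply two-lobed (low H);
outside it is diffuse (H near 1).

Two numerical choices stabilize the deterministic matched-filter
estimator (both are provider parameters):

* **Spherical smoothing** — the fused field receives two one-ring
  Laplacian passes (vertex ← ½ vertex + ½ ring mean) before maxima
  extraction. The raw radial-mean response is noisy at the vertex scale;
  smoothing removes spurious local maxima the way a learned spherical
  regressor produces inherently smooth outputs. On phantoms this
  reduced mean centerline error by roughly a third.
* **Antipodality gate** — a point truly inside a tube sees maxima along
  ±axis, i.e. a near-antipodal pair. Points *outside* a vessel but near
  a bright artery instead produce a convergent pair (both maxima staring
  at the neighbouring lumen), which is spatially coherent and would
  otherwise fool the orientation-consensus cost. Pairs more than 45°
  from antipodal are therefore marked degenerate (no directions). This
  emulates the outside-lumen suppression a trained estimator learns from
  zero-response background sampling, and on phantoms it is what makes
  orientation-guided tracking of sub-voxel arteries clearly better than
  intensity-guided tracking.

The ground-truth-driven *oracle* provider (a test double with the same
output contract) emits Watson-like two-lobed fields
exp(κ((v·t)² − 1)) along the local centerline tangent t inside artery
tubes (κ = 20) and uniform fields elsewhere. Its notion of "inside" uses
a capture radius max(tube radius, 0.75 mm): without the floor, a 0.6 mm
hypoplastic artery on a 0.5 mm grid contains almost no grid node and the
provider would be mute exactly where the method matters. Overlapping
tubes add their lobes (a crossing yields a four-lobed field).

## Cost functions and path extraction

Four node costs on the grid, all designed to be low inside lumina:

* orientation consensus: C_orient(x) = ½(1 − mean cossim N(x)), the mean
  over the up-to-26 lattice neighbours y of
  ½ max(⟨d1ˣ,d1ʸ⟩+⟨d2ˣ,d2ʸ⟩, ⟨d1ˣ,d2ʸ⟩+⟨d2ˣ,d1ʸ⟩) — the pairing maximum
  because the direction pair is unordered. Degenerate nodes or
  neighbours contribute similarity 0; boundary nodes normalize by their
  actual neighbour count. C_orient ∈ [0, 1].
* entropy: C_entr(x) = H(f_x) ∈ [0, 1].
* image: C_img(x) = −I(x) with I the volume normalized to [0, 1] between
  its 1st and 99th intensity percentiles (trilinear at x). Since
  Dijkstra needs non-negative weights, the *tracking* form is
  1 − I(x); the constant shift preserves the pointwise ordering the
  method relies on, and each cost field records both raw and tracking
  values plus the offset.
* sum: the sum of the three.

Paths are Dijkstra shortest paths on the 26-connected grid with edge
weight w(x,y) = ½(c(x)+c(y))·‖y−x‖ + ε (trapezoidal node-cost
averaging × Euclidean step, anisotropy-aware; ε = 1e−6 mm keeps weights
strictly positive). Landmarks snap to the nearest grid node (midpoint
ties to the lower index). All seven template segments are extracted
unconditionally — aplastic arteries included — which is the complete-CoW
prior: absence is decided later by the classifier, not by the tracker.
Shortest paths are computed with scipy's Dijkstra; with the ε floor,
exact weight ties are vanishingly rare and the extraction is
deterministic for fixed inputs. No path smoothing or pruning is applied.

## Classification and graph reconstruction

Each path is summarized by 50 intensity samples at equidistant
arc-length positions in the normalized volume. A Random Forest (100
trees, maximum depth 2, balanced class weights, fixed seed) labels the
profile normal vs hypo-/aplastic; the score is the hypo-/aplastic vote
fraction, thresholded at 0.5 (ties go to hypo-/aplastic). The classified
edges plus the nine landmarks form the output graph, serialized as JSON
and GraphML.

The anterior and posterior CoW sections are then assigned Lippert-style
classes. The mapping is configuration-driven (pattern overrides are
supported); the default rules are: anterior — A all normal, B AcoA
hypo-/aplastic only, C any A1 hypo-/aplastic; posterior — P0 all normal,
P1 one PcoA, P2 both PcoAs, P3 any P1 with both PcoAs normal, P4 a P1
and a PcoA. These rules are total: every one of the 2⁷ label patterns
maps to exactly one (anterior, posterior) pair. Variants outside this
scheme (fetal-type PCA, duplications, azygos ACA) are out of scope.

## Landmarks

Bifurcation points are encoded as Gaussian heatmaps (σ = 5 voxels, in
voxel units per axis, peak value 1) and decoded by taking the global
argmax voxel (ties to the lowest linear index) followed by an
intensity-weighted centroid over a 5³ window. The window weights are
the intensities raised to (σ/0.707)² — equivalent to sharpening the blob
to an effective ~0.7-voxel Gaussian. A σ = 5 blob is nearly flat across
a 5³ window, so the plain centroid collapses onto the argmax voxel
(~0.3 voxel error); with sharpening the round-trip error is ~10⁻³
voxels, and off-lattice points are recovered well below 0.2 voxels.
Ensembles of heatmaps are decoded from their voxel-wise mean. Detection
itself is pluggable; the shipped detector returns ground-truth nodes
with configurable isotropic Gaussian jitter (≈1 mm emulates realistic
sub-2 mm median localization error). Preprocessing helpers (resampling
to (0.36, 0.36, 0.50) mm, 256×256×128 center crop, z-scoring) are pure
functions; bias-field correction is an external hook.

## The synthetic phantom

The generator is the package's ground-truthed study population. A
variant is drawn from a prevalence over (anterior, posterior) class
pairs (default: mostly complete circles, posterior variation dominated
by one or two underdeveloped PcoAs; an underdeveloped segment is
hypoplastic with probability 0.5, else aplastic). Geometry realizes the
variant on a nominal ~20 mm-wide node layout with Gaussian node jitter
(0.4 mm), quadratic-Bezier centerlines with per-segment bows (plus
0.5 mm control jitter) sampled ≤ 0.25 mm apart, and diameters drawn per
status (normal ranges per segment within [1.0, 3.0] mm, matching
reported CoW calibres: A1 1.6–2.4, AcoA and PcoA 1.0–1.8, P1
1.5–2.3 mm; hypoplastic 0.5–0.9 mm). Aplastic segments have no
centerline.

Crucially, the phantom also renders *context vessels*: the distal
continuations present in any real angiogram — the internal carotid
trunks (descending through the PcoA-ICA points), M1, A2 and P2
continuations, and the basilar trunk. Without them every CoW bifurcation
is a dead end and intensity-guided tracking is artificially immune to
its characteristic failure (leaking into neighbouring bright arteries);
with them, hypoplastic-PcoA tracking becomes genuinely hard in exactly
the way it is on clinical data. Context vessels are rendered and carry
orientation signal but are not CoW segments.

Rendering thresholds the distance to each centerline at the tube radius
(voxel centers within radius get the lumen peak), smooths with a
Gaussian (0.3 mm, a partial-volume surrogate), adds Gaussian noise, and
clips at zero. Defaults: background 20 ± 5, lumen peak 100, 96×96×64
voxels at 0.5 mm isotropic. The phantom reproduces the decisive
difficulty of the real problem — sub-voxel hypoplastic arteries fading
into noise — but not MR physics (flow-related signal variation, bias
fields, ghosting), nor rare variants (fetal PCA, duplications), so
passing phantom tests demonstrates correct mechanics and the *direction*
of the method's advantages, not clinical performance numbers.

## Problem sizes used in validation

Validation studies are sized for a single CPU: recovery experiments use
20 phantoms (default geometry/noise; both PcoAs hypoplastic when the
study targets them), mesh level 2, 4 radial samples, grid margin 2 mm —
about 28k grid nodes per case; the classifier study uses 130 phantom
graphs (30 train / 100 held-out, 910 paths) extracted with the oracle
provider, which isolates the classifier from orientation-estimation
error. Under these conditions the package achieves mean Fréchet
distance ≈ 0.6–0.7 mm on normal segments (threshold: under two grid
spacings), hypoplastic-PcoA correct-tracking rate above the image-cost
baseline, and held-out macro-F1 above 0.9 — each recomputed by the test
suite, not quoted from elsewhere.

## Known limitations

* The matched-filter provider is a deterministic surrogate with SIRE's
  output contract (two maxima + entropy), not a learned estimator; its
  absolute accuracy on clinical data is untested and a trained provider
  can be slotted in behind the same interface.
* Costs are node-wise only; no curvature or length regularization, so
  minimal paths cut corners inside wide lumina (~0.5 mm scale).
* The Lippert letter assignment beyond the default rules is
  configuration, not a claim about the original nomenclature.
* Landmark detection error is modelled as isotropic Gaussian jitter;
  real detectors fail anisotropically and with outliers.
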
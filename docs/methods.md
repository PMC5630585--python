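# Methods

## Model

The segmenter is an interactive, graph-based contour finder for hypoechoic
lesions in 2-D B-mode ultrasound. Its prior is *star-shapedness*: every ray
from the user's seed crosses the lesion boundary exactly once. The contour
is found as the minimum s-t cut of a radial-ray graph.

Gray values are sampled at K×N sub-pixel node positions — K rays spread
clockwise from "up" around the seed, N nodes per ray at radii
(i+1)·R/N for i = 0..N−1, template radius R — by bilinear interpolation
(out-of-image positions clamp to the border pixel). Infinite-capacity
intra-edges run outward→inward along each ray; infinite inter-edges
connect (k, i) to (k±1, max(0, i−Δr)) including the wrap-around pair, so
any finite cut is a per-ray prefix with circularly |c_k − c_{k±1}| ≤ Δr.
Terminal capacities derive from the deviation profile a_i = |g_i − m|:
node 0 → source with a_0, node N−1 → sink with a_{N−1}, interior node i
carries |a_i − a_{i−1}|, bound to the source for negative differences and
to the sink otherwise (zero differences tie to the sink with zero cost).

A useful identity: for a cut at prefix index c the severed terminal
capacity telescopes to a_c − a_0 plus a per-ray constant, so the global
optimum is the Δr-smooth star contour minimizing Σ_k a(c_k) — the contour
settles where the sampled profiles cross the reference gray m. Two
consequences shape the design:

1. **Reference gray m.** If m is estimated from a small window deep inside
   a homogeneous lesion, a ≈ |noise| everywhere inside and the cut
   position inside the lesion is decided by noise. The default therefore
   estimates m as the mean over all template nodes (`avg_mode="template"`):
   the template covers lesion and surrounding tissue in roughly fixed
   proportion at any lesion scale, so m lands between the two gray levels
   and the a-profiles have a genuine minimum at the boundary crossing. The
   square-window estimator (`avg_mode="window"`, side `avg_window`,
   default 9 px, odd) is retained; it reproduces the same cut on
   noise-free images and is the natural choice when the seed is
   deliberately placed near the transition zone.
2. **Tie-breaking.** On a noise-free step profile every cut strictly
   inside the homogeneous lesion costs zero; only the outermost of these
   lies on the boundary. The solver therefore returns the *maximal source
   set* — the outermost co-optimal contour — computed exactly as the
   complement of the nodes that can reach the sink in the residual
   network. This also fixes the degenerate all-uniform image: the contour
   expands to the template radius (flow 0), a documented no-lesion output.

Max flow is computed with `scipy.sparse.csgraph.maximum_flow`. Float
capacities are fixed-point scaled (scale ≤ 2^20, chosen so the scaled
capacity total stays below 2^29, leaving headroom under the backend's
int32 arithmetic); the "infinite" capacity is the scaled total plus one,
so infinite edges can never be saturated. The reported flow value is
re-accumulated from the unscaled weights of the severed terminal edges. An
independent dynamic-programming oracle (cycle over rays, enumerating the
first ray's index) verifies exact optimality on small instances in the
test suite.

Helper seeds map to their nearest (ray, index) node; all nodes inward of
the helper gain an infinite source edge, all nodes outward an infinite
sink edge, pinning c_k exactly (two helpers on one ray: last wins, with a
warning). The contour vertex on each ray sits at the radial midpoint
between the last foreground and first background node (±half a node
spacing of quantization); at c_k = N−1 it sits at R. Masks are rasterized
with a pixel-center-inside test (half-open boundary rule via a +1e-9
nudge, shapely point-in-polygon).

## Parameters

| parameter | default | meaning |
|---|---|---|
| K (`n_rays`) | 60 | angular resolution; 6° between vertices |
| N (`n_nodes`) | 40 | radial resolution; quantization ±R/(2N) |
| R (`max_radius`) | min(border distance, 0.45·min(H,W)) | template radius, px |
| Δr (`delta_r`) | 2 | max cut-index jump between adjacent rays |
| `avg_mode` | template | reference-gray estimator (see above) |
| `avg_window` | 9 px | window side for `avg_mode="window"` |

Δr = 2 is the fixed smoothness used throughout; larger values allow more
irregular contours, Δr = 0 forces a circle-like constant-index cut.

## Metrics

DSC is computed on masks in percent (both-empty defined as 100). The
Hausdorff distance is the symmetric max-min Euclidean distance over all
foreground pixel centers — identical to the boundary-based value for solid
masks and simpler to specify. Caliper diameters treat pixels as unit
squares (+1 px on extreme center distances, so a single pixel has
a = b = one pixel): *a* is the maximal center distance (via the convex
hull), *b* the longest foreground chord along the direction perpendicular
to *a* (a projection-width variant is available via `projection_b=True`).
The ICC is the two-way random, absolute-agreement, single-measure form
ICC(2,1), the standard choice for inter-operator agreement; the variant is
printed in every report. Median CIs use the percentile bootstrap
(2000 resamples by default, seeded).

## Synthetic phantoms

Each phantom is a star-shaped hypoechoic lesion in speckled tissue.
Echogenicity is 1.0 (background), `halo_gain` in an optional echo-poor rim
of `halo_width` px, `lesion_gain` inside the boundary
r(θ) = r₀·(1 + Σ A sin(fθ + φ)), f ∈ 2..6, A ≤ 0.25. Speckle is L-look
intensity speckle: per look an i.i.d. circular complex Gaussian field is
blurred coherently by a Gaussian PSF (`psf_sigma`, px; periodic boundaries
keep the field exactly stationary) and detected; the L averaged
intensities have coefficient of variation exactly 1/√L per pixel. The
intensity map is multiplied by the echogenicity, log-compressed
(log(1+50·I)) and mapped linearly to 8-bit gray. Everything is
deterministic given `rng_seed`.

The 105-case suite emulates the clinical material the method targets:
maximal diameters are drawn by piecewise log-linear interpolation through
the quantile anchors 6 / 14 / 20 / 27 / 115 mm (min / Q1 / median / Q3 /
max of the clinical size distribution), and the per-case zoom maps
diameters to 30–250 px on screen (spacing = mm diameter / px span), as a
sonographer would zoom. Contrast and noise are the open calibration:
`lesion_gain` ~ U(0.10, 0.35) models *clearly visible* hypoechoic
metastases after log compression, and `speckle_looks` ~ U{16..32} models a
displayed clinical image after spatial/frequency compounding and
persistence rather than raw single-frame speckle. 30 % of cases carry an
echo-poor halo (`halo_gain` ~ U(0.55, 0.8), width 2–6 px); the halo is
*not* part of the ground truth by default (`include_halo_in_truth=True`
gives the wider reading). These choices were fixed once, on the grounds
above.

What the phantoms do not model: attenuation, shadowing and enhancement
artifacts, anisotropic and depth-dependent PSF, neighboring anatomy
(vessels, diaphragm), non-star-shaped lesions, and operator variability in
seed placement. Passing the synthetic evaluation therefore demonstrates
the correctness and internal robustness of the implementation under its
own model class, not clinical accuracy.

## Evaluation harness

`evaluate_suite` segments each phantom with the seed at the truth-mask
centroid and a surrogate of the examiner's refinement loop: up to `k_max`
(default 4) helper seeds are placed on the true boundary at the ray angle
where the current contour's radial error is largest, re-solving after
each. A case counts as "satisfied" at DSC ≥ 70 %. On the packaged suite
(master seed 105) the raw single-click cut already reaches median DSC
≈ 92 % and is fully satisfactory on small and medium lesions; failures
concentrate on the largest lesions, where N = 40 nodes leave the radial
sampling coarser than the speckle grain so spurious gray matches inside
the lesion compete with the boundary — precisely the situation the helper
workflow repairs (all cases ≥ 86 % DSC with ≤ 4 helpers). The harness
reports per-case scores, medians with bootstrap CIs, diameter differences
in mm and the satisfied rate; `scripts/acceptance.py` wraps the default
105-case run (about half a minute on one CPU).

## Numerical and degenerate-input conventions

- Capacities are exact for integer gray values; fixed-point quantization
  error for interpolated values is below 2^-20 per edge.
- Seed on a border pixel is allowed; the derived template radius then
  falls back to N px (one node per pixel) — pass `max_radius` explicitly
  for control.
- Empty masks: DSC(∅,∅) = 100 %, Hausdorff and diameters raise.
- A contour thinner than one pixel rasterizes to an empty mask; the
  segmentation then reports the polygon extent as both diameters.
- All randomness flows from explicit seeds; identical inputs give
  bit-identical results everywhere (solver, phantoms, bootstrap).

## Known limitations

- The objective depends on a single global reference gray; strongly
  inhomogeneous lesions (necrotic cores, septations) violate its
  assumptions and need helpers.
- Thick echo-poor halos are ambiguous by construction: the cut may follow
  the halo's outer rim while the ground truth stops at the lesion proper,
  mirroring the disagreement between human readers on such cases.
- Metrics are 2-D; no volumetric extension is provided.
- The helper-placement policy of the harness uses the ground-truth
  boundary and is a surrogate for human refinement, not a claim about
  examiner behavior.
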
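# Methods

## Problem and algorithm

The package segments 2-D grayscale images into `c` fuzzy clusters and targets
the regime where a small, bright, compact structure (a tumor in a FLAIR-like
slice) must survive impulse noise. The driver `ifcm_ms` iterates, per pass:

1. adaptive scales `D`, `G` per pixel (mean absolute deviation over clusters
   of the spatial distances and of the squared gray gaps);
2. similarity `Sim = exp(-dis²/D) · exp(-((Δg)/G)²)` between every pixel and
   every cluster, where `dis` is the distance to the cluster's
   membership-weighted spatial centroid;
3. aggregate `S_ik` (identity by default; optionally a membership-weighted
   3×3 neighborhood mean);
4. membership update `u_ik ∝ S_ik^{2/(m-1)}`, then gray and spatial centers
   as plain `u`-weighted means;
5. hesitation `π` from a Sugeno generator and renormalized `u' = u + π`;
6. membership transfer: per cluster, guided-filter the current map using the
   median-filtered previous map as guidance; clip and renormalize;
7. stop when `max|U_new − U_old| ≤ η`.

The classical FCM baseline (`fcm`) is the standard intensity-only
alternation with powered weights and hard assignment at zero distance.

## Assumptions

- Single-channel 2-D images whose classes are separable mainly by intensity;
  the spatial similarity term assumes clusters are reasonably compact, which
  holds for lesions but only loosely for background.
- Impulse noise is sparse (a few percent). The transfer filter removes
  isolated membership outliers; structured artifacts (bias fields, streaks)
  are out of scope.
- Tumor-vs-rest evaluation assumes the tumor is the brightest tissue class.

## Numerical design choices

**Unit normalization.** Intensities are divided by the representable maximum
and coordinates by the image diagonal before the similarity stage. The
adaptive scales make both exponents scale-dependent: on a 0–255 intensity
scale the gray factor is numerically inert (G is a deviation of squared gaps,
~10⁴) while raw pixel distances make the spatial exponent dominate every
assignment. On the unit scale the two factors are commensurate, which is the
behaviour the similarity is meant to have. Reported centers are mapped back
to the original scales.

**Adaptive scales as mean absolute deviations.** The scales are defined from
centered deviations; read literally, averaging centered values gives
identically zero, so the package uses the mean *absolute* deviation — the
smallest repair that still reflects the spread of the per-cluster distances
and gray gaps. Degenerate cases (all clusters equidistant and equal-gray) are
floored at `similarity.scale_floor` (default 1e-12).

**Log-domain memberships.** `u ∝ S^{2/(m-1)}` is computed from `log Sim`
with a per-pixel shift, so strongly contrasted similarities (exponents of
hundreds during early iterations, when centroids nearly coincide) cannot
underflow the normalization. Inside the monitored objective, `S` is floored
at 1e-150 to keep `J` finite.

**Initialization.** The membership stack is initialized as seeded per-pixel
normalized uniforms; it seeds the first transfer guidance. Initial centers,
however, come from a hard nearest-seed assignment of each pixel to `c` gray
levels spread evenly over the observed intensity range. Deriving the first
centers from the random stack instead places every center at the image mean
— a symmetric configuration from which the exponential-similarity update
reliably collapses clusters (duplicate background centers, tumor merged with
tissue, measured over seeds); and a *soft* first assignment pulls all
centers toward the global mean, losing small bright bands on noise-free
images. The hard spread bootstrap gives every intensity band a center to
claim from the first iteration and keeps the run deterministic per seed.

**Renormalized intuitionistic memberships.** `u' = u + π` cannot satisfy the
sum-to-one constraint unless `π = 0`, so the stack is renormalized per pixel
after the hesitation is added. With a Sugeno generator `u + π` is monotone in
`u`, so this step never reorders a pixel's cluster preferences on its own.
Hesitation is recomputed from the current memberships each iteration. Yager
exponents outside (0, 1) are rejected at construction: they give `π ≤ 0`,
which is not a hesitation. Default generator: Sugeno, λ = 2.

**Transfer defaults and edge handling.** Guided filter radius 3, ε = 0.01 on
the [0, 1] membership scale, no subsampling (`s = 1`; the fast path is for
large images), median radius 1; replicate padding for both filters.
Constant-guide windows with ε = 0 take `a = 0` (the 0/0 guard). Pixels whose
clipped post-filter sum collapses to zero are reset to uniform membership
and logged.

**Convergence and ties.** The stopping metric is the max-abs entrywise
difference of consecutive post-transfer stacks against `η = 1e-5`, capped at
100 iterations (the transfer step keeps injecting small changes, so full
IFCM-MS typically runs to the cap with deltas around 1e-4; results are
returned with `converged=False` rather than raising). Final labels take the
per-pixel argmax with the lowest cluster index winning ties. Constant images
are rejected up front. Center updates use plain (unpowered) weights, with
`center_weights_powered` switching to the classical `u^m` form.

## Ablation switches

`use_similarity=False` replaces `Sim` by the pure intensity kernel
`exp(-(g-v_i)²/G)` (with adaptive or `fixed_gray_scale` G);
`use_transfer=False` skips step 6; `use_ifs=False` skips step 5.
`ablation_configs` enumerates the ladder: plain kernel → +IFS → +transfer →
+similarity. With all switches off and a tight fixed gray scale, the loop's
fixed points coincide with classical FCM's on well-separated two-value
images.

## The phantom generator

`make_phantom` renders a piecewise-constant scene — background 10, brain
ellipse 90, tissue blob 140, one small bright tumor blob 220 (≥ 9 px), the
defaults at 128×128 with within-class Gaussian sd 4 — and returns the exact
generating partition as ground truth. `salt_and_pepper` corrupts an *exact*
`round(p·n)` count of distinct pixels to 0 or the dtype maximum with equal
probability, so noise grids are reproducible per seed rather than
Bernoulli-approximate; the evaluation grid is 0, 0.005, 0.01, 0.02. The
phantom emulates the piecewise intensity structure and impulse corruption of
the target images but none of the real-data complications (bias fields,
partial-volume mixing, Rician noise, anatomical texture), so passing tests
demonstrate the mechanism — impulse robustness and small-structure retention
— not clinical performance.

## What the synthetic study shows

On the default phantom, classical FCM's random initialization sometimes
merges the tumor band with tissue and its pixel-wise assignment mislabels
every salt pixel, while IFCM-MS holds tumor accuracy near 1.0 at 0–2% noise
(see `examples/` and `scripts/acceptance.py`, which recompute these numbers;
test problem sizes — 128×128 phantoms, 20 seeds for the study, 48–64 px
fixtures for per-iteration invariants — are the package's standard fixture
sizes). The ablation ladder is monotone: the intensity kernel alone merges
tumor and tissue, transfer removes impulse noise from the memberships, and
the similarity term restores the small bright cluster.

## Known limitations

- The similarity's spatial term assumes compact clusters; large wrap-around
  backgrounds rely on the gray factor to stay coherent.
- Full IFCM-MS usually exhausts the iteration cap rather than meeting the
  1e-5 stack tolerance; the labeling is stable well before that.
- The neighborhood aggregation mode is provided for experimentation and is
  slower than the default identity mode.
- Multichannel and 3-D volumes, automatic selection of `c`, and kernel
  distances are out of scope.
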
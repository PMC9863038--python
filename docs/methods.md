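# Methods

This note records the model, the parameter choices, the numerical decisions,
and what the synthetic fixtures do and do not establish.

## Brightness classification

The class of a frame is a step function of its mean brightness `la`:
`T1 = (la − La)/la` with defaults `La = 112`, `t1 = 0.3`. The denominator is
the *observed* mean, making the deviation relative to the frame at hand; the
three classes partition the line with boundary ties (`|T1| = t1`) assigned
to medium. For 8-bit uniform frames the change points fall at intensity 87
(low→medium) and 161 (medium→high).

"Mean brightness" is not uniquely defined for color images; the default is
BT.601 luma (`0.299R + 0.587G + 0.114B`), the conventional scalar brightness
on the 8-bit scale `La` lives on. The HSV V channel and the plain channel
mean are available via `ClassifierParams.brightness_channel` — on
red-dominant tissue V (the max channel) runs well above luma, so the choice
matters and is deliberately exposed.

## Low-light enhancement

Operates on V only; H and S are carried through untouched, so chromaticity
is preserved exactly up to the final uint8 requantization (±1 per channel).

* **Adaptive gamma**: `γ = log 0.5 / log(μ_V/255)` with `μ_V` clipped to
  [1, 254] — the standard "map the mean to mid-gray" rule: parameter-free,
  monotone, `γ < 1` (brightening) exactly when `μ_V < 127.5`. A fixed
  exponent can be forced for experiments (`γ = 1` plus `denoise=False`
  makes the whole chain an identity within ±1).
* **Wavelet**: Haar, one level, symmetric extension (odd sizes supported).
  One level because the equalization acts on a single approximation band;
  the family is configurable.
* **Singular-value equalization**: `ξ = (max Δ + max Δ_γ)/(2 max Δ)` scales
  the approximation band halfway between the original and gamma-corrected
  intensity scale. Since every singular value is multiplied by the same
  scalar, `LF_eq = ξ·LF` exactly and the singular vectors are untouched; the
  implementation therefore computes only the two leading singular values.
  An all-zero band falls back to the gamma-corrected band.
* **Denoising**: universal soft threshold `λ = σ̂·√(2 ln N)` with the MAD
  estimate `σ̂ = median|HF_diag|/0.6745` — parameter-free and inert on
  noise-free bands.
* **Requantization**: round-half-away-from-zero, then clip to [0, 255].

## Detection

Two branches over a top-hat/bottom-hat contrast-enhanced image
(`out = in + tophat − bottomhat`, disc radius 5 px for frames up to 512 px,
scaled proportionally above).

**Absolute branch.** One scalar threshold per frame,
`Th = max(g,b) − τ·(σ_g+σ_b)/2`, with `τ` = 0.3 / 0.8 / 1.1 for high /
medium / enhanced-low frames: brighter frames get a larger threshold (fewer
false bright-tissue hits), darker frames a smaller one (fewer missed dim
highlights). Larger `τ` is strictly more permissive, so the three masks are
nested. A pixel is flagged when `max(G(p), B(p)) ≥ Th`. Two numerical
guards:

* the *near-constant gate*: if `σ_g + σ_b < 1` on the **raw** frame, the
  absolute mask is declared empty — with no spread, `Th` collapses to the
  frame maximum and every pixel qualifies vacuously. The gate reads the raw
  frame because contrast enhancement amplifies 8-bit quantization dither
  about threefold, which would defeat the guard on a visually uniform frame.
* `Th` is clipped below at 0.

Note the threshold is *relative to the frame maximum*: on a textured frame
with no specular blob at all, the brightest tissue structure is necessarily
flagged. This is inherent to the design; the empty-mask behavior applies to
smooth frames where the gate is active.

**Relative branch.** Unnormalized 3×3 Sobel magnitude on grayscale (ideal
step edge → 1020); candidates exceed a cut of 4× the mean gradient
magnitude (scale-adaptive; floored at a tiny positive value so
gradient-free frames yield nothing), are gated on intensity
`≥ μ_gray + σ_gray` (relative highlights are bright; vessel and halo edges
are dark and drop out), and enclosed holes are filled (a bright disc with a
flat interior still has a high-gradient rim).

**Union and dilation.** Final mask = dilation of (absolute ∪ relative) by a
digital disc (default radius 2), absorbing the dark halo ring around bright
spots. Radius 0 is the identity.

## Inpainting

State: working image, known-pixel mask (filled pixels become sources),
confidence map (1 on known, 0 on the hole), all updated locally per step.

* **Confidence** `C(p)`: sum of confidence over known pixels of the 9×9
  patch divided by the (border-cropped) patch area. Newly filled pixels
  inherit the priority-time confidence of the step that filled them.
* **Data term** `D(p)`: the strongest trusted central-difference gradient
  within the patch (a gradient sample is trusted only where the pixel and
  its 4-stencil neighbors are known), rotated 90° into the isophote,
  dotted with the front normal (from the mask gradient; an isolated pixel
  defaults to normal (1, 0) in (y, x) convention), normalized by α = 255
  and clipped to [0, 1].
* **Curvature** `K(p) = ∇·(∇I/|∇I|)` by finite differences on a 5×5 crop;
  0 where `|∇I| ≤ 1e−6`.
* **Priority**: the hybrid combiner (see README) is a single replaceable
  function (`combine_priority`); classic mode is the pure product
  `C(p)·D(p)`. `w = 0.7`, `β = 0.5` by default — `w` within its stated
  (0, 1) range, `β` balancing the data term against the O(1) regularized
  confidence.
* **Search window**: bounding box inflated by `n·h` rows / `n·w` columns;
  `n = n1 = 2` when the contour length `lc` is below the pivot `a`,
  `n = n2 = 4` otherwise. `a` defaults to `0.05·(H+W)` — tied to frame
  resolution, so small-on-screen highlights search proportionally nearby;
  pin `a` explicitly when cross-resolution comparability is needed. If a
  window holds no fully-known candidate, `n` grows by 1 until it does
  (bounded by the full frame; a frame with no fully-known 9×9 patch
  anywhere is an error).
* **Matching**: SSD over the target's known pixels, integer arithmetic
  (exact — no floating-point near-ties), candidates fully inside the window
  and fully known. All ties (priority and SSD) break lexicographically in
  (y, x), making the output deterministic.
* **Border patches** are cropped; denominators and SSD supports shrink
  accordingly.
* Per-step work is confined to the region's bounding box and its window,
  so runtime tracks highlight size, not frame size; the run statistics
  (`candidate_evaluations`, `fill_steps`) expose this.

Improved mode with `force_full_window=True` and `force_priority="criminisi"`
reduces exactly to classic mode on single-region masks; this byte-exact
equivalence is exercised in the tests.

## Evaluation

Pooled confusion counts by default; per-image averaging is provided
separately (`mean_scores`) because the two differ whenever mask sizes vary
and published tables rarely state which was used. 0/0 ratios (both masks
empty) return 0 with a warning — an empty prediction never earns credit —
while accuracy is computed normally. Dice ≡ F1 algebraically and
`Jaccard = Dice/(2−Dice)`; both identities are asserted in the tests. COV
uses population σ on BT.601 luma. NIQE is not implemented (it requires a
pretrained natural-scene-statistics model); any external no-reference
scorer with the same call shape can be used alongside.

## Synthetic frames

The generator emulates what the detector relies on: red-dominant smooth
texture (R > G, B on ≥95% of tissue), darker curvilinear vessels (random
walks), soft-edged yellowish fat (boost blurred with σ = 2.5 px — real
adipose tissue glistens but has no sharp rim, and this keeps steep
gradients exclusive to specular spots), and specular blobs with channels in
[240, 255], spread ≤ 8, plus an optional 2 px darker halo. Default frames
are 128² with 3 blobs of radius 3–7 px, putting the mask fraction in the
0.2–3 % range typical of endoscopic highlight datasets. Brightness is
steered to the requested class by bisecting a power-law tone-curve exponent
(no hard clipping, so bright frames keep tissue below saturation); the
low-class start point (exponent 2.4) emulates markedly underexposed footage
that is dark in V as well as in luma, which is the regime the enhancement
stage exists for.

What passing on these fixtures does **not** show: robustness to JPEG
artifacts, motion blur, smoke, fluid reflections, instrument shafts
(metallic, gray, sharp-edged — a known confuser for the relative branch),
or saturated fat. The detector's thresholds were chosen for the paper-style
brightness regimes, not tuned per fixture.

## Problem sizes

The test suite and the reproduction script use 128² frames (50 per
experiment), 32² single-hole frames for the byte-exact engine comparison
(20), and one 256²-vs-1024² pair for the locality check — sizes at which
every experiment runs in seconds while still exercising all three
brightness classes, multi-region repair, and window clipping.

## Known limitations

* The absolute threshold is relative to the frame maximum; highlight-free
  textured frames always get a small false-positive mask.
* The data/curvature terms use grayscale only; thin colored structures with
  equal luma are invisible to the fill-order logic.
* Exemplar search is exhaustive within the window (no PatchMatch-style
  acceleration); very large windows on very large highlights are quadratic.
* Single-level Haar enhancement can ring at sharp V-channel edges; the
  soft threshold suppresses but does not eliminate this.
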
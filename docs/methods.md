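# Methods

`rodtrack` tracks bubble-propelled tubular micromotors — rod-shaped,
micron-scale swimmers that eject oxygen microbubbles from one end — in
grayscale microscopy video. The pipeline is: simulate training data →
train a U-Net to segment rods while suppressing bubbles → threshold and
measure per-frame instances → link instances across frames by
minimum-cost assignment → convert trajectories to calibrated speeds and
angular velocities. This note records the models, the parameters that
matter, the numerical choices, and the limitations.

## Synthetic scenes and image formation

A scene holds rod micromotors and two bubble populations. Rods are
capsules (rectangle with semicircular caps) of length L and width W,
default 10 px × 3 px. At the default calibration of 1.53 μm/px a
physical 15 μm × 2 μm rod would be ≈ 9.8 px × 1.3 px; a 1.3 px-wide
shape is thinner than the blur kernel and cannot be segmented or
oriented reliably, so the default simulated width is 3 px and physical
dimensions are recovered through the calibration rather than the shape.

Placement follows normal distributions: motor and background-bubble
positions are N(field center, dims/4), clipped to a 5 px inset; headings
are uniform on [0, 2π). Each rod drags 2–5 trailing bubbles (its
exhaust) behind its tail: radii W·U(0.7, 1.3), successive centers
roughly touching (center spacing U(0.9, 1.4) × sum of radii), with ±15°
of angular jitter per step around the reversed heading. Background
bubbles have radii U(6, 14) px. These distributional parameters are the
package's own choices where no published values exist; they are defaults,
not reconstructions, and all are overridable.

Image formation is an explicit four-step chain, deliberately simple and
fully controllable:

1. rasterize — rods as capsules at `background_level + object_contrast`
   (default 0.75 − 0.45: dark rods on a bright field), bubbles as
   bright rims (+|object_contrast|) with background-level interiors;
   sub-pixel edges get fractional coverage over a ~1 px ramp;
2. Gaussian blur with `blur_sigma` (default 1 px) as a point-spread
   proxy;
3. a linear illumination gradient of amplitude `illum_gradient_amp`
   (default 0.08) in a random direction;
4. additive Gaussian noise (`noise_sigma`, default 0.02) and clipping
   to [0, 1].

What this emulates: the gross appearance of bright-field frames — dark
elongated objects, ring-like bubbles at many scales, uneven
illumination, sensor noise. What it does not: diffraction rings,
defocus, motion blur, optical flow of the medium, occlusions between
motors, or camera vignetting beyond a linear ramp. Tests passing on
this generator therefore demonstrate that the architecture and training
procedure can learn bubble-vs-rod discrimination and that the tracking
back-end is correct; they do not certify performance on any particular
microscope's footage.

Ground-truth masks cover motors only — bubbles contribute nothing, which
is precisely what teaches the network to ignore them. `filled` mode
marks capsule interiors (pixel-center test); `outline` mode marks a
2 px inner boundary band (the filled mask minus its 2-iteration
erosion), since 1 px outlines at this scale are close to unlearnable.
Filled is the pipeline default; outline is retained for fidelity to the
original training-target convention.

### Motion model

Per frame: `x += v·cos φ`, `y += v·sin φ`, `φ += ω`. With ω ≠ 0 the
trajectory is a regular polygon inscribed in a circle. Note the exact
algebra: every chord has length exactly v, so the circumradius is
`v / (2 sin(|ω|/2))`, which approaches the continuous-limit radius v/|ω|
from above as ω → 0 (0.06% difference at ω = 0.12). Trailing bubbles are
re-seeded behind the current pose every frame, so the plume follows the
motor. The boundary can be `none` (bare update rule) or `wrap`
(periodic); wrap exists so that fast motors can be simulated for many
frames in a finite field — a wrapped jump always exceeds any sensible
linking gate, so it cleanly terminates one track and starts another
rather than corrupting velocity samples.

## Segmentation network

A U-Net: `depth` encoder levels of two 3×3 same-padded conv + ReLU
layers with `base_filters·2^i` channels at level i, 2×2 max-pooling
between levels; a decoder of 2×2-stride-2 transposed convolutions, each
followed by concatenation with the matching encoder feature map and two
conv + ReLU layers; a head of one conv + ReLU at `base_filters` and a
final 1-channel conv; sigmoid output. The full-scale configuration is
depth 5, base 64 (filters 64…1024); the desk-scale default used
throughout the tests is depth 3, base 16 on 128 px frames (~119 k
parameters). No batch normalization: the described blocks are conv +
ReLU only. Inputs must be divisible by 2^(depth−1).

The network runs on a compact numpy engine written for this package:
convolutions lower to matrix multiplication (im2col + BLAS GEMM), the
conv backward pass reuses the same lowering via the flipped-kernel
correlation, and all layer gradients are verified against central
finite differences in the test suite. Everything is float32 except the
float64 path used by the gradient checks.

Training minimizes pixelwise binary cross-entropy (fused with the
sigmoid for numerical stability) using AMSgrad — Adam (β₁ 0.9, β₂ 0.999,
ε 1e-7, bias-corrected step) with the non-decreasing second-moment
accumulator — at learning rate 1e-4. Dataset shuffling, the validation
split (last `validation_fraction` of the shuffled set, default 0.125)
and weight initialization are all driven by explicit seeds; repeated
runs are bit-identical on the same machine in single-threaded mode.

Two initialization/normalization choices matter at small step budgets
(a few hundred optimizer steps):

* **Foreground-prior output bias.** Rods cover well under 1% of a
  frame. With a zero-initialized output bias, early optimization spends
  most of its budget driving every logit negative before the rods can
  emerge. The final conv's bias is therefore initialized at the prior
  logit log(p/(1−p)), p = 0.01 — standard practice for heavily
  imbalanced dense prediction — so the initial prediction already
  matches the background and the gradient signal goes to the rods from
  the first step. All other weights are He-initialized.
* **Per-frame standardization.** Frames are normalized to zero mean and
  unit variance before the network (constant frames map to zero). This
  removes the arbitrary illumination level and keeps activation — and
  therefore per-step gradient — magnitudes independent of camera
  contrast. It replaces an earlier min-max-to-[0,1] scheme, which left
  activations so small that adaptive-gradient steps moved the output
  logits an order of magnitude too slowly.

Checkpoints are `.npz` archives embedding the architecture spec (and
optionally the training config) as JSON, so a checkpoint is
self-describing and reload reproduces predictions bit for bit.

## Instance extraction

Heatmaps are thresholded at 0.5 (closed lower bound: a pixel exactly at
threshold is foreground). Outline-style masks are morphologically
closed (3×3) and hole-filled so moments see the full rod. Components
are labeled with 8-connectivity and filtered by area
([8, 400] px² default) and by moment aspect ratio (≥ 1.5): bubbles
are round, rods are ~3:1 elongated, so the aspect filter is what
rejects bubble remnants that survive thresholding.

Each surviving component yields an intensity-weighted centroid (weights
= heatmap values when available) and the principal-axis orientation
θ = ½·atan2(2μ₁₁, μ₂₀−μ₀₂) ∈ [0, π) from central second moments.
Axis lengths are 4√λ of the covariance eigenvalues; a zero minor axis
gives aspect ratio ∞ (passes the filter); single-pixel or isotropic
components return θ = 0 with a degenerate flag. Binary rasterization
limits single-frame orientation accuracy for a 10×3 px rod to ≈ 1.8°
(1 σ); a sub-pixel capsule-template fit was evaluated and did not
improve on the moment estimate, so the closed-form estimator stays.
Touching rods merge into one component — overlapping motors are not
split (no watershed); this is a known limitation.

## Linking

Frame-to-frame linking solves the minimum-cost bipartite assignment on
centroid Euclidean distance (scipy's Jonker–Volgenant solver; the test
suite checks it against exhaustive permutation search up to 7×7, and
ties between equal-cost optima are broken toward lexicographic (row,
col) order by an index-ordered perturbation ~1e-12 of the cost scale).
The gate is enforced by augmenting the matrix so every track and every
detection can stay unmatched at exactly `gate_px`: links more expensive
than the gate never form. Defaults: gate 80 px (the fastest published
speeds, ~750 μm/s at 7 fps and 1.53 μm/px, are ≈ 70 px/frame), up to 2
consecutive missed frames with no motion prediction (the last position
coasts), minimum final track length 5. Gating, track birth/death and
gap tolerance are this package's choices — the original description
specifies only the assignment step.

## Kinematics

With calibration (μm/px, fps): for a step spanning g frames,
v = ‖Δr‖·px_size·fps/g (μm/s) and ω = Δθ·fps/g (rad/s), where Δθ is the
minimal signed axial rotation in (−π/2, π/2] (orientations are defined
modulo π; a rod's head and tail are indistinguishable from shape).
θ is unwrapped cumulatively from these steps, and the head/tail
ambiguity is resolved by the direction of motion whenever displacement
exceeds 1 px/frame. Velocities are raw finite differences
("instantaneous"); any smoothing is opt-in and for plots only.
Steps across detection gaps divide by g and carry a gap flag.

When judging recovery of a constant turn rate against ground truth, the
recovered quantity is |mean(ωᵢ)| per track, not mean(|ωᵢ|): the sign of
ω is consistent along a track, and rectifying before averaging inflates
the estimate whenever per-step orientation noise (≈ 2.5° for a 10×3
rod) is comparable to the per-frame rotation. Per-sample ω values and
histograms are unaffected by this choice.

Summaries report per-track mean/s.d. of v and ω, path length, duration,
and sample count; histograms are produced both over all instantaneous
samples and over per-track means, since either convention is found in
practice.

## Problem sizes used by the test suite and acceptance script

All checks run on synthetic data generated at run time: assignment
optimality on 200 matrices up to 7×7; orientation recovery over 36
angles; parameter recovery on a 50-frame 256×256 video with motors at
5/10/15 px/frame (one turning at 0.05 rad/frame, riding its fully
in-field circle of radius v/ω = 100 px; the straight motors run on
wrap-around lanes at the field's top and bottom, and the linker uses
max_missed_frames = 0 there so a wrap-terminated track cannot coast
onto a neighbour); training at depth 3 / base 16 on 128 pairs of
128×128 frames for 10 epochs (batch 8), evaluated on 16 fresh pairs,
8 bubble-only frames, and one fresh 30-frame video through the full
network-in-the-loop pipeline. Training-history determinism is verified
at a smaller size (8 pairs, 2 epochs); the code path is identical at
every size. These sizes are the package's reduced-scale study
configuration; the full-scale configuration (depth 5, base 64, 256×256,
1024 pairs, batch 64, 30 epochs) is available via `UNetSpec.paper_scale()`
and the CLI flags.

## Known limitations

* The optics model is phenomenological; no claim is made about transfer
  to a specific instrument without retuning contrast/noise defaults.
* Overlapping or touching motors merge into one detection.
* No motion model during missed frames; long occlusions fragment tracks.
* Orientation is axial; heading is only disambiguated while the motor
  moves.
* The numpy engine is CPU-only and single-device; it is sized for the
  reduced-scale study, not for large-scale training.
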
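# Methods

## Model

The tracked object is a closed piecewise-linear contour p̂ = (p̂_1 … p̂_n),
stored counter-clockwise (positive shoelace area) in pixel coordinates with
wrap-around indexing. Its image energy is the length-normalized absolute
flux of the Sobel gradient through the contour,

    E_X(p̂) = − | (1/L) ∮ (N(s)/‖N(s)‖) · G(p̂(s)) ds |,

where G is the 3×3 Sobel gradient of the [0, 1]-normalized frame, N the
outward unit normal and L the perimeter. The 1/‖N‖ factor is a no-op here
because N is unit by construction. The absolute value makes E_X independent
of traversal orientation; |E_X| is bounded by the maximum gradient
magnitude in the image (it is a length-weighted mean of projections). There
is deliberately no internal (curvature/elasticity) term: the membrane of a
crawling cell is held by its actin cytoskeleton, not rounded by surface
tension, and thin pseudopods must not be smoothed away. Using gradient
*direction* (the signed projection onto the normal) rather than magnitude
means a coherent weak edge integrates to a strong signal while clutter with
incoherent gradient directions cancels.

### Normal extrusion

Between consecutive frames each vertex i moves only along its normal, by an
integer extrusion level x_i ∈ [−R, R] (pixels):

    r̂_i = p̂_i + x_i · N_i(x_i).

N_i(x) is *multi-scale*: it is perpendicular to the tangent

    T_i(x) = Σ_{j=i−M}^{i+M} exp(−c_ij² / 2σ(x)²) · sgn(i−j) · (p̂_i − p̂_j),

where c_ij is the arc length between vertices i and j, σ(x) = max(|x|, 1)
and M = floor(3σ) vertices per side (clamped to ⌊(n−1)/2⌋) — a 3-sigma
window. Large candidate moves therefore use tangents estimated from
proportionally broader stretches of the contour, which keeps their
directions stable where the local polygon is noisy. σ(x) = max(|x|, 1)
extends the definition to retraction (x < 0, same smoothing scale as the
equal-magnitude extrusion) and to x = 0 without division by zero. Both
halves of the sum point along the traversal direction, so T is the forward
tangent; the outward normal of a counter-clockwise contour is T rotated by
−90°, and positive extrusion grows the enclosed area. A degenerate
(zero-magnitude) tangent falls back to the neighbour chord p̂_{i+1} − p̂_{i−1}.

### Per-frame objective and its exact minimization

The per-frame problem is

    minimize over x ∈ [−R,R]^n :   − | Σ_e  ē(e; x) |  +  κ · |S(x)|,

where ē(e; x) is the **mean projected gradient** along candidate segment e
(the line integral ∫ N·G ds over the segment divided by its length, with N
linearly interpolated between the endpoint multi-scale normals and
renormalized), and S(x) is the set of segments either of whose endpoints
has a nonzero level. Two design points deserve emphasis:

* **Why the per-segment mean and not the raw integral.** The contour-level
  1/L normalization cannot be carried into an additive per-segment cost
  (L depends on the whole candidate assignment), but simply dropping it is
  wrong: a raw line integral grows with path length, so the optimizer would
  buy flux by taking longer paths inside a gradient band — in practice,
  sawtooth zig-zags along edges and pinch-offs of thin protrusions. The
  per-segment mean is the DP-compatible discretization of the 1/L
  normalization: tilting or stretching a segment inside the band no longer
  pays, and each segment's cost lives on the gradient-magnitude scale.
* **Why κ works at 0.02.** On that scale, κ = 0.02 is far below the mean
  projected gradient of a real edge (≈ 0.1–1.5 on the synthetic scenes)
  but comparable to the flux of pure noise, so it suppresses noise-driven
  jitter in flat regions without impeding edge tracking; κ = 0 tracks too
  but wanders more. Conversely the gain from moving any one segment is at
  most twice the maximum gradient magnitude, so any κ above that bound
  provably freezes the contour (the inert-curve property, tested at
  κ = 10 × max‖G‖).

The prose definition of κ (a penalty added to every moved segment) is
implemented rather than a subtracted −κ|S| term, which would reward
movement and contradict the inert-curve behaviour.

Because each vertex moves on an independent 1-D rail and the objective is
additive over segments, minimization is exact: the candidates form a
layered cyclic graph (n layers, 2R+1 states each) and a forward DP sweep —
equivalent to Bellman-Ford on this layered graph, where negative edge costs
occur but no cycles within a pass — finds the global minimum. The absolute
value is handled by two sign passes (−|f| = min(+f, −f), so minimizing both
signed sums and keeping the lower total is exact). Cyclic closure is
enforced by running the sweep once per candidate start level with the end
state pinned to it, O(n(2R+1)³); a `fast` mode does a single open-path
sweep over n+1 layers and is cheaper by a factor 2R+1 but only
approximately cyclic. Ties between equal-cost predecessors prefer smaller
|x|, then smaller x — a deterministic inertia bias.

### Tracking loop

Frame 0 holds the user-drawn initialization (resampled); there is no
automatic initialization front-end, since normal extrusion cannot converge
from a rough outline — accurate manual initialization is the user's part of
the contract. For each later frame: Sobel gradient → global extrusion
optimization from the previous contour → apply → remove self-intersections
(keep the largest-area loop; smaller loops are pinch-off artifacts) →
resample at uniform arc-length spacing (default 2 px, keeping vertex
density commensurate with the pixel grid without inflating DP cost).
Cleanup runs in that order because resampling a self-crossing polygon is
ill-defined. Frames whose optimal extrusion is all-zero keep the previous
contour object untouched — nothing moved, and re-running arc-length
resampling on its own output is not bit-stable — so zero-gradient
sequences are exact fixed points. Any |x_i| that reaches R flags the frame:
the method normally selects levels of only a few pixels, and a
radius-limited selection usually means the track is slipping. The whole
pipeline contains no randomness; identical inputs give bit-identical
output.

## Parameters

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| R | 16 | px | extrusion search radius per vertex per frame; bounds trackable inter-frame motion |
| κ | 0.02 | gradient units | penalty per moved segment; 0 disables inertia, ≥ max‖G‖ freezes the contour |
| resample spacing | 2 | px | target vertex spacing after each frame |
| segment sample step | 0.25 | px | arc-length step of the midpoint quadrature along segments |
| closure | exact | — | exact cyclic DP vs single-pass open-path approximation |

The quadrature step is a quarter of the pixel pitch: the gradient field is
bilinearly interpolated (with border clamping), and its kinks at pixel
boundaries leave a 0.5 px midpoint rule with worst-case errors of a few
percent on weak segments, while 0.25 px stays within 2% of a 100×-refined
rule with margin (measured over randomized smooth fields, excluding
segments whose signed integrand mostly cancels, where relative error is
ill-conditioned and no energy signal exists anyway). Within one edge of the
candidate graph all (2R+1)² segments share a sample count chosen from the
longest candidate, so shorter segments are sampled at least as densely.

Intensities are normalized to [0, 1] by the nominal bit-depth maximum
before gradients, so κ has one fixed scale across 8-, 12- and 16-bit
sources; 12-bit data in 16-bit containers is detected by a max ≤ 4095
heuristic, overridable per call.

## Evaluation

Masks rasterize a polygon by the even-odd rule at integer pixel centers,
ties on the boundary counting as inside (unambiguous and
oracle-checkable). Dice = 2|R∩T|/(|R|+|T|) (defined as 1 when both masks
are empty), sensitivity = TP/(TP+FN), specificity = TN/(TN+FP) with the
reference mask as truth. Sequence summaries report mean ± sd and exclude
frame 0, whose contour is the initialization itself and would bias both
rates toward 100%.

## Synthetic data

The generator emulates the qualitative appearance of phase-contrast
imagery rather than its optics: background 0.45; interior offset 0
(shade-off — interiors match background, the property that defeats
region-based methods); a bright halo ridge (+0.30, Gaussian profile of
width 2 px centered 2 px outside the outline); a dark boundary band
(−0.25, width 2 px, centered 2 px inside); additive Gaussian noise
σ = 0.02 on the [0, 1] scale. Halo and band sit symmetrically about the
true outline so the steepest intensity transition lies on it. Profiles are
functions of the signed distance to the truth polygon (KD-tree distance to
a densely resampled boundary, sign from the rasterized interior).

Three archetypes drive the ground truth, with per-frame displacement kept
below R so tracking is feasible by construction: `spread` (disk of radius
30 px growing 1 px/frame), `extrude` and `retract` (a body of radius 25 px
with a 6 px-wide capsule protrusion growing or shrinking 2 px/frame from
initial lengths 2 and 20 px). Truths are exact simple polygons every
frame, so end-to-end accuracy needs no external data.

What passing on these scenes does **not** show: the renderer has no
physical phase-contrast point-spread (no obscured-Airy convolution), no
shading or illumination drift, no debris, nuclei or neighbouring cells,
and its noise is white — real recordings add structured clutter that can
attract the snake (the method is known to latch onto debris occasionally
and recover thanks to the global optimum). Results on the synthetic
archetypes demonstrate the mechanics — lock maintenance, protrusion entry,
inertia — not performance on real microscopy.

## Problem sizes used in the shipped checks

Optimizer-vs-brute-force checks use n ≤ 6 vertices and R ≤ 2 (the
exhaustive space (2R+1)^n ≤ 15 625, enumerable exactly); tracking checks
use 160×160 px scenes, 10 tracked frames, and the full R = 16 default.
These sizes were chosen so every claim is recomputed from scratch in
minutes on a single core while exercising the same code paths as
full-size data (800×600 frames track at a few seconds per frame).

## Known limitations

* One cell per contour: no splitting, merging, or shared-boundary handling
  between touching cells; no re-initialization scheduling.
* Initialization must already be reachable from the truth by normal
  extrusion — the method refines and tracks, it does not discover.
* Integer extrusion levels quantize per-frame motion to whole pixels along
  each normal.
* The `fast` closure mode may return a slightly suboptimal cyclic
  assignment (its open-path optimum is evaluated cyclically).
* Open (non-closed) snakes and 3-D contours are out of scope.
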
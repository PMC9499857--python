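# Methods

This note records the modelling assumptions, parameter conventions and
numerical choices behind `ocumask`, and what the synthetic test world does
and does not establish about behaviour on real clinical video.

## Coordinate and camera conventions

All meshes live in model units in a face-local frame with x right, y
**down**, z away from the camera, so image coordinates (origin top-left,
y down) follow directly from projection. Two camera models are provided:
pinhole `(f·x/z + cx, f·y/z + cy)` (the default) and weak-perspective
`(s·x + cx, s·y + cy)`. Detector outputs are pixel coordinates only, so
intrinsics are configuration, not estimation: the default is `f = 3000` px
with a 1920×1080 principal point and a face at ~600 model units depth,
which puts the inter-eye distance at ~205 px and the iris radius at ~22 px —
representative of consumer DSLR/phone video of a patient's whole face at
0.3–1 m, the regime ophthalmic examination videos are shot in. Error
statistics are normalized by the inter-eye pixel distance, so they are
insensitive to this scale; per-frame gaze jitter under detector noise is
not (it improves with eye resolution), which is why the default emulates
video-class rather than webcam-class resolution.

## Generative models

* **Face** — bilinear: vertices are the core tensor contracted with a shape
  vector (identity-like, first frame only) and a motion vector (per frame).
  The bilinear form has a scale gauge (`αw^fs` with `w^fm/α` is invariant);
  we pin the leading entry of both vectors to 1 and optimise the rest,
  which makes first-frame recovery well-posed.
* **Eyelid** — affine: template plus shape- and motion-basis offsets, one
  model per eye, vertices in the face-local frame so the face pose carries
  over unchanged.
* **Eyeball** — a sphere of radius `r_e` carrying an explicitly indexed
  iris ring: the circle at polar angle `arcsin(r_i/r_e)` from the gaze
  axis (−z in the eyeball frame). Gaze is yaw-then-pitch:
  `Rot(θ, φ) = Rx(θ)·Ry(φ)`; this convention is shared by the fitter and
  the synthetic generator, so recovery tests are self-consistent.
  Tessellation is a latitude–longitude grid (7×12 plus poles) with a
  19-vertex iris ring appended; with two eyes this yields the 38 eyeball /
  200 eyelid evaluation-landmark budget used for error reporting.

## Staged fitting

Stages run strictly face → eyelid → eyeball per frame; there is no joint
refinement. Each stage is a nonlinear least-squares problem solved by
Gauss–Newton with Levenberg damping: `p ← p − (JᵀJ + μI)⁻¹Jᵀr`, starting
at `μ = 0` (so linear problems finish in one undamped step) and escalating
μ only when a step would increase the cost; accepted steps therefore never
increase the objective, and damping preserves the fixed points of the
undamped method. Termination is on relative step size (1e-10), relative
cost decrease (1e-14) or 100 iterations. Jacobians are analytic throughout
and are cross-checked against central differences in the tests. Rotations
are optimised through an axis-angle chart `R = Exp(δ)·R_ref` anchored at
the initial rotation, with the exact right-Jacobian correction for
derivatives away from the anchor; the result is orthonormal by
construction. The rotation smoothing penalty is evaluated as written, in
the Frobenius norm on the matrix difference.

First-frame pose initialisation uses a closed-form 2D similarity (Umeyama)
alignment of the mean model's landmarks to the detected ones; later frames
start at the previous frame's solution.

### Temporal smoothing

Later frames add `λ‖x − x_prev‖²` penalties on face motion weights,
rotation, translation, eyelid motion weights and the two gaze angles.
Defaults: `λ_fm = λ_em = λ_θ = λ_φ = 1e-2`, `λ_R = λ_t = 1e-3`, all
configurable. These are deliberately weak relative to the data terms
(whose normal-matrix entries are O(10³–10⁵) on the default geometry):
strong smoothing would lag fast dynamics — a 3 Hz nystagmus moves ~3° per
frame at 30 fps — so the defaults act as a tie-breaker and mild damper, not
a filter. Frame 0 has no predecessor; smoothing is disabled there.

### Occlusion handling

Feature visibility masks drop the corresponding residual rows everywhere
(landmark terms, curve fits, error records). An eyelid whose sparse
landmarks are all hidden keeps its semantic-line term if lines were
detected; an eye with fewer than three visible iris landmarks inherits the
previous frame's gaze.

### Eyeball statics prior

The method needs `(r_e, r_i, p_e)` before gaze can be tracked; they are
estimated once, on the first frame, by a documented stand-in convention:
`r_e` is a fixed fraction (default 0.2) of the distance between the two
eye-region centroids of the fitted face; the eyeball centre sits behind its
eye-region centroid along +z by 0.5·`r_e`; and `r_i` comes from a Kåsa
least-squares circle fit to the visible iris landmarks, back-projected at
the iris-plane depth (`z_c − √(r_e² − r_i²)`, solved by 1D root finding in
`r_i`). The back-projection is exact when the first frame is near-frontal
with neutral gaze, which the estimation assumes; the synthetic generator
uses the identical convention and starts every motif frontal, so on
synthetic data the statics are recovered exactly at zero noise.

## Eyelid curve machinery

Sparse eyelid landmarks per lid are summarised by a least-squares cubic in
image x (Vandermonde system); with fewer than four distinct x values the
degree degrades to (distinct − 1) to keep the system full-rank. The curve
is resampled uniformly in x over the fit domain into dense landmarks
(default count: the eyelid chain length, 25 per lid). Projected eyelid
vertices are matched to their nearest point on each semantic polyline
(point-to-segment minimum over the whole line, not arc-length
correspondence); the distance residual's gradient is the unit vector to
the closest point, which is exact wherever the distance is nonzero.

## Synthetic world

`generate_assets` builds seed-deterministic assets: a face-template grid
with a dome profile and designated eye-socket/brow regions; a core tensor
whose shape/motion offsets are smooth random quadratic-and-cubic polynomial
fields (constant and linear monomials excluded so no basis direction mimics
a rigid motion) plus structured brow-raise and lower-face motion fields;
per-eye eyelid models of four 25-vertex chains (fold, upper, lower, bulge)
whose bases displace only the vertical coordinate with per-chain cubic
profiles. Three properties are deliberate contracts with the fitter: chain
depth is constant and profiles are cubic, so pinhole projection of a chain
is again a cubic in image x; sparse landmarks are chain vertices including
the endpoints, so uniform-in-x densification resamples exactly onto the
projected chain; and motifs start frontal with neutral gaze for the statics
estimator. Under these conditions the whole pipeline is exactly
self-consistent, which is what makes the zero-noise recovery tests sharp.

Trajectory motifs are geometric caricatures of clinical signs — fixation,
triangular ±20° gaze sweep, ramped 10° strabismic yaw offset of one eye,
ramped-and-held ptotic closure, 5° 3 Hz nystagmus oscillation, raised-cosine
blink — not clinical simulations. Detector noise is i.i.d. Gaussian per
coordinate; occlusion is a frame-range schedule per feature kind and eye.

What passing tests therefore show: the energies, derivatives, solver and
bookkeeping implement the stated model correctly, identifiably and stably
under noise at video-realistic resolution. What they do not show: behaviour
under real detector error structure (correlated, heavy-tailed, systematic
near occlusions), model mismatch between a real face and the bilinear
span, rolling shutter, or re-identification risk of real reconstructions.

Measured regression bounds on the default synthetic asset (frozen in the
test suite): at σ = 0.5 px landmark noise, median normalized pixel error
< 2% (measured ~0.3%) and gaze RMSE < 0.5° (measured ~0.37°); at σ = 0,
reprojection ARE < 1e-4 and gaze error < 0.1° on 90-frame sequences of
every motif. Problem sizes used throughout (120-vertex face, 100-vertex
eyelids, 105-vertex eyeballs, 20/14/38 face/eyelid/iris detected landmarks
per frame, 90-frame sequences) were chosen as the smallest world in which
every stage is identifiable and the evaluation granularity (238 landmarks)
is preserved.

## Evaluation metrics

`D_abs` is the pixel distance between a detected landmark and the
projection of its corresponding reconstructed point; `D_norm = D_abs/D_eye`
with `D_eye` the inter-eye pixel distance, recomputed per frame from the
centroids of each eye's visible iris landmarks (the centre definition is a
package convention; per-video-constant `D_eye` would change cohort numbers
only marginally and can be computed from the per-record table). MRE/ARE are
the max/mean over non-excluded records; excluded pairs carry no values and
are written as empty CSV cells.

## Verification metrics

Acceptance at threshold is `score ≥ t`; TAR = TP/(TP+FN),
FAR = FP/(FP+TN). The ROC enumerates thresholds at every distinct score
plus ±∞ sentinels, AUC is trapezoidal (and equals the tie-corrected
Mann–Whitney U statistic divided by the pair counts, which the tests assert
exactly). TAR@FAR uses step-function semantics — the strictest threshold
with FAR not exceeding the level — with no interpolation. Rank-1 counts a
query as identified only if its single best gallery match shares its
identity; ties count as failure (conservative for a privacy claim), which
is configurable.

## Clinical statistics

Cohen's κ is computed from the paired 2×2 (or k×k) cross-table with
Landis–Koch labels (≤0 poor, ≤0.2 slight, ≤0.4 fair, ≤0.6 moderate, ≤0.8
substantial, above almost perfect). The McNemar comparison uses the exact
binomial test for discordant totals below 25 and the χ² form without
continuity correction otherwise (statsmodels backend). Agreement is
reported per (disease, eye) on three-rater majority calls.

The sample-size routine follows the Cantor construction: with the raters'
positive-call rates assumed as design constants, chance agreement `p_e` is
fixed and the κ test reduces to a one-sample normal test on observed
agreement `p_o = p_e + κ(1 − p_e)` with variance factor
`Q(κ) = p_o(1 − p_o)/(1 − p_e)²`; the returned n is
`ceil(((z_a√Q(κ₀) + z_b√Q(κ₁))/(κ₁ − κ₀))²)`. Because only `p_o` enters,
the construction is well-defined even for rate pairs whose joint 2×2 table
could not literally attain κ₁ (e.g. rates 0.3/0.7 with κ = 0.85) — a known
property of this approximation, inherited from the reference R routine
whose convention the function mirrors, including its critical value: `z_a`
is taken at `1 − α/2` (halved again under the two-sided flag), so the
significance argument acts as a symmetric two-tailed budget. Under this
convention the standard design (κ₀ = 0.6, κ₁ = 0.85, rates 0.3/0.7,
α = 0.025, power 0.9) yields n = 82. One caveat documented here because the
tests reflect it: the attained power of the discrete test is not monotone
in n (rejection counts are integers), so the Monte-Carlo cross-check
asserts the target power at the returned n and the crossing of the
normal-approximation design equation between n−1 and n, rather than
strictly lower simulated power at n−1.

## Known limitations

* The eyebrow deformation transfer is an optional post-stage on mesh
  vertices; it does not feed back into the fitted parameters.
* The statics prior is a stand-in convention: real deployments would
  calibrate the radius/offset ratios anatomically.
* Weak-perspective mode is provided for completeness; the statics
  back-projection and all defaults are tuned for the pinhole model.
* The CSV landmark fallback cannot carry semantic lines; use JSONL streams
  when line features matter.
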
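# Methods

This note documents the models, the synthetic data they are validated on,
the numerical choices, and the limits of what the tests demonstrate.

## Synthetic face generator

The generative model is deliberately simple: the mean mesh is a
half-ellipsoid (semi-axes 70 × 90 × 55 mm — half-width, half-height,
depth) sampled quasi-uniformly with a Fibonacci spiral and triangulated by
its convex hull, so any vertex count is supported and every vertex is
referenced by a face. Shape modes are sums of six random Gaussian bump
displacement fields on the surface, QR-orthonormalized, with geometrically
decaying mode scales `8.0 · 0.7^i` mm — large enough that faces differ
visibly, small enough that landmarks stay well separated. Landmarks use a
reduced 17-point scheme (5 jaw, 2 brow, 4 eye-corner, 2 nose, 4 mouth
analogues) chosen as the mesh vertices nearest canonical directions on the
ellipsoid; eight facial acupoints (midline point between the brows, paired
forehead/infraorbital/nostril-side points, chin midline) are anchored to
their three nearest mean-mesh vertices by barycentric coordinates plus a
normal offset, which transfers them exactly to any sampled mesh and
provides per-face 3D ground truth.

Rendering is Gaussian vertex splatting: each vertex contributes a blob at
its pinhole projection, weighted by a fixed per-vertex albedo and a depth
cue. The result is a deterministic, face-like texture that deforms with
the mesh — sufficient for the landmark cascade and the HOG detector to
learn from, and exactly consistent with the projected ground truth. What
it does **not** emulate: photographic appearance, illumination or skin
texture variation, self-occlusion at large pose angles, camera noise, or
lens distortion. Passing tests therefore demonstrate the correctness and
internal consistency of the geometry and learning machinery, not
photographic-domain accuracy.

Calibration scenes place the camera 650 mm above the arm's XY plane,
offset laterally (obliqueness up to ~13°) but aimed at the workspace
center, with a small random roll. Reference points use a 3/4/3/3
staggered-row layout (13 by default) with ±2 mm jitter to avoid exact
collinearity. Image/arm pairs are computed from the exact plane-to-image
homographies, as are the ground-truth transforms T and F, so stored pairs
are consistent with the camera to machine precision.

## Morphable model fitting

PCA is computed by SVD of the centered mesh matrix; mode scales are
singular values over √(n−1), and the basis sign is fixed deterministically
(largest-magnitude entry positive). The camera is a full-perspective
pinhole with known intrinsics; pose estimation is DLT on
intrinsics-normalized coordinates, projection onto the rotation manifold,
then Levenberg–Marquardt refinement of the reprojection error.

Landmark fitting alternates PnP with a ridge-regularized linear solve for
`α` in which the perspective division is linearized by freezing each
landmark's depth; steps that would increase the reprojection RMSE are
rejected, making the iteration monotone. Because alternation can stall
short of the joint optimum, a final Levenberg–Marquardt pass refines pose
and shape together (same objective, accepted only if it improves). The
ridge penalty is `λ Σ (αᵢ/sᵢ)²` with the mode scales `sᵢ` as a Mahalanobis
prior and `λ = 1e-3` by default — standard 3DMM practice; at `λ → 0` on
noiseless fixtures `α` is recovered to ~1e-7 relative.

## Acupoint transfer

Affine MLS uses weights `1/d^(2α)` with `α = 1` (the common inverse-square
setting). Queries within 1e-9 px of a control point return the
corresponding destination exactly (MLS interpolates its controls). The
first transfer stage has exactly three control points per acupoint, where
the affine fit is an exact interpolant; it is implemented as barycentric
remapping for numerical stability, with an inverse-distance-weighted
fallback (flagged) for collinear neighbor triangles. Only points are
deformed; no dense image warp is produced — overlays draw crosses at
acupoints and dots at landmarks.

## Tracking

The correlation filter follows the classic adaptive-filter recipe:
log-compressed, zero-mean/unit-norm, cosine-windowed patches; a Gaussian
target response (σ = 2 px); eight small seeded rotation jitters at
initialization; running numerator/denominator averages with learning rate
0.125 and regularizer 1e-5. The correlation window is 2× the target box —
tight windows lose fast targets to the cosine-window attenuation. The raw
response argmax is biased up to ~1 px toward the window center by the
same attenuation, so the peak is refined by per-axis parabolic
interpolation.

PSR uses the full response window minus an 11×11 mask centered at the
peak (argmax ties break to the smallest row, then column); zero sidelobe
deviation maps to +∞ for a strict peak and to 0 (flagged degenerate) for
a flat plane. The re-detection threshold defaults to PSR < 7, and
re-detection runs only on low PSR by default; a fixed every-N-frames
cadence is available via `TrackerConfig.redetect_every`. The default
detector is a logistic scorer over HOG features (8-px cells, 9 unsigned
orientation bins, L2-Hys block normalization via scikit-image) scanned
over a small scale pyramid with greedy NMS at IoU 0.3.

## Landmark cascade

The detector is a scaled-down shape-indexed boosting cascade: 6 stages of
50 depth-3 trees (shrinkage ν = 0.1), each stage sampling a 200-point
pixel pool anchored to the nearest mean-shape landmark, with split
features the difference of two pool-pixel intensities and candidate pairs
drawn with an exponential distance prior (scale 0.1 in mean-shape units).
Residuals are regressed in the similarity-normalized frame, so prediction
is equivariant to similarity transforms of the input up to resampling.
Leaves store `ν ×` the mean residual of their training samples, which
makes the training loss provably non-increasing per tree. Pixel lookups
clamp at image borders. Training can replicate each image with jittered
initialization boxes (size/position) so the cascade tolerates imprecise
detector boxes; the end-to-end demo uses 2 initializations with ±12 %
size and ±8 % position jitter.

## Hand-eye calibration

The linearized system stacks `X = ax + by + c − gxX − hyX` rows, then the
corresponding Y rows, into a 2n × 8 matrix solved by orthogonal
decomposition (SVD-based least squares); the explicit normal-equations
formula `(AᵀA)⁻¹Aᵀb` is retained as a test oracle only. Coordinates are
similarity-normalized before assembly and denormalized afterwards for
conditioning. Rank deficiency (smallest singular value < 1e-10 × largest)
raises an error naming the deficiency — three point pairs always fail.

The height factor in the combined mapping is implemented as the
interpolation coefficient `s = (k − a)/(b − a)`, which reproduces both
limit behaviors (`k = a` → T, `k = b` → T∘F) and matches the parallax
geometry to first order; the correction is exact at the two calibrated
heights and approximate (but in practice ~mm-accurate over a 50–70 mm
span) in between. The acupoint height `k` is supplied per point by
configuration — in the demo, as the constant face-surface offsets of the
mean model's acupoints, since the face translates in-plane.

## End-to-end demo

The demo builds one consistent world: the robot-arm frame is the world
frame, the face lies on the workspace looking up, and a single camera
(focal 1500 px, 640×640) serves both calibration and face observation, so
every acupoint has exact image and arm ground truth. Problem sizes — 120
training renders for the cascade, 40/80 positives/negatives for the
detector, 8 evaluation frames — keep a full run under ~15 s while leaving
wide error margins (typical acupoint errors ≈ 0.4–1.5 px and 0.2–0.8 mm
against thresholds of 3 px / 1 mm).

## Known limitations

* The fitting camera is strictly perspective with known intrinsics; there
  is no affine-camera option and no intrinsic calibration.
* Only face translation/yaw within the synthetic motion range is
  exercised; large out-of-plane rotations break the splat renderer's
  no-self-occlusion assumption before they break the fitter.
* The height correction is first-order in the plane offset; accuracy
  degrades when `k` extrapolates beyond the calibrated pair of planes
  (a warning is raised beyond a 10 mm margin).
* The HOG detector is trained on splat renders and is not expected to
  transfer to photographs; it exists to exercise the detect–track–localize
  loop. Real deployments would plug in a photographic detector and a
  photographically trained cascade through the same interfaces.
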
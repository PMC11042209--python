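# Methods

This note records the models, conventions and numerical choices behind
`reachkin`, in the order data flows through the pipeline.

## Coordinate and data conventions

All 3D quantities are millimetres in the *box frame*: origin at the
pellet rest position, +x forward (from the slit toward the pellet), +y
sideward, +z upward. The slit plane sits 7 mm behind the pellet
(`slit_pellet_distance`). Frames are 0-based and contiguous; time is
`frame / fs` seconds at a default sampling rate of 100 Hz. Missing data
is NaN everywhere; likelihoods are tracker confidences in [0, 1] and
carry no other semantics.

CSV track tables flatten the keypoint/field hierarchy into
`<keypoint>_u`, `<keypoint>_v`, `<keypoint>_likelihood` columns with a
leading `frame` column; the CSV dialect deliberately carries no
metadata (RFC-4180 plain table), so `fs` and the view name are reader
arguments, while the HDF5 dialect stores both as attributes. The two
dialects parse to identical structures and every reader/writer pair is
a lossless roundtrip on valid data.

## Camera model and calibration

Each view is a projective pinhole camera, a 3×4 matrix `P` mapping
homogeneous mm to pixels. Mirror views are *virtual cameras*: the front
camera reflected about the mirror plane, `P·H` with `H` the Householder
reflection about the plane (point + unit normal). Reflection flips
handedness, so a virtual camera decomposes (RQ) into `K[R|t]` with
`det(R) = −1`; the `mirrored` flag records this. Keeping the reflection
inside `P` means triangulation and calibration treat mirror views like
any other camera.

`calibrate_dlt` solves the homogeneous least-squares DLT system by SVD
after Hartley normalization of both point sets (centroid at the origin,
mean norm √dim) — normalization is essential for conditioning with
pixel coordinates in the hundreds. Two degeneracies are rejected
explicitly: fewer than 6 correspondences, and a (near-)coplanar 3D
point set (third singular value of the centered points below 1e-8 of
the first), which is why calibration fixtures use the checkerboard in
at least three orientations. The sign of `P` is fixed by cheirality
(median projective depth of the calibration points positive), which
makes `det(R)` a reliable handedness indicator, and the mean
reprojection error is reported alongside the camera.

Triangulation stacks the per-view DLT rows for each frame and takes the
SVD null vector; frames observed by fewer than two views yield NaN and
a frame's failure never affects its neighbours.

Because DLT calibration is only defined up to the world frame of its
correspondences, a final similarity transform (Umeyama closed form:
rotation constrained to det +1, isotropic scale, translation) maps
triangulated static reference points — pellet rest position and the two
slit edges by default — onto their nominal box-frame coordinates. Scale
is included to absorb residual calibration gauge; the checkerboard
fixes the metric so the fitted scale is ~1. Collinear reference sets
are rejected.

## Trajectory cleaning

Cleaning is three ordered steps, each per coordinate:

1. likelihood masking (2D stage only): samples below `likelihood_min`
   (default 0.6) become NaN;
2. gap interpolation: interior NaN runs up to `max_gap` frames
   (default 5 = 50 ms) are filled linearly; longer gaps and edge gaps
   stay missing;
3. Savitzky–Golay smoothing, window 7 frames / order 3, applied
   independently to each finite run; runs shorter than the window are
   left unsmoothed with a warning.

The filter reproduces polynomials up to the fit order exactly, so
constant and linear motion pass through untouched; at 100 Hz the 70 ms
cubic window attenuates tracker noise with negligible bias on
reach-speed time scales. Derivatives (velocity, acceleration, jerk) are
central differences on the *smoothed* series, one-sided at run edges —
third differences of raw 100 Hz positions are noise-dominated, so
smoothing is a precondition of the jerk scalar, not a cosmetic choice.

## Reach segmentation

The detector replaces manual span selection. On the aligned palm
trajectory it takes local maxima of x(t) with prominence at least
`min_prominence` (3 mm) whose height exceeds the resting baseline by
`forward_threshold` (2 mm); the baseline defaults to the median of the
finite forward coordinate, which tracks the slit plane because the paw
rests there most of the session. Window bounds extend outward to the
hysteresis level `baseline + 0.25 × prominence`. Overlapping spans —
possible when smoothing leaves two equal-height samples on one apex
plateau — are merged, keeping the higher apex (earlier on ties);
segments split only where x genuinely crosses below the hysteresis
level. Durations outside [`min_duration`, `max_duration`] = [10, 200]
frames (0.1–2 s at 100 Hz) are discarded. All thresholds are scaled to
the mm geometry and 100 Hz rate and are config-exposed; segmentation is
invariant to time translation, and detected windows never overlap.

Manually selected spans (CSV of half-open `(start_frame, end_frame)`
pairs) are validated against the trajectory and enter the same
downstream path with `source="manual"`; the apex of a manual span is
the argmax of x within it.

## Kinematic scalars

Per reach: duration `(end − start)/fs`; endpoint and apex position, the
3D coordinates at the frame of maximal forward extension (the segment
*end* belongs to retraction, so the endpoint is taken at the apex);
outward path length (summed finite steps from start to apex, which
equals the straight-line distance exactly for straight reaches); mean
and max speed; `tvmax_frac`, the speed-peak time as a fraction of the
window; maxima of acceleration and jerk magnitudes. Acceleration and
jerk are reported as maxima of magnitudes; the full profiles remain
available programmatically via `differentiate`. Segments with less than
50 % finite frames get NaN kinematics, a recorded completeness
fraction, and should be scored as artifacts downstream.

`average_trajectory` linearly time-normalizes each reach to a fixed
number of samples and averages pointwise per axis, returning the mean
and SD band per direction (forward/sideward/upward as distance to
pellet) — the standard reach-shape summary.

## Outcome classification

The six-way cascade (first match wins) operationalizes video-based
labels from geometry alone:

1. **artifact** — paw track under 50 % finite in the window, or
   duration outside the acceptable bounds;
2. **in_vain** — pellet track entirely missing in the window (no
   pellet present);
3. **missed** — minimum paw–pellet distance above `contact_radius`
   (2 mm, the pellet diameter);
4. **grasped / lost** — the pellet was *carried*: paw–pellet distance
   below `contact_radius` while the pellet is displaced at least
   `displacement_min` (1 mm) from its rest position, for at least 3
   consecutive frames. Grasped if the pellet sat inside the mouth zone
   (5 mm sphere around a configurable mouth point behind the slit) when
   carrying ended, lost otherwise;
5. **flicked** — not carried, but the pellet was displaced at least
   `displacement_min` (knocked off);
6. otherwise **missed** (a touch that moved nothing).

Two deliberate refinements over a naive distance test: carrying
requires pellet *displacement*, not just proximity — during the slow
final approach the paw hovers within 2 mm of a static pellet for many
frames on every reach, which must not count as co-movement; and rules
4–5 evaluate over the window extended by `fate_horizon` (60 frames,
clipped at the next reach's onset), because a detected window closes at
the hysteresis crossing early in retraction, before transport to the
mouth completes. Judging grasped-vs-lost at the frame where carrying
ended makes the rule insensitive to whatever happens to the pellet
supply afterwards. Manual labels (CSV of `segment_index,label`)
override the cascade per reach.

Clustering standardizes the scalar features to zero mean/unit variance
(making it invariant to feature rescaling) and runs k-means,
Ward-linkage agglomerative clustering or a Gaussian mixture,
deterministic under the seed; rows with non-finite features (artifacts)
receive cluster −1 and the silhouette score is reported. The default k
is the number of non-empty outcome categories when labels exist, else
the silhouette-maximizing k in [2, 6].

## Session metrics

From the four per-session counts: total reaches, percentage of
right-paw reaches, success rate = successful / (failed + successful).
The dominant paw is the paw used for *more than* 70 % of all reaches —
the boundary is exclusive, so exactly 70 % (or 30 %) assigns no
dominance; the left-paw rule mirrors at below 30 %. Shaping passes with
at least 20 reaches and established dominance. The learner criterion is
success rate ≥ 30 %, boundary inclusive (the threshold is a lower bar a
learner reaches). Zero-total sessions report NaN rates with all flags
false rather than raising. Learning curves aggregate a cohort into
per-day mean ± SEM (SD/√n over animals with data that day); a day with
one animal reports SEM 0 with a warning so curves stay plottable.

## The synthetic scene generator

The generator defines the study conditions for every test. A session
alternates idle epochs (paw resting at the slit, 0.02 mm jitter, with a
short continuous walk whenever the rest posture changes — the paw never
teleports) and reach events. Each reach is a straight minimum-jerk
transport `s(τ) = 10τ³ − 15τ⁴ + 6τ⁵` from the rest posture to an
outcome-dependent apex over 0.25–0.40 s, a 3-frame static hold, and a
minimum-jerk retraction (via the mouth point for grasped/lost). The
minimum-jerk family is the standard idealization of ballistic limb
transport and has closed-form derivatives: peak speed 1.875·D/T at
mid-movement, which gives exact expected scalars. The recorded
ground-truth max speed is the peak over *all* phases of the window —
the retraction to the mouth, not the outward reach, is usually fastest.

Outcome semantics: grasped — pellet co-moves with the paw to the mouth;
lost — co-moves, then detaches partway (detach fraction chosen so the
drop point stays well outside the mouth zone while the carried run
exceeds 3 frames); flicked — pellet jumps 6 mm off the disk within two
frames of contact; missed — apex offset 3.5–5 mm sideways; in_vain —
pellet track missing for the whole trial; artifact — grasped kinematics
with the middle 60 % of the paw window blanked to NaN. The default
outcome mix (grasped .35, missed .25, flicked .15, lost .10, in_vain
.15) omits artifacts: they are recording failures, not behaviors, and
carry no detectable forward peak; sessions including them are used
where the artifact rule itself is under test. Gaussian world noise
(default σ = 0.05 mm) is added to finite samples; the sensor log's
front-bar channel rises at each reach onset, with floor-touch and
beam-break streams derived from the paw position.

The camera rig places the front camera 26 cm before the box (f = 1800
px, 1440×1080) with vertical mirrors at ±45° flanking the slit. Mirror
tracks are produced by *explicitly reflecting* each 3D point about the
mirror plane and projecting through the front camera — an independent
code path from the geometry module's virtual-camera algebra, so the two
validate each other. Projection adds per-view pixel noise (default 0.5
px) and a bimodal likelihood: dropout frames draw below 0.5, all others
above 0.9 — only the thresholding behavior matters downstream, so no
attempt is made to imitate a specific tracker's confidence
distribution. Calibration fixtures project a 4×4-square, 1 mm-pitch
checkerboard (25 exactly spaced corners) in ≥ 3 random poses; a single
pose would be coplanar and DLT-degenerate. Everything derives from one
seed; identical seeds give bit-identical output.

### What the generator does and does not emulate

It reproduces the geometry, timing, noise scale and outcome logic of
the task well enough to test calibration closure, parameter recovery
and rule-based classification end to end. It does not model limb
biomechanics (no joint constraints, no grasp aperture), curved or
corrective reach paths, tracker-specific error structure (outliers,
identity swaps, correlated confidence), lens distortion, motion blur,
or the animal's trial-to-trial learning. Passing tests therefore
demonstrate the pipeline's correctness on well-posed input, not
robustness to every pathology of real video; the likelihood gate, gap
rules and artifact category are the designed containment for such
pathologies.

## Problem sizes in the test suite

Tests run sessions of 3–10 reaches (≈ 600–1500 frames at 100 Hz),
Monte-Carlo loops of 20–50 seeds, 100-seed calibration noise sweeps,
and an exhaustive enumeration of all session-count vectors with total
≤ 30; these sizes give stable statistics while keeping the whole suite
in the seconds range.

## Known limitations

- Lens distortion is not modeled; real calibrations should undistort
  upstream or accept the residual as reprojection error.
- The linear DLT triangulation is not the maximum-likelihood point
  estimate under pixel noise; tests show it tracks a per-point
  nonlinear reprojection minimizer within 10 % at 0.5 px noise, which
  is adequate at this geometry.
- Phase-level parsing of a reach (reaching / pronation / grasping /
  retraction) and per-digit aperture metrics are out of scope; the palm
  keypoint drives segmentation and fingers are not modeled.
- The flicked/lost boundary for a pellet carried briefly and dropped
  near the disk is inherently conventional; the displacement-gated
  carried test with a 3-frame minimum is this package's convention and
  is config-exposed.
- Session metrics assume the four counts are given or derived upstream;
  mapping per-reach outcome labels to "successful/failed" (grasped =
  successful, artifact excluded) is a convention of the synthetic
  session's `counts()` helper.
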
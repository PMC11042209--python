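# reachkin

Kinematic analysis of the mouse reach-to-grasp (single-pellet) task:
from two-view 2D keypoint tracks — one high-speed front camera plus
tilted side mirrors — to calibrated 3D paw trajectories, segmented
reaches, per-reach kinematic scalars, trial-outcome categories and
session-level learning metrics.

The single-pellet assay is the standard rodent model of skilled
forelimb movement: a food-restricted mouse reaches through a narrow
slit for a ~2 mm sugar pellet resting 7 mm away on a feeder disk.
Markerless trackers output per-frame `(u, v, likelihood)` pixel
coordinates of the paw and pellet in each camera view; this package
turns those tables into quantitative behavior. A deterministic
synthetic scene generator (minimum-jerk reaches, pellet dynamics,
virtual mirror cameras, checkerboard calibration targets, sensor logs)
stands in for animal video, so the entire pipeline is testable offline
with exact ground truth.

## The model in brief

**Mirror views as virtual cameras.** A planar mirror turns the single
physical camera with projection matrix `P = K[R|t]` into a second,
*reflected* camera `P·H`, where `H` is the 4×4 reflection about the
mirror plane. The reflected camera has `det(R) = −1` (the `mirrored`
flag); because the reflection lives inside `P`, standard two-view
geometry applies unchanged. Cameras are calibrated with the normalized
direct linear transform (DLT) from checkerboard correspondences
(homogeneous least squares via SVD, Hartley normalization), points are
triangulated per frame by the linear DLT system, and trajectories are
mapped onto the box frame (origin at the pellet rest position, +x
forward, +y sideward, +z upward, mm) with a least-squares similarity
transform anchored to static reference points.

**Reach detection.** Reaches are prominent excursions of the forward
coordinate x(t): local maxima with prominence ≥ 3 mm above the slit
baseline, window bounds at the hysteresis level baseline + 25 % of the
prominence, durations restricted to 0.1–2 s at 100 Hz. Manually
selected spans can be supplied instead.

**Per-reach scalars.** duration, endpoint/apex coordinates (distance
to pellet per axis at maximal forward extension), outward path length,
mean/max speed, relative timing of the speed peak, max acceleration and
jerk — derivatives by central differences on Savitzky–Golay-smoothed
trajectories.

**Outcomes.** Each reach gets one of six categories — `grasped`,
`missed`, `flicked`, `lost`, `in_vain`, `artifact` — from a
deterministic rule cascade over paw–pellet distance, pellet
displacement and the mouth zone (manual labels override). Reaches can
additionally be clustered on standardized scalar features (k-means,
agglomerative, or Gaussian mixture).

**Learning metrics.** With per-session counts of failed/successful
reaches per paw:

    total = fr + fl + sr + sl
    pct_right = (fr + sr) / total × 100 %
    success_rate = (sr + sl) / total

The dominant paw is the one used for **more than 70 %** of reaches
(strict); shaping passes at ≥ 20 reaches with established dominance; a
*learner* reaches the 30 % success-rate threshold. `learning_curve`
aggregates cohorts into per-day mean ± SEM series.

## Worked example

Simulate a six-reach session (0.5 px tracker noise), reconstruct 3D
from the front and left-mirror views, and score it:

```console
$ reachkin simulate demo --seed 3 --n-reaches 6 --noise-px 0.5
wrote session fixtures to demo
$ reachkin reconstruct --calibration demo/calibration.toml \
    --track front=demo/front.csv --track left_mirror=demo/left_mirror.csv \
    -o demo/traj3d.csv
triangulated 2 keypoints -> demo/traj3d.csv
$ reachkin analyze demo/traj3d.csv -o demo/scalars.csv
scored 6 reaches -> demo/scalars.csv
```

The scalar table (one row per detected reach):

```
 start_frame  end_frame  duration_s  end_x_mm  end_y_mm  vmax_mm_s   label
          77        116        0.39      0.22     -0.24      69.15 grasped
         228        258        0.30      0.20      0.20      83.90 grasped
         361        394        0.33      0.29     -0.19      69.16    lost
         500        538        0.38      0.07      4.15      57.67  missed
         614        650        0.36     -0.16      0.26      83.25 grasped
         771        814        0.43      0.00     -4.15      51.77  missed
```

Endpoints read as distance to the pellet: grasped/lost reaches end
within ~0.3 mm of the pellet, the missed ones ~4 mm to the side; peak
speeds of 50–85 mm/s are the retraction-phase maxima of the underlying
minimum-jerk movements. All six labels match the generator's ground
truth (`demo/ground_truth.json`).

Session metrics from a counts table work the same way:

```console
$ reachkin metrics counts.csv -o metrics.csv --curve curve.csv
```

## Layout

- `reachkin.io_formats` — track tables (CSV/HDF5), sensor logs,
  calibration TOML, scalar tables: the only I/O surface
- `reachkin.geometry` — DLT calibration, virtual mirror cameras,
  triangulation, similarity alignment
- `reachkin.trajectory` — cleaning (likelihood masking, gap
  interpolation, Savitzky–Golay), reach segmentation, manual spans
- `reachkin.kinematics` — derivatives, per-reach scalars, averaged
  trajectories
- `reachkin.outcomes` — six-way outcome rules, manual labels,
  clustering
- `reachkin.session_metrics` — totals, paw dominance, success rate,
  shaping/learner criteria, learning curves
- `reachkin.synthetic` — ground-truth scene generator
- `reachkin.cli` — `reachkin` command-line entry point

See `docs/methods.md` for the modeling choices, parameter defaults and
known limitations.
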
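# headgaze

Measure large horizontal eye–head gaze shifts with a wearable eye tracker
plus a fixed downward camera watching a planar fiducial marker on the head.

The world-fixed gaze direction is assembled as **G = E + H + c**:

- **E** (eye-in-head): the tracker's gaze point in scene-camera pixels,
  converted to visual angle through an ideal pinhole model
  (`azimuth = atan((cx − x)/f)`, positive = leftward).
- **H** (head-in-world): yaw of a square marker recovered per frame from its
  four corner pixels by a direct-linear-transform homography, normalized by
  the camera intrinsics and decomposed into rotation + translation; the yaw
  about the optical axis is the head angle, zeroed on a reference fixation.
- **c**: a single additive constant fitted by least squares to fixations of
  wall targets at known azimuths during a calibration sweep.

Both streams are clock-synchronized from head-oscillation episodes
(velocity cross-correlation with sub-sample refinement), linearly resampled
to a common 200 Hz grid, and fused. On top of the fused record the package
provides:

- **quality**: mean absolute accuracy against targets, windowed RMS
  sample-to-sample precision (41-sample sliding windows, median across
  windows), effective sampling frequency, and the bimodal sample-interval
  distribution of the eye stream;
- **events**: gaze-saccade segmentation by gaze-velocity thresholding with
  peak-relative bound refinement, VOR-phase extraction with eye–head
  velocity gain, pre/post-onset velocity analysis of eye–head relative
  timing, and per-condition amplitude/velocity/duration summaries including
  the peak-head-velocity vs gaze-amplitude slope;
- **simulate**: a kinematic ground-truth generator that renders the whole
  protocol (calibration sweep, oscillation episodes, six target-separation
  conditions from 17.6° to 143.6°) into the exact raw CSV formats the
  pipeline consumes — marker corner pixels, scene-camera gaze pixels with a
  bimodal 4/8 ms interval mixture, sensor noise, a true clock offset, and a
  ground-truth event table, so every stage is testable without hardware.

## CLI

```bash
# generate a synthetic session into a directory
headgaze simulate --seed 1 --out runs/s1
# optionally override generator parameters
headgaze simulate --config my.yaml --seed 1 --out runs/s1

# individual stages
headgaze pose runs/s1/marker.csv --camera ceil.json --marker-side 0.1 --out pose.csv
headgaze convert runs/s1/eye.csv --camera scene.json --out angles.csv
headgaze sync runs/s1 --out sync.json
headgaze fuse runs/s1 --out fused.csv

# full pipeline: fused record + events + quality + coordination summary
headgaze report runs/s1 --out runs/s1/report
```

A session directory contains `eye.csv` (`timestamp,x_px,y_px,valid`),
`marker.csv` (`timestamp,x0,y0,…,x3,y3,valid`), `targets.csv`,
`annotations.json` (corner-fixation window, calibration fixation windows,
oscillation episodes, condition spans), `cameras.json`, and — from the
simulator only — `truth.json`. The processing path never reads the truth.

## Library example

```python
from headgaze import pipeline
from headgaze.simulate import SimConfig, simulate_session

sess = simulate_session(SimConfig(seed=1))
res = pipeline.process_session(sess.marker, sess.eye, sess.annotations,
                               sess.ceiling_camera, sess.scene_camera,
                               sess.marker_model)
print(res.calibration.c, res.quality.precision_rms_s2s)
print(res.summary.head_velocity_slope, res.summary.head_leads_fraction)
```
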
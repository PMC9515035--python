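# spheretrack

Inside-out 6-DoF tracking of retroreflective sphere markers from a head-mounted
depth camera, with ultrasound probe calibration and accuracy evaluation — as a
hardware-free Python library and CLI.  A synthetic depth camera replaces the
AR-headset sensor, so the complete tracking, calibration and evaluation
workflow runs and is testable on any machine.

## The problem

Freehand ultrasound guidance and medical augmented reality need the 6-DoF pose
of a hand-held probe.  Instead of an external optical tracker, an inside-out
approach uses the time-of-flight depth camera already built into AR glasses:
retroreflective spheres rigidly attached to the probe appear as bright blobs in
the camera's infrared *active-brightness* (AB) image, and the co-registered
depth image gives each blob's range.  This package implements that pipeline:

1. **Blob detection** — threshold, connected components, area/circularity
   filters, intensity-weighted subpixel centroids in the AB image.
2. **Back-projection** — a blob at pixel `p` with depth `d_p` becomes the
   camera-frame surface point `D_s = d_p · L(p)`, where `L` is the camera's
   per-pixel lookup table of unit ray directions, then chains into the world
   frame through `W_s = W_T_L · L_T_D · D_s`.
3. **Surface-to-center correction** — the camera sees the sphere *surface*;
   the center is one radius farther along the viewing ray:
   `W_s_c = W_s + r_s · (W_s − W_c_d)/‖W_s − W_c_d‖`.
4. **Kalman filtering** — each sphere center runs through its own 9-state
   constant-acceleration filter (position/velocity/acceleration per axis,
   position-only measurements) to suppress the depth camera's noise.
5. **Correspondence** — the marker's pairwise sphere distances are unique, so
   measured centers are identified by matching the distance pattern; ambiguous
   or unmatchable frames raise errors rather than producing wrong poses.
6. **Pose estimation** — SVD landmark registration (Kabsch, reflection-safe)
   of the marker's reference sphere centers `RF_s_c,i` onto the measured
   `W_s_c,i` yields `W_T_M` and an RMS fiducial residual.

Around the tracker sit the supporting pieces of a tracked-ultrasound system:
**spatial calibration** of the US image into the marker frame
(`M_T_US = (OT_T_M)⁻¹ · OT_T_US` from stylus-tip landmark pairs), **pivot
calibration** of a stylus, **temporal alignment** of two trackers' trajectories
by cross-correlating a shared sinusoidal motion segment, **in-situ image
placement** (US image corners in world coordinates), and **accuracy metrics**:
per-sphere relative distance errors
`d_e = ‖s_c,p2 − s_c,p1‖ − ‖ŝ_c,p2 − ŝ_c,p1‖` and relative pose errors
`T_e = ((T_p1)⁻¹ T_p2)⁻¹ ((T̂_p1)⁻¹ T̂_p2)`, decomposed into translation and
intrinsic Z-Y-X Euler rotation, summarized as min / 25th / median / 75th /
max / RMS tables.

The synthetic camera (`spheretrack.simulate`) renders 512×512 16-bit AB/depth
frame pairs at up to 45 Hz with a configurable noise model (sphere-level depth
noise with a common-mode component, per-viewpoint systematic bias, per-pixel
noise, blob-center jitter, dropouts) and generates the standard experiment
protocols: a 20-pose × 30-sample static acquisition over 0.3–1 m, dynamic
sinusoidal trajectories with a leading pure-sinusoid segment for temporal
calibration, and stylus scenes for the US calibration.  See
`docs/methods.md` for the model details and what the simulator does and does
not emulate.

## Worked example

Run the static accuracy protocol — 20 marker poses over 0.3–1 m, 30 frames per
pose, 2 mm depth noise — and score tracking against ground truth with the
Kalman filter on and off:

```python
from spheretrack import NoiseModel, generate_static_experiment, run_static_evaluation

bundle = generate_static_experiment(n_poses=20, samples_per_pose=30,
                                    noise=NoiseModel(depth_sigma=2.0), seed=0)
report = run_static_evaluation(bundle)
for metric, unit in [("d_e_rms", "mm"), ("t_mag", "mm"), ("r_mag", "deg")]:
    for filt in (False, True):
        s = report.summary(metric, filt)
        print(f"{metric:8s} filter={'on ' if filt else 'off'}  "
              f"median {s.median:6.2f}  p75 {s.p75:6.2f}  max {s.max:6.2f}  rms {s.rms:6.2f} [{unit}]")
```

which prints:

```
d_e_rms  filter=off  median   2.44  p75   2.98  max   4.40  rms   2.57 [mm]
d_e_rms  filter=on   median   1.36  p75   1.70  max   3.38  rms   1.52 [mm]
t_mag    filter=off  median   4.79  p75   7.20  max  16.91  rms   6.30 [mm]
t_mag    filter=on   median   3.83  p75   5.48  max  11.46  rms   4.70 [mm]
r_mag    filter=off  median   1.38  p75   1.99  max   3.87  rms   1.65 [deg]
r_mag    filter=on   median   1.27  p75   1.67  max   2.70  rms   1.38 [deg]
```

`d_e_rms` is the per-(pose, sphere) RMS of the relative sphere-distance error
over the 30 samples of each pose; `t_mag`/`r_mag` are the magnitudes of the
relative pose error against the first pose.  The filter roughly halves the
sphere-level distance error and lowers the translation error, while the
rotation error — driven by systematic, per-viewpoint depth biases the filter
cannot remove — barely changes.  On clean (zero-noise) data the same pipeline
reproduces every ground-truth pose to better than 1e-6 mm and 1e-6 degrees.

The same workflow is scriptable from the shell:

```bash
spheretrack simulate --mode static --poses 20 --samples 30 --seed 1 --out run1
spheretrack track --bundle run1 --no-filter --out run1/poses.csv
spheretrack evaluate-static --bundle run1 --out run1/report --plot
```

plus `calibrate-us`, `align-time` and `evaluate-dynamic`; every artifact embeds
the seed and a configuration hash, and identical seeds reproduce outputs
byte-for-byte.

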
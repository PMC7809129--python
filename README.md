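# shankgait

Stride-by-stride spatial gait parameters from a single 6-axis IMU
(accelerometer + gyroscope) mounted on each shank just above the malleolus.

The pipeline reconstructs the per-stride shank trajectory and reports stride
length, stride velocity, stride duration, and shank vertical displacement:

1. **Gait events** (`gait_events`) — SMF/SMB from the integrated sagittal
   tilt, heel strike / toe off / mid-stance from the gyroscope z channel;
   the stream is segmented into `[ms(i), ms(i+1))` gait-cycle windows.
2. **Orientation** (`orientation`) — at every mid-stance the accelerometer
   is assumed to read pure gravity and the orientation is re-initialised by
   gravity alignment; in between it is propagated by first-order quaternion
   integration of the gyroscope.  No smoothing/fusion filter.
3. **Velocity + drift removal** (`velocity_drift`) — lab-frame linear
   acceleration is trapezoid-integrated per segment; the mid-stance shank is
   modelled as an inverted pendulum pivoting about the stationary malleolus,
   giving an update velocity `w × r`; the mismatch between the integral and
   the update velocities at both segment ends fits a linear drift model that
   is subtracted.  A zero-velocity-update (ZUPT) baseline replaces the
   update velocity with zero.
4. **Trajectory + stride frame** (`trajectory_frames`) — corrected velocity
   is integrated to position, and each stride is rotated into a frame whose
   y axis is the inter-mid-stance displacement and x axis the vertical.
5. **Stride parameters** (`stride_parameters`) — length (forward
   displacement between mid-stances), vertical displacement (max vertical
   excursion), duration (heel-strike pair), velocity (length / duration).
6. **Ground-truth simulator** (`synthetic_gait`) — closed-form planar gait
   kinematics (stationary malleolus pivot in stance, smooth lifted swing)
   with configurable sensor noise/bias, so every stage is testable against
   analytic truth without any recorded data.
7. **Agreement statistics** (`validation_stats`) — stride-matched error
   summaries, Pearson correlation, Bland–Altman bias and 1.96-SD limits of
   agreement, plus an IPM-vs-ZUPT comparison harness.

## Conventions

- Lab frame: `x` superior (vertical), `y` forward, `z` lateral; gravity
  direction `[1, 0, 0]`, magnitude 9.80665 m/s².
- Sensor frame: `x` inferior/superior (along the shank), `y`
  posterior/anterior, `z` medial/lateral (sagittal normal).
- Quaternions `[w, x, y, z]`, Hamilton products, canonicalised to `w >= 0`.
- IMU CSV: header `t,ax,ay,az,gx,gy,gz`; accelerometer in m/s², gyroscope
  in deg/s by default (`--gyro-units rad` for rad/s).
- For mirror-mounted sensors (left vs right shank) use `--flip-z` /
  `EventConfig(flip_z=True)` to negate the gyro z channel.

## CLI

```sh
# synthetic trial: IMU CSV + ground-truth positions/events/strides + config
shankgait simulate -o simdir --n-strides 10 --stride-length 1.2 --seed 1

# reconstruct stride parameters from an IMU recording
shankgait reconstruct simdir/imu.csv --r 0.05 --gyro-units rad \
    --method ipm -o strides.csv --trajectory-out traj/

# agreement statistics against a reference stride CSV (e.g. motion capture)
shankgait validate strides.csv simdir/truth_strides.csv -o stats.csv

# side-by-side IPM vs ZUPT report on simulated data
shankgait compare --seed 1 -o comparison.csv
```

`--r` is the sensor-to-malleolus distance in metres.

## Library example

```python
from shankgait import GaitSimConfig, simulate_walk, reconstruct

cfg = GaitSimConfig(n_strides=10, stride_length_m=1.2, fs_hz=100.0)
trial = simulate_walk(cfg)
result = reconstruct(trial.rec, r=cfg.r_m, method="ipm")
for s in result.strides:
    print(s.stride_length_m, s.velocity_mps, s.vertical_disp_m)
```

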
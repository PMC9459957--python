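# phenoscan

Software counterpart of a turntable + 2D-LiDAR platform for 3D phenotyping of
potted maize seedlings. A 2D profile scanner (70° aperture, 0.0833° angular
resolution, 70–300 cm working range) sweeps a laser beam vertically while the
plant rotates on a stepper-driven turntable (0.1° steps through a 1:36 worm
gear); combining the vertical sweep with the rotation yields a full 360° point
cloud of the plant. This package implements everything downstream of (and in
place of) the hardware:

- **Scanner simulator** — ray-casts range profiles of parametric scenes
  (reference cube, planar calibration target, maize seedlings with per-point
  stem/leaf ground truth) under the platform's noise model: Gaussian range
  noise with distance-dependent sigma, grazing-incidence inflation, and
  100-repeat profile averaging.
- **Reconstruction** — the homogeneous-coordinate chain taking each polar
  return (s, θ) at turntable angle ϕ into Cartesian disc-frame coordinates:

      p' = (−s·cos θ, 0, s·sin θ, 1)ᵀ            (sensor plane)
      p  = R_z(ϕ) · T(d, 0, h) · R(φ) · p'       (disc frame)

  with the sensor offsets (d, h) and tilt φ estimated by scanning a
  40 × 4.5 cm planar target standing through the disc center.
- **Metrology** — cube-edge accuracy analysis: individual errors
  |m − Ref|/Ref·100 for the twelve edges U1–U4/L1–L4/D1–D4, per-axis means,
  and the absolute error √(Σ(m−m̄)²/(N(N−1))); plus the precision experiment
  fitting a cubic σ(d) = a₃d³ + a₂d² + a₁d + a₀ to repeated-measurement
  dispersions (d in m, σ in cm; platform values 0.0639, 0.1139, 0.0473,
  0.0589).
- **Phenotyping** — statistical outlier removal, Z-window cropping (pot
  removal), plant height h = max z, and voxel-count volume
  v = c·ΣVᵢ (default c = 2.5×10⁻³ cm³ per occupied voxel).
- **Organ classification** — per-point eigenvalue morphology descriptors
  (linearity, planarity, sphericity, verticality, density, normalized height,
  radial distance to the stem axis), a Random Forest trained with a plant-wise
  60/20/20 train/tune/validate split per growth stage, and an ascending
  virtual-ring filter that relabels stray stem predictions as leaf.

## Worked example

Simulate a noisy scan of the 5.5 cm reference cube at 1 m (one profile per
degree), reconstruct it, and measure its edges:

```sh
phenoscan simulate --scene cube --edge 5.5 --step 1 \
    --distance 100 --height 20 --seed 1 --out-dir demo
phenoscan reconstruct demo/profiles.csv \
    --calibration demo/calibration.json --out demo/cube.txt
phenoscan measure-cube demo/cube.txt --ref 5.5
```

prints (abridged):

```json
{
  "abs_error_cm": 0.00075,
  "accuracy_pct": 0.0387,
  "axis_mean_errors_pct": {"X": 0.0625, "Y": 0.0259, "Z": 0.0278},
  "mean_m_cm": 5.5006
}
```

All twelve simulated edges land within a few thousandths of a cm of the true
5.5 cm: the per-axis mean errors (percent) and the absolute error (cm,
standard error of the twelve measurements) quantify the platform's accuracy
and precision exactly as for the physical device, where surface scattering
and calibration residuals push the same numbers to the percent /
0.03 cm scale.

A plant scan works the same way:

```sh
phenoscan simulate --scene seedling --seedling-height 25 --step 2 \
    --height 25 --seed 3 --out-dir plant
phenoscan reconstruct plant/profiles.csv \
    --calibration plant/calibration.json --out plant/plant.txt
phenoscan phenotype plant/plant.txt --pot-z 0.2
```

```json
{
  "height_cm": 29.605457,
  "n_points_filtered": 30283,
  "n_points_raw": 31271,
  "volume_cm3": 10.0525
}
```

Height is the maximum z of the filtered cloud (leaves arch above the 25 cm
stem tip, hence 29.6 cm); volume is 2.5×10⁻³ cm³ times the number of occupied
voxels. `phenoscan calibrate`, `phenoscan train-classifier`, `phenoscan
classify` and `phenoscan report-table2` cover the remaining pipeline stages;
`report-table2` turns any 12-row edge CSV (columns `ID,Ref,m`) into the full
error report.

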
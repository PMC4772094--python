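# qdtherm

Quantum-dot ratiometric fluorescence thermometry for living cells.

Semiconductor quantum dots red-shift their emission peak as temperature
rises (≈ 0.105 nm/°C), but resolving sub-degree changes from the peak
position directly needs a high-resolution spectrograph. `qdtherm`
implements the alternative: split the emission into two adjacent 20 nm
bands around λₘ = 650 nm and use the **band-intensity ratio**

> R = I(650–670 nm) / I(630–650 nm)

as the thermometric parameter. R rises as the spectrum shifts red, is
measurable with an ordinary two-detector confocal setup, and — being a
ratio of simultaneously acquired intensities — cancels overall
brightness changes from photobleaching or focus drift. With a measured
sensitivity of about 0.062 per °C on a baseline ratio near 1, its
relative sensitivity S = |dR/dT|/R is a few %/K, orders of magnitude
above what the raw peak shift offers.

The package covers the full measurement chain for anyone analyzing (or
simulating) this kind of experiment:

- **`qdtherm.spectral`** — emission-spectrum model, band integration,
  the ratio statistic, closed-form Gaussian band ratio, temperature
  response models, relative sensitivity, Gaussian spectrum fitting.
- **`qdtherm.synthetic`** — a synthetic microscope: spectra, bleach
  traces, calibration series, two-channel spot images, z-profiles and
  voxel cell phantoms, all seeded and emitted with ground truth.
- **`qdtherm.photometry`** — spot detection, 2D Gaussian fitting,
  FWHM diameter estimation, aperture ratio extraction, diameter and
  z-position quality gates.
- **`qdtherm.calibration`** — exponential photobleach fit
  R(t) = (R₀ − R_eq)·e^(−λt) + R_eq and multiplicative correction,
  per-particle R-vs-T calibration lines, ensemble mean slope,
  measurement resolution, reversibility check.
- **`qdtherm.thermometry`** — ΔR → ΔT conversion, stimulus-response
  classification against the resolution, compartment comparison with
  Welch or permutation tests.
- **`qdtherm.shape3d`** — z-stack segmentation and 3D morphometry:
  surface area, volume, sphericity Ψ = π^⅓(6V)^⅔/A and specific
  surface area A/V of cell compartments (the heat-dissipation side of
  the story).

## Worked example

Simulate a three-particle temperature calibration (30–42 °C in 1 °C
steps, noise off), fit the per-particle lines, and convert a
compartment ratio difference into a temperature difference:

```sh
$ qdtherm simulate --preset calibration --seed 7 --out caldata
$ qdtherm calibrate caldata/calibration.csv
qd1: slope 0.074/degC, r 1.000
qd2: slope 0.053/degC, r 1.000
qd3: slope 0.06/degC, r 1.000
mean_slope_per_degC: 0.062
pooled_r: 0.594
```

Each quantum dot responds linearly with its own slope and intercept;
the ensemble sensitivity is the **mean of the per-particle slopes**
(0.062/°C). Note the pooled correlation over all merged points is far
weaker than any individual line — particle-to-particle baseline
differences swamp the shared temperature response, which is why the
calibration is per-particle.

```sh
$ qdtherm convert --delta-r 0.10 --slope 0.062
delta_T_degC: 1.61
```

A cell-body-minus-neurite ratio difference of 0.10 therefore reads as a
≈ 1.6 °C temperature difference. The same conversion runs on sampled
groups with a significance test:

```sh
$ qdtherm simulate --preset compartments --seed 7 --out cells
$ qdtherm compare cells/ratios.csv --slope 0.062
groups: cell_body vs neurite
mean_cell_body: 1.724
mean_neurite: 1.606
mean_diff: 0.118
p_value: 0.000662
delta_T_degC: 1.91
```

(Those numbers are one random draw of 10 spots per compartment; the
generating means are 1.74 and 1.64.)

Other presets exercise the rest of the chain: `spectrum` (ensemble
spectrum → `spectrum-fit`), `bleach` (bleach trace → `bleach-fit`),
`stimulus` (stimulus time course → `classify`), `phantom` (voxel
compartments → `shape`).

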
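# holodm

A simulate–reconstruct–quantify toolkit for label-free cytotoxicity assays by
off-axis digital holographic microscopy (DHM). Synthetic cell populations are
rendered as phase objects, imaged through an off-axis hologram forward model,
reconstructed with a Fourier-method chain, and scored by cell-population
dry-mass time courses and 24-h dry-mass increments with a two-sided t-test /
Bonferroni endpoint.

## Modules

| Module | What it does |
| --- | --- |
| `holodm.phantom` | Ground-truth synthetic cell scenes (paraboloid / hemisphere / disc thickness profiles) with closed-form dry mass, plus scripted 24-h scenarios: exponential or linear growth, arrest, lysis (with debris), delayed toxicity. |
| `holodm.holosim` | Forward model: object wave with optional quadratic aberration and defocus, tilted-reference interference with a spatial carrier, per-frame decorrelated coherent-noise phase screens, detector noise. |
| `holodm.recon` | Reconstruction: FFT sideband location (canonical half-plane), masking + re-centering (tilt removal), inverse FFT to the complex object wave, quadratic-aberration compensation inferred from the sideband, angular-spectrum numerical refocusing, atan2 phase, 2-D unwrapping, multi-frame averaging. |
| `holodm.background` | Rolling-ball background subtraction: true grayscale opening with a spherical-cap structuring element (radian-scaled height), ImageJ-style downscale for large radii. |
| `holodm.drymass` | Phase → population dry mass, `dm = λ/(2πα)·Δφ̄·S_FOV` (α = 0.19 mL/g), per-FOV time courses, 24-h increments, two-sample t-test with Bonferroni correction and the `***`/`**`/`*`/`ns` star convention. |
| `holodm.stackio`, `holodm.config`, `holodm.experiment`, `holodm.cli` | Float32 multi-page TIFF stacks with JSON metadata, YAML/JSON experiment configs, the seeded end-to-end virtual-experiment runner, and the CLI. |

## CLI

```sh
# full virtual experiment: simulate, reconstruct, quantify, test
holodm run-all --config examples/experiment.yaml --out results/run1 --seed 1

# or staged:
holodm simulate    --config experiment.yaml --out holograms/
holodm reconstruct --input holograms/ --out phase/
holodm drymass     --input phase/ --out courses.csv --increments increments.csv
holodm stats       --increments increments.csv --control medium --out stats.csv
```

`run-all` writes `courses.csv` (per-FOV dry-mass samples), `increments.csv`
(per-FOV 24-h increments), `stats.csv` (per-arm mean ± std, t, p, Bonferroni-
adjusted p, stars), a reproducibility `manifest.json`, plots, and (optionally)
the hologram / phase-map TIFF stacks. Runs are deterministic given the master
seed. Exit codes: 0 success, 2 configuration error, 3 data error.

A minimal config:

```yaml
conditions:
  - name: medium
    is_control: true
    scenario: {kind: control-exponential, doubling_time_h: 24.0}
  - name: digitonin
    concentration_ug_per_ml: 500.0
    scenario: {kind: lysis, decline_rate_per_h: 0.05}
n_experiments: 3
fovs_per_condition: 4
timepoints_h: [0.0, 12.0, 24.0]
master_seed: 1
```

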
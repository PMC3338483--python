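# geledge

Quantitative tools for **interfacial mechanical edge effects** in soft 3D
hydrogel culture: what a cell-sized probe feels near the rigid support under
a soft gel, and how encapsulated cells respond to it.

Soft gels (e.g. basement-membrane matrix, E ≈ 450 Pa) are almost always cast
on rigid glass or plastic (E > 100 kPa). Near that interface the gel's
*apparent* stiffness is elevated — a thin soft layer bonded to a rigid base
resists a probe more than a half space does — so cells within a few tens of
micrometres of the bottom live in a stiffness gradient even though the gel
itself is chemically uniform. Glioblastoma cells respond strongly: near the
interface they spread, elongate (spindle morphology) and migrate ~4× faster
than cells deep in the bulk gel.

`geledge` implements that analysis end-to-end:

- **`geledge.fem`** — axisymmetric finite-element indentation of a
  finite-thickness linear-elastic gel bonded to a rigid bottom, by a
  frictionless rigid sphere (R = 5 µm, δ ≤ 5 µm, displacement-controlled
  unilateral contact). Outputs the force–deflection curve, the effective
  stiffness k = slope of F(δ), and von Mises stress fields including the
  stress reaching the gel–glass interface. Validated against the Hertz
  closed form F = (4/3)·E/(1−ν²)·√R·δ^{3/2} and a bonded-layer
  finite-thickness correction.
- **`geledge.morphometry`** — per-plane cell segmentation (Otsu +
  connected components), spreading area and moment-ellipse aspect ratio,
  height-origin normalization, height-binned profiles and exponential-decay
  fits m(z) = m_bulk + (m₀ − m_bulk)·e^{−z/λ}.
- **`geledge.tracking`** — StackReg-style translation registration of
  time-lapse stacks (phase-correlation, subpixel) to remove global gel
  drift, greedy nearest-neighbour linking, and migration speed = path
  length / observation time (µm/hr).
- **`geledge.stats`** — the study's comparisons: pooled/Welch t,
  Wilcoxon rank-sum (exact or tie-corrected normal approximation), one-way
  ANOVA, descriptive mean ± SD.
- **`geledge.synthetic`** — a seeded synthetic-microscopy generator whose
  defaults reproduce the measured condition statistics (areas 1340±470 /
  400±270 / 2309±1232 µm², aspect ratios 10.4±7.3 / 1.6±0.8 / 2.2±1.5,
  speeds 29.5±11.3 / 7.6±3.1 / 28.2±9.7 µm/hr; 20-min frames over 12 h),
  with per-cell ground truth, so every downstream stage is testable without
  the original microscopy data.
- **`geledge.pipeline` / `geledge` CLI** — orchestration, config files,
  CSV/VTK/TIFF I/O, and a one-command reproduction report.

## Worked example: stiffness vs gel height

```python
from geledge.fem import (ElasticMaterial, IndenterSpec, MeshParams, height_sweep)

table = height_sweep(
    heights=[12.5, 25, 50, 100, 200],               # µm
    material=ElasticMaterial(youngs_modulus=450.0, poisson_ratio=0.45),
    indenter=IndenterSpec(radius=5.0, max_depth=5.0, n_steps=10),
    mesh_params=MeshParams(refine_radius=15.0, fine_size=0.5, coarse_size=25.0),
)
print(table)
```

```
   height_um  stiffness_N_per_m   max_vm_Pa  interface_vm_Pa
0       12.5           0.005212  294.656520        49.074950
1       25.0           0.004181  250.682321        11.846572
2       50.0           0.003800  234.702986         2.705963
3      100.0           0.003631  228.432971         0.702302
4      200.0           0.003551  225.690166         0.161913
```

Reading the table: a 12.5 µm gel feels ~1.47× stiffer to the probe than a
200 µm gel, and the stiffening is concentrated below 50 µm — exactly the
height range where cells change behaviour. The von Mises stress reaching
the gel–glass interface collapses from ~17% of the field maximum (12.5 µm)
to ~0.1% (200 µm): in tall gels the indentation field never "sees" the
bottom.

## Worked example: recovering migration speeds through the full pipeline

```python
import numpy as np
from geledge.conditions import PRESETS
from geledge.synthetic import (ImagingConfig, simulate_tracks, apply_drift,
                               render_time_lapse)
from geledge.tracking import analyze_time_lapse

params = PRESETS["40pct_low"]                # interface condition, 29.5±11.3 µm/hr
config = ImagingConfig(image_shape=(1600, 1600), frame_interval=20.0, duration=12.0)
rng = np.random.default_rng(1)
tracks = simulate_tracks(params, 45, config, persistence=0.7, seed=rng, margin_um=280)
drifted, drift = apply_drift(tracks, config, drift_scale=1.0, seed=rng)
stack = render_time_lapse(drifted, config, drift=drift, seed=rng, cell_radius_um=7.0)
_, speeds, offsets = analyze_time_lapse(stack, 20.0, expected_speed_um_hr=params.speed_mean)
print(f"{len(speeds)} tracks, mean speed {speeds.speed_um_hr.mean():.1f} µm/hr")
```

```
41 tracks, mean speed 29.1 µm/hr
```

The measured 29.1 µm/hr recovers the configured 29.5 µm/hr through drift
application, rendering, registration, segmentation and linking — the drift
itself is recovered to <0.2 px RMS.

The CLI exposes the same stages: `geledge fem-sweep`, `geledge
synth-generate`, `geledge morpho-analyze`, `geledge tracks-analyze`,
`geledge stats-compare`, and `geledge reproduce --config
examples/config.yaml` for the full run plus report.

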
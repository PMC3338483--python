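# Full reproduction-run configuration (all keys optional; defaults shown).
# Run with:  geledge reproduce --config examples/config.yaml --out results/run

seed: 1
log_level: INFO

# --- finite-element indentation model -------------------------------------
youngs_modulus_pa: 450.0        # gel modulus E
poisson_ratio: 0.45             # near-incompressible hydrogel
indenter_radius_um: 5.0         # rigid sphere radius (10 µm diameter probe)
max_depth_um: 5.0               # displacement-controlled indentation depth
n_steps: 10                     # load increments tracing the F(δ) curve
heights_um: [12.5, 25, 50, 100, 200]
gel_radius_um: 500.0            # truncated model radius (free side boundary)
mesh_refine_radius_um: 15.0     # fine-mesh zone around the contact
mesh_fine_size_um: 0.5
mesh_coarse_size_um: 25.0
write_fields: false             # set true to export VTK stress fields

# --- synthetic experiment --------------------------------------------------
conditions: [40pct_low, 40pct_high, glass]
comparisons: [[40pct_low, 40pct_high]]
n_cells_tracking: 45            # tracked cells per condition
morpho_cells_per_plane: 9
morpho_n_planes: 4              # 4 fields x 9 cells = 36 cells/condition
track_image_shape: [1600, 1600]
morpho_image_shape: [1024, 1024]
pixel_size_um: 1.0
frame_interval_min: 20.0
duration_hr: 12.0
drift_scale_um: 1.0             # per-frame gel swelling drift magnitude
persistence:                    # directional persistence of the random walk
  40pct_low: 0.7
  glass: 0.7
  40pct_high: 0.2
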
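# Methods

This note documents the models, parameter choices and numerical decisions
behind `geledge`, and what the synthetic-data validation does and does not
demonstrate about real microscopy data.

## 1. Indentation model

**Problem.** A rigid sphere of radius R = 5 µm (a cell-sized probe) is
pressed up to δ = 5 µm into a cylindrical gel disc of height h bonded to a
rigid bottom, with a free side boundary. The gel is isotropic linear
elastic with E = 450 Pa. The central question is how the apparent
(effective) stiffness and the stress reaching the bottom depend on h over
12.5–200 µm.

**Formulation.** Axisymmetric small-strain linear elasticity in (r, z),
discretized with 4-node bilinear quadrilaterals. The volumetric (λ) term is
integrated with a single central point and the shear term with 2×2 Gauss
quadrature (selective reduced integration), which keeps the element usable
near the incompressible limit where fully integrated bilinear elements
lock. Strain components are (ε_rr, ε_zz, ε_θθ, γ_rz); element stresses are
recovered at centroids. Assembly and solves are in SI units; all public
interfaces speak µm/Pa and convert at the boundary, avoiding magnitude
mixing at 1e-6 scales.

**Contact.** The sphere is analytic (never meshed). Frictionless contact
constrains only u_z of top-surface nodes under the sphere:
u_z ≤ g(r) = −δ + R − √(R² − r²). The active set is found by direct
elimination: prescribe u_z = g on a trial set, release nodes whose vertical
reaction is tensile, add free nodes that penetrate, iterate to consistency
(typically 2–5 iterations per load step, warm-started between steps). The
reaction force is the sum of vertical nodal reactions on the contact set.
For linear elasticity this unilateral problem is path-independent; the 10
equal displacement increments exist to trace F(δ), whose superlinear shape
comes entirely from the growing contact area.

**Effective stiffness** is the plain least-squares straight-line slope of
the whole (δ, F) record including (0, 0), with a free intercept. Whether
the original analysis constrained the line through the origin is unknown;
the free-intercept convention was fixed here once. Note that for a Hertzian
F ∝ δ^{3/2} curve the free-intercept slope sits slightly *above* the secant
F(δ_max)/δ_max (continuous-limit ratio 36/35), not below it.

**Boundary conditions and domain.** Bottom: u_r = u_z = 0 (gel bonded to
glass). Axis: u_r = 0. Side: free, at a truncated model radius of 500 µm —
two orders of magnitude beyond the ~5 µm contact radius; the physical
~3.5 mm dish radius would waste elements (doubling the model radius changes
nothing at reported precision).

**Mesh.** Graded structured quads: uniform `fine_size` spacing within
`refine_radius` of the axis at the top surface, growing geometrically
(ratio 1.25, capped at `coarse_size`) toward the side and bottom. Defaults
for the height sweep: fine 0.5 µm, refine 15 µm, coarse 25 µm (≈5k–7k
elements). Halving the fine size changes the effective stiffness by <0.4%
(the test suite enforces <2%). The Hertz validation case (δ = 0.25 µm,
contact radius ≈1.1 µm) uses fine 0.1 µm and agrees with the closed form to
~0.3%.

**Poisson ratio.** The source analysis does not report ν (nor the element
type or solver settings), and exactly ν = 0.5 is singular for displacement
elements. Hydrogels are water-dominated, so the default is ν = 0.45,
configurable. The package's sensitivity test shows the thin-gel stiffening
strengthens as ν → 0.5 but the h = 50 µm ratio k(50)/k(200) remains in the
1.06–1.08 range for all admissible ν — consistent with the bonded
incompressible-layer correction 1 + 1.133χ + 1.283χ² + 0.769χ³ + 0.0975χ⁴
(χ = √(Rδ)/h), which predicts ≈1.09 at this geometry. A ">10% above
baseline" cut-off therefore lands at h = 25 µm, not 50 µm, in this model
class; the qualitative finding (stiffening concentrated below ~50 µm,
negligible above, far below 10-fold) is robust.

**Known limitations.** Small-strain kinematics with fixed geometry: at
h = 12.5 µm the indentation is 40% of the gel height, where a
finite-deformation model would stiffen further; the gel is treated as
purely elastic (no viscoelasticity or poroelasticity); no adhesion, tension
or friction at the contact; no cell–gel coupling.

## 2. Synthetic microscopy generator

The generator emulates the *statistical structure* of the study's imaging:
its defaults are the measured condition statistics (see
`geledge.conditions.PRESETS`): three conditions — 40% v/v gel lowest plane
(interface), 40% v/v gel highest plane (bulk), bare glass — each with
area, aspect-ratio and speed mean ± SD, imaged at 20-min intervals for 12 h.

**Distributions.** Area and aspect ratio are drawn from *shifted gamma*
distributions (support > 0 for area, ≥ 1 for AR) whose mean and SD equal
the configured values exactly by construction. A truncated normal cannot
represent the bulk AR statistics (1.6 ± 0.8 on support ≥ 1 requires more
dispersion than any truncated normal admits, and truncation at 1 would bias
the realized mean by ≈ +0.3 — larger than the recovery tolerance), so the
gamma family is used for bounded-support metrics. Speeds use a normal
truncated at 0, where the truncation bias is negligible (+0.06 µm/hr at
7.6 ± 3.1, +0.15 at 29.5 ± 11.3).

**Two populations.** Near the interface the measured dispersion reflects a
mixture of spindle-shaped and rounded cells. The generator draws spindle
membership with probability `spindle_fraction` (default 0.5 at the
interface; the proportion is not reported) and offsets the component means
by one pooled SD (spindle above, rounded below, shared for area and AR so
spindle cells are jointly large and elongated); a common component SD
absorbs the remaining variance so the *pooled* mean/SD still match the
printed values exactly. Pooled SDs too small to support the separation
raise an error.

**Depth dependence** follows m(z) = m_bulk + (m₀ − m_bulk)·e^{−z/λ} for
every statistic, with λ = 100 µm by default — profiles flatten well before
the >500 µm bulk reference, matching the observed exponential decay of
spreading with distance from the support.

**Still planes** rasterize each cell as a filled ellipse (A = πab,
AR = a/b, uniform orientation) at 1 µm/px, placed uniformly with 3 px
clearance and no border contact, over background 100 with foreground 1000
and additive Gaussian noise (SD 20). Rasterization with pixel-center
inclusion inflates the moment aspect ratio of thin ellipses (~6% at a 5 px
minor axis, <1% at 20 px); pooled-mean recovery is unaffected at the
tested sizes.

**Time lapse.** Per-cell target speed is drawn once; every frame the cell
steps a constant length speed·Δt in a direction following a wrapped-normal
persistent random walk (directional correlation 0.7 for
interface/glass — directed mesenchymal movement — and 0.2 in the bulk).
Path-length speed equals the target exactly by construction, so recovery
error isolates the measurement pipeline. Cells render as 7 µm-radius
disks; start positions sit on a jittered grid with 280 µm margins in a
1600×1600 µm field, sized so that 12-h trajectories (net displacement RMS
≈140 µm at the fastest condition) remain in the field and encounters are
rare — in the real experiment the operator's field/cell selection plays
this role.

**Drift** (gel swelling) is one global offset sequence per field: a
persistent directional component (0.7·scale per frame in a random
direction) plus temporally smoothed wander, default scale 1 µm/frame. The
gel background is textured with ~1000 dim speckles fixed in gel
coordinates; they carry the drift and are the stationary features
registration keys on, as real gel texture was for the original StackReg
alignment. The speckle density is set high enough that the static texture,
not the moving cells, dominates the correlation.

**Not emulated:** optics (PSF, z-blur, vignetting), photobleaching, cell
division, cell–cell adhesion/interaction, z-motion, intensity
heterogeneity within cells. Passing recovery tests therefore demonstrates
the *pipeline's* correctness on data with known truth and realistic
statistics — not robustness to focus drift, clumping or label decay in
real microscopy.

## 3. Morphometry

Global Otsu threshold → 8-connected components → discard regions
< 50 µm² or touching the border; labels are dense from 1. This is an
automated stand-in for the original manual ImageJ analysis ("discrete cells
in focus"), whose inclusion criteria were subjective; the min-area filter
and threshold are configurable. Area = pixel count × pixel_size²; aspect
ratio = major/minor axis of the moment-equivalent ellipse (capped at 100
for degenerate regions). Touching cells merge into one region — a
documented limitation, mitigated in the generator by placement clearance.
Height profiles use bins 0–50, 50–100, 100–200, 200–500, >500 µm (the
study's reporting landmarks), sample SD (n−1), empty bins omitted; heights
are normalized so zero is the first plane containing cells (substrate
roughness makes the true bottom unknowable). The exponential profile fit
uses `scipy.optimize.curve_fit` with λ > 0 bounded, initialized from the
first/last bins; flat profiles are flagged rather than fit (λ
unidentifiable).

## 4. Tracking

Registration is translation-only (rotation/scaling out of scope), each
frame to the first, by phase cross-correlation with 1/20-px upsampled
refinement. The phase (whitened) normalization is essential: plain
cross-correlation locks onto bright moving cells once they decorrelate
from frame 0, while the phase peak follows the dominant rigid component —
the gel texture. Offsets follow the "shift to apply" convention (content
moved by +d gets offset −d); featureless frames get zero offset with a
warning. Applying the offsets to detected centroids, linking is greedy
nearest-neighbour frame-to-frame with links > max_step forbidden
(default 3× the expected per-frame travel); each detection is used once;
unmatched detections start new tracks; there is no gap closing, so a
missed detection splits a track, and tracks observed in <80% of frames are
dropped to avoid short-track bias. Speed is Σ‖Δp‖ / total time in µm/hr —
path length, not net displacement — matching the original definition.
Summaries warn below 15 cells per group.

Measured end-to-end performance on the generator (enforced by tests):
drift recovered to <0.5 px RMS (typically ~0.1); registered speeds within
5% of the undrifted truth; unregistered speeds biased upward whenever
drift ≥ 1 µm/frame — the quantitative reason the pipeline registers first.

## 5. Statistics

Pooled-variance two-sample Student's t by default (the classic "Student's
t-test"; Welch by flag); Wilcoxon rank-sum (Mann–Whitney U) exact for
tie-free pooled n ≤ 20, otherwise the midrank normal approximation with
tie and continuity corrections (both routes exposed since the original
software's choice is unreported); one-way ANOVA (for two groups F = t²
exactly); all p-values two-sided. Degenerate inputs return limiting values
(identical groups → p = 1; zero within-variance with distinct means →
F = ∞, p = 0, flagged) instead of NaN. The exact Wilcoxon path is verified
against full enumeration of rank assignments; all three tests hold 5% ± 1%
type-I error in 10,000-replicate null simulations at n = 30 per group.

## 6. Reproducibility and problem sizes

All randomness flows from `numpy.random.Generator` seeds;
`RunConfig.stage_seed` expands one global seed into independent per-stage
streams via `SeedSequence([seed, crc32(stage_name)])`, so stages replay in
isolation. Identical seeds give bit-identical outputs (enforced for
samples, images and CSVs). The validation suite and the acceptance script
use the study's own problem sizes where stated — 45 tracked cells per
condition at 20-min/12-h sampling, ≥30 cells per condition for
morphometry, the five printed gel heights — and package-chosen
discretizations elsewhere (mesh defaults above; 10,000 null simulations;
10,000-sample moment checks). Every CSV written by the pipeline carries
the configuration hash in a header comment.
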
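# Methods

## Model

### Geometry and steady state

The half-domain assay is modeled as a 2D rectangle: `x` runs along the
experimental axis with the light-dark border at `x = 0`, `z` runs from the
glass surface (`z = 0`, where all cells sit) into the hydrogel. Pheromone
diffuses freely in the bulk (`D ∇²c = 0` at steady state) and reacts only on
the surface, which enters as a flux boundary condition at `z = 0`:

    −D ∂c/∂z = r·ρ_α·production(x) − Ω·ρ_A·uptake(x)·c

with `production` and `uptake` indicator functions of `x`. All other sides
are no-flux walls. Two idealized configurations matter:

- **source**: production on `x < 0`, uptake everywhere. The infinite-domain
  surface profile is `c(x) = c_far · f(x)` with
  `f(x) = Θ(−x) + [cos(u)·sign(u)·(π/2 − Si(|u|)) + sin(u)·Ci(|u|)]/π`,
  `u = x/λ`, `λ = D/(Ω·ρ_A)`, `c_far = r·ρ_α/(Ω·ρ_A)`. `f` obeys
  `f(x) + f(−x) = 1` (so `f(0) = 1/2` exactly) and decays as `λ/(πx)` — a
  heavy tail, not an exponential: a consequence of uptake being confined to
  the surface while diffusion explores the bulk.
- **perfect sink**: production everywhere, and the domain `x > 0` degrades
  the ligand infinitely fast. The surface profile is `g(x) = 2f(x) − 1` for
  `x < 0` and exactly 0 for `x ≥ 0`.

The perfect-sink closed form is the odd reflection of the source solution,
which solves the problem in which the concentration vanishes on the whole
half-plane `x = 0` — i.e. nothing leaks over the top of the sink. The
numerical solver therefore implements the sink as a Dirichlet clamp through
the full gel depth above the marked surface region. This is a genuine
modeling choice: clamping only the `z = 0` line lets pheromone cross the
border through the bulk and converges to a surface profile about 15% of
`c_far` above `g` near the border. The full-depth clamp is the
idealization consistent with the closed form and with the observation that
an effective sink region suppresses responses rather than merely displacing
them.

Concentrations are carried in EC50 units throughout (the EC50 of the
gene-expression response is the natural unit; absolute nM values enter only
as a presentation-layer conversion and are never stored).

### Response model

Readouts are Hill functions of the local concentration,
`θ̂(x) = A·θ(c(x)) + b` with `θ(c) = cⁿ/(1 + cⁿ)` for `c` in EC50 units.
The gene-expression channel (P_FUS1-driven GFP) is non-cooperative (`n = 1`
fixed); the morphology channel (cell length) is switch-like with an integer
`n ∈ 1…7` selected by exhaustive search. The far-field concentration
`C ≡ 2c(0)/EC50` and decay length `λ` are shared between channels — with
two channels of different steepness, `C` and the amplitudes `A` become
separately identifiable even though each single channel would confound
them.

## Numerical solver

5-point Laplacian on a grid that is cell-centered in `x` (so a half-domain
indicator changes value exactly at `x = 0`, the continuum border) and
node-centered in `z` (the Robin row sits at `z = 0`, eliminated via a ghost
node). The sparse system is solved directly (SuperLU); the relative
residual is checked against 1e−10 and a warning is emitted when
`dx > λ/5`. Defaults: `dx = dz = 10 μm`, `L_x = 12λ`, `L_z = 4λ` for
oracle comparisons; the default gel thickness 2,600 μm corresponds to
0.5 cm³ of gel over a 1.554-cm well.

Measured behavior at `λ = 735 μm`, 10-μm resolution: the homogeneous-mask
limit reproduces `c_far` to ~1e−12; the source surface profile matches the
closed form within 0.6% of `c_far` over `|x| ≤ 3λ` (the residual is
dominated by domain truncation, not discretization); the sink profile
matches within 1.7%, limited by the Robin/Dirichlet corner singularity at
the border, near which convergence is first-order (self-convergence away
from the corner is better than first order). Flux conservation
(production = uptake + sink flux) holds to rounding.

## Synthetic data generator

Emulates the segmentation pipeline's per-object table: identity
(emitter/receiver), position (μm), area (pixels), mean GFP (a.u.), plus
cell length (μm) and ellipse orientation (degrees). Defaults reproduce the
study conditions: 6,686 receivers uniformly over ±2,700 μm (a ~5.4-mm
stripe, 330 μm wide), generator truth λ = 735 μm, C = 1.45, morphology
n = 3, gene-expression n = 1. Amplitudes and baselines default to
A_g = 1 a.u., b_g = 0.1 a.u., A_m = 25 μm (shmooing roughly quintuples the
5-μm round-cell length), b_m = 5 μm (one cell diameter) — conventional
readout scales, as the experimental per-channel calibrations are not part
of the model.

Noise model: GFP is the model mean times a mean-one lognormal factor with
CV 0.30 (typical yeast gene-expression variability; the choice is stated
explicitly because downstream recovery statements depend on it); length is
the model mean plus Gaussian noise of SD 1.5 μm (mean-field mode), or a
round/elongated two-component mixture whose mixing weight is the Hill
probability (bimodal mode — per-bin means are identical by construction).
Orientations are uniform on (0, 180]: the generator encodes the observed
absence of gradient alignment as its null. Segmented area scales with cell
length (24 px/μm, SD 12 px), so the conventional 200-px area cutoff
separates elongated from round cells. Emitters carry no readouts.

What the generator does **not** emulate: cell clumping and spatial
aggregation, segmentation errors and debris, position-dependent cell
density (growth), illumination inhomogeneity, prezygotes/diploids, and any
transient (pre-steady-state) behavior. Passing recovery tests therefore
demonstrate estimator correctness under the stated noise model, not
robustness to every artifact of real microscopy.

All randomness flows from one explicit seed; identical seeds give
byte-identical tables. Tables are written as CSV with a `#`-commented YAML
metadata header (seed and all generator parameters); files carrying only
the four segmentation-pipeline columns (identity, x_um, area_px, gfp_au)
are accepted on read, with length/orientation marked absent.

## Inference pipeline

- **Binning**: 100-μm bins anchored at the leftmost cell, per-bin mean,
  SEM (= sd/√n, 0 for singletons) and count; empty bins dropped; bins
  intersecting the leftmost 100 μm excluded by default (the experiment
  trims cells near the reflective wall, where accumulation is not modeled;
  the trim width is exposed as a parameter since the study states no
  number). At study scale this yields 53 retained bins.
- **Joint fit**: for each integer morphology coefficient n, the six
  continuous parameters (λ, C, A_g, b_g, A_m, b_m) are fitted by bounded
  trust-region least squares (λ ∈ [10, 5000] μm, C ∈ [0.01, 100], A ≥ 0,
  b free) with 8 multi-starts from a coarse (λ, C) log-grid and
  data-driven amplitude initialization; the n with minimal loss wins, ties
  resolved toward the smaller (more parsimonious) n.
- **Loss weighting**: residuals are weighted by 1/SEM by default. The two
  channels live in incommensurate units (a.u. vs μm) with amplitudes
  differing by a factor ~25; an unweighted sum of squares is dominated by
  the morphology channel, which alone cannot separate (λ, C, n) — measured
  at study scale, the unweighted joint fit drifts to λ ≈ 1000 μm with
  n = 4 preferred in half the ensembles, while the inverse-SEM fit recovers
  λ within 2%, C within 1% and n = 3 in 20/20 ensembles. Raw unweighted
  SSE remains available as an option. When all SEMs are zero (noiseless
  data) weights fall back to 1.
- **Degeneracy and diagnostics**: λ or C pinned at a bound and a flat SSE
  landscape over n (e.g. a morphology channel with no signal) are flagged
  rather than silently returned.
- **Perfect-sink prediction**: the source-experiment fit pushed through the
  sink profile with zero refitting — flat at b_m for x > 0, rising on the
  diffusion side with the same λ, C, A_m, b_m, n.
- **Orientation test**: axial orientation angles are doubled onto the
  circle and tested for uniformity with the Rayleigh test, restricted to
  cells above an area cutoff (elongation proxy; default 200 px).

## Numerical and design choices

- Si/Ci come from `scipy.special.sici`; for `|x|/λ < 1e−8` the analytic
  border limits (f = 1/2, g = 0) replace the direct expression, whose
  `sin(u)·Ci(u)` term is a removable singularity at 0.
- The border gradient is reported as a centered finite difference over
  δ = 5 μm (one cell diameter) because the true derivative diverges
  logarithmically at the border; with λ = 735 μm and C = 1.45 this gives
  3.8×10⁻³ EC50/μm. Any finite-difference convention at a log-divergent
  point carries an O(ln δ) convention dependence, so this number is an
  order-of-magnitude diagnostic, not a sharp constant.
- Self-consistency of the fit is defined on noiseless cells placed exactly
  at bin centers (recovery to optimizer tolerance, ~1e−10 relative).
  Cell-averaged bins carry an O(width²) binning bias relative to the model
  at the bin center: measured 0.4% (n = 1 channel) and up to 1.4% in the
  border bin of the switch-like n = 3 channel, whose curvature is largest
  where the concentration slope log-diverges.
- Problem sizes: recovery experiments use 20 ensembles of 6,686 receivers
  (the study-scale table) and complete in about a minute; oracle
  comparisons use the fitted λ = 735 μm on a 882×295 grid (~4 s per
  solve).

## Known limitations

- The solver is 2D (stripe cross-section); the real well is a cylinder,
  and lateral averaging over the 330-μm stripe width is ignored.
- Transient dynamics (gradient establishment, Bar1 transport) are out of
  scope; everything is steady state.
- The perfect sink is an idealization; a finite Bar1 activity would
  interpolate between the source and sink profiles and is not modeled.
- Absolute concentration calibration (nM) is intentionally not performed;
  all concentrations are in EC50 units.
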
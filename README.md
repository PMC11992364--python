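# pherograd

Reaction-diffusion modeling and inference of surface-generated yeast
pheromone gradients.

## The problem

In mating populations of *Saccharomyces cerevisiae*, MATα cells secrete the
peptide pheromone α-factor, and MATa cells read its concentration to decide
whether to induce mating genes (a graded, Michaelian response through
P<sub>FUS1</sub>) and whether to arrest and elongate into shmoos (a
switch-like response). In a half-domain assay, a monolayer of cells attached
to glass under a thick hydrogel produces pheromone only on one side of a
light-dark border; receiver responses read out along the axis perpendicular
to the border constrain the shape of the collectively generated gradient.

`pherograd` implements the steady-state biophysics of that assay and the
statistical pipeline that turns single-cell readouts into gradient
parameters, for quantitative biologists who want to model, simulate or
re-analyze surface-generated signaling gradients.

## The model

Pheromone with diffusivity *D* obeys Laplace's equation in the gel, with all
chemistry on the cell layer at *z* = 0: surface production at rate
*r·ρ<sub>α</sub>* on the illuminated domain and surface uptake at rate
*Ω·ρ<sub>A</sub>·c* everywhere. The surface concentration at steady state
depends on a single decay length

&nbsp;&nbsp;&nbsp;&nbsp;λ = D / (Ω·ρ<sub>A</sub>)

and interpolates, through a closed form built from the sine and cosine
integrals Si and Ci, between the far-field value
c<sub>far</sub> = r·ρ<sub>α</sub>/(Ω·ρ<sub>A</sub>) in the production
domain and a heavy λ/(πx) tail in the dark domain, crossing exactly
c<sub>far</sub>/2 at the border. When the illuminated domain instead
secretes the α-factor protease Bar1 (a perfect sink), the concentration
vanishes there and follows the odd reflection 2f(x) − 1 of the source
profile on the diffusion side.

Cellular readouts are Hill functions of the local concentration in EC50
units, θ̂(x) = A·cⁿ/(1 + cⁿ) + b, with n = 1 for gene expression and an
integer n fitted for morphology. Binned gene-expression and morphology
profiles are fitted jointly by bounded least squares with λ and the
far-field concentration C = 2c(0)/EC50 shared between channels; the
morphology Hill coefficient is selected by exhaustive search over n = 1…7.

The package provides:

- `pherograd.profiles` — closed-form profiles, Hill responses, diagnostics;
- `pherograd.pde` — a sparse finite-difference steady-state solver (the
  brute-force oracle for the closed forms, and the route to finite-size and
  above-surface behavior);
- `pherograd.simulate` — synthetic single-cell tables emulating segmented
  microscopy output (positions, GFP, cell length, area, orientation);
- `pherograd.fit` — binning, joint fitting, normalization, zero-parameter
  perfect-sink prediction, parameter-recovery experiments, orientation
  (chemotropism) tests;
- a `pherograd` command-line tool (`profile`, `simulate`, `fit`,
  `predict-sink`, `oracle`, `recover`) for reproducible runs.

## Worked example

Generate a synthetic half-domain experiment (4,000 receiver cells, 30%
GFP noise, 1.5 μm length noise) from the gradient λ = 735 μm, C = 1.45,
morphology Hill coefficient 3, then re-infer the parameters:

```sh
pherograd simulate --n-receivers 4000 --n-emitters 0 --seed 21 -o sim
pherograd fit sim/cells.csv -o fit
```

which logs

```
INFO pherograd: wrote 4000 cells to sim/cells.csv
INFO pherograd: fit: lambda=753.5 um, C=1.423 EC50, n_m=3 (SSE by n:
  {1: 1126.2992, 2: 195.0435, 3: 116.1809, 4: 125.3838, 5: 153.4586,
   6: 184.8539, 7: 214.9272})
```

`fit/fit.json` holds the full report: the decay length is recovered at
753.5 μm (2.5% from the generating 735 μm), the far-field concentration at
1.423 EC50 (1.9% from 1.45), and the integer-n scan is minimized at n = 3 —
the generating coefficient — with the n = 1 alternative (no morphology
cooperativity) clearly rejected. The amplitudes and baselines
(A_g = 1.02 a.u., b_g = 0.096 a.u., A_m = 25.7 μm, b_m = 4.98 μm) match the
generator (1, 0.1, 25, 5). A zero-parameter prediction for the
complementary Bar1 perfect-sink experiment follows from the same report:

```sh
pherograd predict-sink --fit-report fit/fit.json -o sink
```

The predicted morphology profile is flat at the baseline b_m everywhere in
the sink domain and rises on the diffusion side with the same λ.

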
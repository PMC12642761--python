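# Methods

## Model

The package models four Alzheimer's-disease biomarkers on a weighted,
undirected brain graph `G` with `n` nodes (the Desikan–Killiany 68-region
cortical parcellation by default; any `n` is supported for testing).  Edges
come from resting-state functional connectivity: a pair of regions is
connected when its Pearson correlation exceeds `r_min = 0.75` with p-value
below `1e-5` (both strict), the surviving correlation being the edge weight.
With adjacency `A`, degree `d_i = Σ_k a_ik` and combinatorial Laplacian
`L = diag(d) − A`, the dynamics are

    dAb/dt  = −D_Ab  L Ab  + λ_Ab  ∘ Ab  ∘ (K_Ab − Ab)
    dτ/dt   = −D_τ   L τ   + λ_τAb ∘ Ab + λ_τ ∘ τ ∘ (K_τ − τ)
    dN/dt   = −D_N   L N   + λ_Nτ  ∘ τ  + λ_N ∘ N ∘ (K_N − N)
    dC/dt   =  λ_CN ⟨N⟩_d  + λ_C C (K_C − C)

where `∘` is elementwise, `⟨N⟩_d = Σ_v d_v N_v / Σ_v d_v` is the
degree-weighted brain total, and `C` is a whole-brain scalar with no
diffusion term.  The three diffusivities `D_*`, the cognition couplings
`λ_CN`, `λ_C` and capacity `K_C` are global scalars; the logistic rates,
cascade couplings and capacities of the regional equations are vectors over
regions — 6 global + 8 regional parameters in total.  Since `L` is positive
semidefinite and annihilates constants, the `−D L y` terms are dissipative
and act only on regional heterogeneity.  All biomarkers live on a normalized
severity scale: amyloid and tau PET SUVRs are divided by a per-(biomarker,
region) reference value (cohort maximum by default, so end-stage values
approach 1), cortical thickness becomes `N = 1 − thickness/ref`, and MMSE
becomes `C = 1 − score/30`.

The model clock is chronological age with a common origin `t0 = 50` years and
horizon `t_end = 100`; trajectories are integrated with adaptive RK45
(`rtol 1e-6`, `atol 1e-8` by default).

### Patient-specific connectivity

A patient's adjacency deviates from the population mean `Ap` by a symmetric
rank-2 update `A = Ap + (u vᵀ + v uᵀ)/2 − diag(u∘v)`; the diagonal correction
removes the self-connections the update would otherwise introduce.  The
patient Laplacian has the closed form
`L = Lp + diag(u(vᵀ1) + v(uᵀ1))/2 − (u vᵀ + v uᵀ)/2`, which equals the
Laplacian of the updated adjacency exactly (the two diagonal corrections
cancel); this identity is verified to `1e-12` on random instances at
`n ∈ {4, 10, 68}` and serves as the primary correctness oracle for the graph
algebra.  Feasibility means every perturbed off-diagonal weight stays in
`[0, 1]`; new edges may "light up" inside the box.

## Inference

Each subject is fitted by minimizing, over parameters, initial state and
connectivity perturbation,

    Σ_i ‖y(t_i) − ỹ(t_i)‖² / ‖ỹ(t_i)‖²  +  w ‖y(100) − 1‖²

subject to the weight-box constraints, where the sum runs over visits and the
endpoint penalty enforces end-stage saturation of the normalized biomarkers.
The problem is split into four stages, each warm-starting the next:

1. **Homogenized**: every regional parameter and initial value is a shared
   scalar.  A uniform state is invariant (`L·1 = 0`), so each equation is
   integrated as its exact scalar reduction, in cascade order, with the
   previously fitted upstream trajectory as forcing.  The diffusivity has
   *exactly zero* gradient in this stage and is therefore not a stage-1
   variable.
2. **Regional parameters**: sparse deviations `ε` from the stage-1 scalars
   with an L1 penalty `w_reg‖ε‖₁`; the equation's diffusivity is co-fitted
   here, where regional structure first makes it observable.
3. **Regional initial conditions**: sparse deviations `ε_y0` with penalty
   `w_0‖ε_y0‖₁`, growth parameters frozen; the diffusivity is refined jointly,
   because the decay of initial regional spread is its main observable
   signature.  Initial values are optimization variables (never read off the
   first noisy visit) and are clipped to `[0, min(1, K)]` per region.
4. **Connectivity**: `(u, v)` under the weight-box constraints (SLSQP), with
   soft unit-norm penalties `w_u(‖u‖−1)² + w_v(‖v‖−1)²` and L1 sparsity
   `w_su‖u‖₁ + w_sv‖v‖₁`; model parameters frozen.

Bounds follow the published amyloid boxes — `D ∈ [0,2]`, `λ ∈ [0,2]`,
`K ∈ [1,2]`, `y0 ∈ [0,1]` — reused for the analogous parameters of the other
equations; `ε` is bounded so the summed parameter stays in its box.

**Homotopy regularization.**  Every regularization coefficient
(`w, w_reg, w_0, w_su, w_sv`) follows the schedule `1000, 100, 10, 1`
(start 1000, decay 10, four stages), each solve warm-started from the
previous, heavier-regularized solution.  Configured weights act as terminal
values and scale the whole path.  The unit-norm weights `w_u, w_v` are held
constant; their default is 0.1, chosen so that the terminal L1 weight
dominates — at 1.0 the norm pull manufactures a spurious perturbation even
when the data were generated on the population graph.

**Multistart.**  Stage-1 candidates are a data-informed heuristic (baseline
from the first visit's level, capacity from the last), half uniform and half
log-uniform draws over the boxes (rate-like parameters are log-scale
quantities; uniform draws essentially never sample the small-coupling corner
where the cascade's timing lives).  Candidates are screened on the
terminal-weight objective and the homotopy path is run fully from the best
two; the best terminal solution wins.  Ten candidates by default, all
randomness from one seeded generator, so identical seed + config + data give
an identical fit.

**Train/test protocol.**  By default the last visit of each modality is held
out; accuracy is `100·(1 − Σ_i‖y(t_i) − ỹ(t_i)‖₂ / Σ_i‖ỹ(t_i)‖₂)` per
biomarker (clipped below at 0), pooled over visits.  The homogeneous (H,
stage 1) and nonhomogeneous (NH, stages 1–3) models are scored on the same
held-out visits within a single pipeline run.

### Numerical choices

* Objective evaluations integrate on a fixed 101-point age grid with
  classical RK4, substepped per interval so that `h·D·λ_max(L)` stays inside
  the stability region (`λ_max` bounded by twice the maximum degree);
  predictions at visit ages use linear interpolation on the grid.  Reported
  trajectories and accuracies always come from the adaptive RK45 solver.
* Relative-error denominators `‖ỹ(t_i)‖²` are floored at `(0.05)²` per
  observed value: a single near-zero cognition visit otherwise contributes a
  term of order `1e2–1e6` and drives the fit into degenerate corners.  The
  0.05 floor is ~2.5× the default observation noise.
* L-BFGS-B for the box-constrained stages (1–3), SLSQP for the constrained
  connectivity stage; gradients by finite differences.  Iteration caps per
  homotopy stage: 60 / 15 / 15 / 20 for stages 1–4.
* Integration blow-ups during optimization return a large sentinel value
  rather than raising, so the search simply avoids that region.

### Identifiability at desk scale — what fitting can and cannot recover

Quantified on synthetic data during development, these are properties of the
objective, not bugs:

* At the terminal L1 weight 1, mild (~25%) regional heterogeneity costs more
  in `‖ε‖₁` than it earns in data fit, so `ε` activates only for strong
  regional outliers.  This matches the small homogeneous-vs-regional accuracy
  gaps the method reports on real cohorts.
* The diffusivities are nearly flat directions of the profiled loss on sparse
  visit schedules: with `ε ≈ 0` the fitted state is uniform and `D` has zero
  gradient.  Reported `D` values remain close to their fixed initialization
  (0.3) and should not be interpreted as measurements.
* The cognition couplings are degenerate when decline is logistic-dominated
  (an unforced logistic can mimic the forced trajectory); they are best
  identified in the forcing-dominated regime, and then only to ~±30–50% from
  half a dozen visits at noise 0.02.

## Synthetic cohorts

The generator emulates the structure of a multi-modality longitudinal aging
study: 4–7 irregular visits per subject in the 55–95 age window (inclusion
requires ≥3 in a regional modality), per-subject missing modalities
(defaults: tau and neurodegeneration each absent in 20% of subjects,
cognition in 10%), additive Gaussian noise (σ = 0.02) on the normalized scale
clipped at 0, and per-subject connectomes that are sparse rank-2 deviations
(3 active entries per vector, scale 0.1, rescaled into the feasible box) from
a population graph with Bernoulli(0.15) edges weighted Uniform(0.75, 1)
(redrawn until connected — the sparse regime of a correlation-thresholded
connectome, where diffusion does not instantly homogenize the fields).

Ground-truth draws place the cascade inside the observation window: amyloid
logistic rates 0.08–0.16/yr with regional baselines Uniform(0.02, 0.3)
(early-accumulating regions start higher), tau/neurodegeneration rates
0.2–0.4/yr ignited by couplings of 0.004–0.01/yr from essentially zero
baselines, cognition driven by `λ_CN ∈ [0.03, 0.06]` against a gentle
intrinsic rate `λ_C ∈ [0.15, 0.3]` from a zero baseline, and capacities
1.0–1.2 (the normalized scale saturates near 1, consistent with the
end-stage penalty).  Regional spread is multiplicative: rates vary by the
heterogeneity scale (default 25%), capacities by half of it.  Diffusivities
are Uniform(0.1, 0.5).

What passing tests on these cohorts do **not** show about real data: the
generator's noise is homoscedastic Gaussian and visit-independent, modalities
are missing completely at random, the connectome prior is Erdős–Rényi rather
than anatomically structured, and the ground truth is the fitted model class
itself — there is no model misspecification, so real-data accuracy will be
lower and parameter interpretability weaker than the synthetic numbers.

## Sensitivity analysis

Sobol indices are estimated with the Saltelli block design (base sample a
power of two, scrambled Sobol' QMC): `S1` by the Saltelli (2010) estimator,
`ST` by Jansen's, `S2` by the cross-block formula, all after centering the
evaluations (the estimators are shift-invariant only in expectation, and a
large output mean amplifies finite-sample imbalance).  Zero output variance
yields zero indices with a warning.  Bootstrap over sample rows (200
resamples) gives confidence half-widths.  On problems with ≤3 factors the
estimates are cross-checked against conditional-variance quadrature on a
dense grid, and against an independent library implementation of the
first/total-order estimators.

* **Level 1** homogenizes all 14 parameters and tracks the total index of
  C(t) on an age grid; near-constant output at early ages is flagged and
  reported as zero.  Base sample 256 by default (1024 for the generic
  estimator), scalable.
* **Level 2** varies one region-specific parameter across regions with
  everything else fixed, the output being the degree-weighted total of that
  parameter's own biomarker at fixed stage ages (60, 80, 100 by default) from
  a cohort-mean state at age 50.  First-order indices are summed within
  anatomical lobes; second-order indices are summed over region pairs
  spanning each lobe pair.  The shipped lobe map follows standard
  Desikan–Killiany anatomy (index order: left then right hemisphere,
  FreeSurfer `aparc` alphabetical) and is user-overridable; region rankings
  use S1 with ties broken by ST, then index.

## Known limitations

* The connectome is static over a subject's lifespan, undirected and
  positively weighted; negative correlations are discarded.
* Finite-difference gradients make stage 2 the cost bottleneck; at `n = 68`
  with dozens of visits a fit takes correspondingly longer than the
  desk-scale studies here (minutes per subject at `n = 8`).
* The endpoint penalty biases recovered capacities toward 1 whenever the true
  trajectory saturates elsewhere; this is inherent to the objective.
* No uncertainty quantification on fitted parameters; the bootstrap applies
  only to Sobol indices.
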
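# Methods

## Model form

A kinetic model is the mass-balance ODE system dm/dt = S·v(t, m, θ) over
the *dynamic* species of an SBML document (constant/boundary species are
substituted as numeric constants at flattening time and excluded from the
state).  Rates are interpreted in concentration units: each species' row of
S·v is divided by its compartment size, which matches SBML semantics for
concentration-based species and is a no-op for unit compartments.  The
right-hand side is a pure function of (t, m, θ): flux expressions and their
Jacobians ∂v/∂m, ∂v/∂θ are compiled once from sympy into vectorized numpy
functions, and all evaluation is batched over parameter vectors.

Supported SBML subset: species, compartments, global and (namespaced)
local parameters, reactions with MathML kinetic laws, assignment rules,
initial assignments, function definitions (inlined at parse time).  Events,
delays, algebraic rules, rate rules and SBML packages are rejected with an
explicit error — silent misparsing of an unsupported construct would
corrupt every downstream number.  Local parameters are renamed
`<reaction>__<param>`, which is deterministic and reversible.  Units are
parsed but never used for computation; species declared as amounts are
converted to concentrations by dividing by compartment size once, at parse
time.  MathML is converted to sympy directly on the AST (no formula-string
round trip), so numeric literals keep full binary precision on input; on
*output* libsbml's MathML writer prints at most 15 significant digits, so
one export may move a constant by 1 ulp — the export/import cycle is
exactly idempotent from the second round trip onward.

## Simulation

`KineticModel.simulate` integrates with scipy's Radau solver — 5th-order,
implicit, A-stable, with adaptive steps and an analytic state Jacobian
assembled from the compiled flux Jacobians.  Defaults: rtol 1e-8,
atol 1e-11, initial step 1e-10, at most 1e6 right-hand-side evaluations.
Integration failures (step-size underflow, step budget, non-finite state)
are *returned* as unsuccessful trajectories with a diagnostic rather than
raised, so that multi-start screens can count them.  The sampling grid is
exactly the requested times; when fitting, that is the observed times of
the dataset, and the integration starts at the dataset's first time (which
need not be 0).  Initial conditions come from the dataset where observed
(earliest time point, non-missing), falling back to the model's declared
initial values per species.

## Loss

The default loss is the mean-centered squared error

J = (1/N) Σ_{s,t non-missing} ((m_pred[s,t] − m_obs[s,t]) / ⟨m_obs[s]⟩)²

with ⟨m_obs[s]⟩ the per-species mean over that species' non-missing
observations and N the count of non-missing (species, time) pairs.  The
per-species normalization makes metabolites with very different
concentration scales contribute comparably, and makes J invariant to
jointly rescaling a species in predictions and observations.  Only species
present in the dataset enter the loss; unobserved model species are free.
A species whose observed mean is zero cannot be normalized and is rejected
with an explicit error.  Other losses can be plugged in via the trainer
configuration (`loss_cls`), provided they expose a value and a gradient
with respect to the predictions.

## Gradients

Training gradients are computed by *discrete backpropagation* through a
fixed-grid classical Runge–Kutta (RK4) integration: the forward pass runs
on the observed time points with each interval subdivided so no step
exceeds span/`grid_resolution` (default 200), storing the stage states; the
backward pass reverses every stage with vector–Jacobian products of the
right-hand side.  Because the backward pass is the exact transpose of the
forward computation, gradients agree with central finite differences of the
discrete loss to near machine precision (the standing test requires 0.1%
in log space), and the per-iteration cost is independent of the number of
parameters — which is what makes joint training with ~500 neural-network
weights affordable.  The whole forward/backward pass is vectorized over a
batch of parameter vectors, so a multi-start screen is one loop, not n.

The trade-off of a fixed grid is stiffness: a parameter draw that makes the
system stiff beyond the grid's stability limit produces a non-finite state,
which the engine detects, freezes, and reports as a failed run.  In
screening this plays the same bookkeeping role as an adaptive solver's
step-size underflow — the draw counts as a failed initialization (or a
failed training iteration).  Adaptive stiff integration remains available
for simulation; for training stiff systems, increase `grid_resolution`.

## Optimization

Positivity-flagged parameters (all kinetic parameters by default) are
log-transformed; the optimizer works on φ = log θ and every iterate maps
back to strictly positive values.  Neural-network weights are updated in
linear space.  The per-iteration sequence is: loss + gradient on the full
dataset (no mini-batching) → elementwise averaging across datasets when
fitting several at once → clipping of the global L2 norm at ĝ = 4 →
one AdaBelief update (β1 = 0.9, β2 = 0.999, ε = 1e-16, following the
optimizer's published formulation with bias correction on both moments) at
learning rate 1e-3.  Training stops early when J < 1e-6; the reporting
threshold for a "successfully trained" run is J < 1e-3; the iteration
budget defaults to 3000 (large models typically need 10000).  On an
integration failure mid-training the run is marked failed at that
iteration and the best-so-far parameters are returned.  When several
datasets disagree on N, gradients (not losses) are averaged; the reported
loss is the mean of per-dataset losses.  The trace records the loss and
the pre-clip gradient global norm every iteration, plus optional parameter
snapshots.

## Synthetic data and screening

The generator samples ground-truth trajectories at `points_per_species`
(default 10) uniformly spaced times including both endpoints — sparse
sampling on purpose, since real biotechnological time series rarely have
more — with every dynamic species observed at every time, so a 6-species
model yields 60 observations.  Noise, when requested, is multiplicative
Gaussian y·(1+ε) with ε ~ N(0, (noise_pct/100)²); "0.05" means 0.05%,
i.e. a relative standard deviation of 5e-4.  The generator emulates the
noiseless/low-noise, uniformly sampled, fully observed regime; real data
additionally have missing species, irregular sampling, and structured
(non-multiplicative) error, so passing screens here demonstrate correctness
of the machinery, not robustness to those complications.

Multi-start initializations are Latin-hypercube samples within
θ_true/X ≤ θ ≤ X·θ_true, stratified in log10 space (parameters span
decades; linear stratification would oversample the top decade) — each of
the n equal-log-width bins per dimension holds exactly one sample
(scipy's LHS engine, seeded).  A start is *initialization-successful* iff
loss and gradient evaluate finite there; *training success* means the
final loss after at most 3000 iterations is below 1e-3, counted against
all n starts, so it can never exceed the initialization success rate.
Per-run relative improvement is r = (J_init − J_final)/J_init, defined as
0 when the start is already converged (J_init < 1e-6).  Experiments are
replicated three times by default; replicates differ only in RNG seed, and
identical seeds reproduce a screen bitwise.

Built-in fixtures (all simulable at their true parameters): f1 — 1-species
exponential decay (k = 0.5, m0 = 2, horizon 5); f2 — 3-species mass-action
chain A→B→C (k = 0.7, 0.3, horizon 10); f3 — 2-step reversible
Michaelis–Menten pathway A⇌B⇌C in Haldane form with fixed keq per step
(6 trainable parameters, horizon 20); f4 — 6-species mass-action ring
(6 parameters, horizon 6, mirroring the size/horizon of published minimal
biofilm-oscillation models).

## Hybrid models

Masking reaction i removes column i of S and flux i of v; parameters used
only by that reaction leave the trainable registry.  The neural flux term
is an MLP taking (t, m) — time can be disabled for autonomous modeling —
with two hidden layers of 16 softplus units and a *zero-initialized* linear
output head of dimension n_species.  The output is added directly to
dm/dt: the network lives in species space and absorbs the unknown
stoichiometric column, so no stoichiometry is learned separately.  Zero
initialization makes "hybrid ≡ masked model before training" an exact,
testable contract and keeps early training stable.  In the masking
experiment each reaction is masked in turn, a noisy dataset (100 points,
0.05% noise by default) is generated from the full model, and the trained
hybrid is scored by its mean-centered loss against the *noiseless* truth
on the training grid; below 1e-2 (configurable) counts as recovered.

## Problem sizes and numerical choices

The test suite and the acceptance script run the screening experiments at
scaled-down sizes chosen as this package's own defaults for desk-scale
verification: 20 LHS starts (not 100) for the chain and decay screens, and
a single masked reaction of the ring fixture trained for 1500 iterations on
a grid of ~80 steps for the hybrid demonstration (the loss crosses the
recovery threshold within the first ~30 iterations; the remaining budget
only tightens the fit).  Full-size runs (n = 100, 3 replicates, all
reactions masked, 3000+ iterations) use the same code paths through
`replicated_screen`, `masking_experiment` and the CLI.

Ties and degenerate inputs: X = 1 collapses the LHS band to θ_true exactly;
duplicate observation times map to one integration node; a dataset with a
single time point yields predictions equal to the initial conditions and a
zero gradient.  Standard errors (`FitResult.bse`) use a Gauss–Newton
J'J approximation with a central finite-difference residual Jacobian in
log space — adequate near a good optimum, unreliable for sloppy directions.

## Known limitations

* No events, delays, algebraic or rate rules, or SBML packages; no unit
  inference or conversion.
* Fixed-grid RK4 for training gradients: very stiff regions of parameter
  space fail (and are counted) rather than being integrated slowly.
* No steady-state root-finding solver; steady-state observations are
  handled as long-horizon time points.
* No mini-batching, second-order methods, global optimizers, or Bayesian
  posterior sampling.
* Single-reaction masking only; no architecture search for the neural
  flux term.
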
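# Methods

This note records the model as implemented, the parameters that matter, and
the design choices made where the problem was genuinely open.  It is the
companion to the README's summary; nothing here states a result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Environment and trajectory

The environment is a square of side 1 m with periodic boundary conditions (a
torus), discretised for analysis into an 8×8 grid of 12.5 cm bins.  The
virtual rat moves 2.5 cm per 125 ms time step (one theta period, 20 cm/s) in
a persistent random walk: the heading accumulates Gaussian increments of
SD `heading_noise_sd` per step.  The magnitude of that noise is not a
published quantity; the default 0.35 rad was chosen so that a 10,000-step
session covers all 64 bins with high probability while keeping the walk
visibly persistent, and it is configurable.  Gaussian (rather than uniform)
increments were chosen as the least-structured symmetric choice.  All
distances use the minimum-image convention; bins are half-open and
row-major; the trajectory itself is continuous and binned only at analysis
time.

## DG population

Each granule cell is active in the environment with probability
`p_DG = 0.033`; active cells receive `Q ~ Poisson(q)` Gaussian fields of
width σ_f and height β₀ centred uniformly on the torus.  `q = 1.7`,
`β₀ = 1` (rates are in arbitrary units) and `σ_f = 0.1 m` are defaults of
this package, not published values: q sits in the regime of sparse
multi-field granule maps, σ_f at a typical field scale, and the analysis
layer is insensitive to these choices because CA3 activity is re-normalised
by the sparsity/mean control.  Fields are evaluated with the minimum-image
displacement only; for σ_f ≤ side/6 the neglected periodic images contribute
less than e⁻¹⁸ of the peak.  All fields share the same size and height, read
literally from the model's definition.

## CA3 network and activity control

Mossy-fibre (MF) and recurrent-collateral (RC) connectivity are i.i.d.
Bernoulli with expected in-degrees C_MF = 50 and C_RC = 900 at the full
scale of 45,000 DG and 1,500 CA3 units (density 0.6 for RC; autapses
excluded).  MF weights are uniform and fixed; RC weights start uniform at
1/C_RC and are learned.

Two weight-scale choices interact and neither value is published:

* the end-of-learning normalisation pins every unit's incoming RC weights to
  sum 1, so the recurrent drive is of the order of the mean rate (0.1);
* the MF weight J sets the informative signal against that background.

With J chosen so the MF drive is an *average* of connected DG rates
(J = 1/C_MF), the MF signal (~0.003) is ~30× weaker than the recurrent
term's fluctuations, and the sparsity-controlled synchronous map wanders
chaotically — no spatially informative regime exists.  The package therefore
uses a detonator-scale mossy synapse, J = 1: a single active DG field
suffices to drive its target above threshold, matching the physiological
picture of mossy synapses as sparse, strong inputs, and the DG-driven
relaxation then contracts to a fixed point (relative change < 10⁻¹⁰ within
10 sweeps in the test suite).

Inhibition and intrinsic thresholds are summarised by a global threshold T
and gain g, re-regulated at every update so the population sparsity
⟨η⟩²/⟨η²⟩ equals 0.1 and the mean rate 0.1.  The threshold is found in
closed form rather than by bisection: with the drives of one update sorted
in decreasing order and exactly the top k units active, sparsity is a ratio
of quadratics in T whose admissible root is

    T_k = ( S1_k − sqrt( aN (k S2_k − S1_k²) / (k − aN) ) ) / k,

with S1, S2 the prefix sums of sorted drives and their squares; scanning k
and keeping the root inside its own sorted segment gives the exact solution,
vectorised over thousands of time steps at once.  This is what makes the
desk-scale protocol run in minutes on one CPU.  A sparsity target of exactly
1 is attainable only asymptotically for non-flat drives, so targets are
capped at 1 − tol/2 (tol = 10⁻³); flat drives raise a control error rather
than silently returning a tie-broken threshold.  The gain then rescales the
rectified rates to the target mean exactly.  The fast noise δ_i is Gaussian
with SD 0.002, drawn once per time step (its level is published, its
distribution and timescale are not; the drift analysis requires only that it
be negligible).

### Dynamics regimes

* **Externally driven (DG on).**  The network follows the trajectory with
  one synchronous update per time step: the drive at step t combines the MF
  input at the current position with the recurrent echo of the previous
  step's activity, and T, g are regulated once per step.  This is the
  protocol used for learning, template building and DG-on testing.
* **Fixed-point relaxation.**  `ca3_activity` (and `dynamics="relax"`)
  instead iterates the implicit rate equation at a fixed position
  (default 15 sweeps, re-controlling T and g each sweep) — the natural
  reading of the stationary rate equation, used by the convergence tests.
* **Recurrent-only (DG off).**  Each test position is relaxed independently
  for 15 sweeps with the MF input scaled by 1, 1/3, then 0 for the remaining
  13; the final configuration is decoded.  This probes the attractors laid
  down by learning; the relaxation away from the cued position is the
  deterministic *drift*.

## Plasticity

The RC weight update is ΔJ_ij = γ η_i (η_j − Λ_j) per step, with Λ_j the
arithmetic mean of the presynaptic rate over the preceding τ = 14 steps
(mean over whatever history exists during the first τ steps; zero with no
history).  Weights are clipped at zero after every step, applied to the
running accumulator, which starts from the uniform initial weights — this
reading is forced by the requirement that a zero learning rate leave the
(normalised) uniform network unchanged.  During the session the activity is
generated with the weights frozen at their uniform values (learning does not
feed back within the phase); the accumulated matrix is row-normalised and
installed at the end, and never re-normalised mid-session.  γ = 0.01 makes
the accumulated increments comparable to the initial weights at the default
rates; the normalisation makes the analysis insensitive to its exact value.

## Decoding and matrices

Templates are the mean population vector per bin over a 100,000-step
training run (the training run uses the same noise level as testing).  Test
activity is decoded by nearest template in Euclidean distance on raw rates
(no normalisation), ties broken to the lowest bin id.  Unit samples of size
1, 2, …, 256 (10 independent samples each, drawn without replacement) are
decoded against their own template columns; confusion counts accumulate at
(actual, decoded).  Rows with zero test visits abort the analysis rather
than being imputed — unreachable at the default phase lengths.  The reduced
matrix accumulates events by the torus displacement decoded − actual and is
normalised to total mass 1; its information is log₂S − H(Q), the information
of the translation-invariant channel it defines.

Per sample size, mutual information and percent correct are averaged over
the 10 samples, and the per-sample reduced matrices are averaged before the
bump fit.  Information and percent-correct curves versus sample size are
fitted with the sigmoids I_sat/(1+(n₀/n)^b) and
f_min + (f_max−f_min)/(1+(n₀/n)^b).

## Bump fit and reference curves

The averaged reduced matrix is fitted by least squares with an isotropic
Gaussian centred on the zero-displacement cell plus a uniform baseline;
reported are the peak height pc (bump + floor at the origin), the width w in
bin units (1 bin = 12.5 cm), and the discrete bump volume a.  On the 8×8
displacement grid any width below ~0.35 bins places negligible mass outside
the origin cell, so such fits are flagged sub-resolution; for the same
reason planted dispersions below ~1/3 bin are not recoverable by the closed
loop — an identifiability limit of the grid, covered explicitly in the test
suite.

Reference confusion matrices are built from bumps of adjustable width σ on
the displacement torus (σ = 0 is a point mass).  The minimum-information
reference is one origin-centred bump of volume a over a uniform remainder.
The maximum (unbiased) reference places 1/a bumps, one on the correct bin
and the rest on distinct random wrong bins; since 1/a is rarely an integer,
⌊1/a⌋ full bumps are used plus one fractional bump carrying the remaining
mass, which keeps the construction continuous in a (rounding the count
would, for a > 2/3, discard the remaining error mass entirely and inflate
the reference).  Placements are random per row, averaged over 50 draws, and
shared across σ evaluations (common random numbers), which makes the
reference information monotone in σ and the bisection well-posed.  The
references use a uniform stimulus prior (they are idealised channels; the
empirical test prior was measured to differ negligibly, < 0.005 bits of
entropy).  In the drift-adjusted variant every bump is replaced by two
half-volume copies, one in a random axis-neighbouring bin.

## Metric resolution

Per sample size, the measured full-matrix information — taken from the
fitted sigmoid, mirroring the use of fit curves in the source analysis (a
raw-value mode exists) — is bracketed by the reference information at σ = w
(floor) and σ = 0 (ceiling), and σ is solved by Brent's method; χ = 1 − σ/w.
Out-of-bracket values can either raise or be clamped to the nearer endpoint;
the experiment driver clamps and records a warning per affected size, since
scaled-down runs occasionally graze the floor.  For the DG-off condition the
bump parameters (a, w) are reused from the DG-on fits — the DG-off reduced
matrix mixes drift with genuine imprecision and its own fit parameters are
unreliable — and the drift-adjusted (two-bump) references are used.  The
non-spatial metric content λ = (I − I_min)/(I_max − I_min) is reported
alongside from the closed-form bounds at the fitted percent correct.
The unbiased ceiling (Eq.-style log₂S + log₂f) exceeds the biased one for
f > 1/2, where its defining construction no longer exists; the bound
inequalities are therefore only asserted for f ≤ 1/2.

## Global topology

The 64 full-population templates give a similarity matrix d = 1 − r
(Pearson; a √(2(1−r)) variant is available).  A 3-D embedding minimises the
Sammon stress by gradient descent with step halving (500 iterations,
accepted steps never increase the stress), initialised from classical MDS
with a tiny seeded jitter to break degeneracies.  Stress and a torus
adjacency check (adjacent bins embed closer than maximally separated ones)
are reported.

## Problem sizes and presets

The full-scale protocol (45,000 DG, 1,500 CA3, 400,000 test steps) is the
`paper` preset.  The package's own analyses and the acceptance script run
the `desk` preset — 4,500 DG and 300 CA3 units (RC density preserved, so
C_RC = 180), the same learning (10,000) and template (100,000) lengths, and
50,000 test steps — which reproduces the qualitative regime in a few minutes
on one CPU; a `tiny` preset exists for smoke tests.  Scaling down is not
free: the recurrent attractor map is coarser, so the DG-off condition loses
more information than the drift-adjusted references can represent at the
larger sample sizes (those sizes clamp at the floor, visible as warnings in
the result), and per-size χ values scatter more than at full scale.  The
synthetic protocol also idealises real data in ways that matter for
interpretation: perfectly Poisson multi-field maps, no theta-scale dynamics,
no behavioural inhomogeneity, and rate vectors observed noiselessly — so
passing tests certify the model analysis chain, not properties of
experimental recordings.
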
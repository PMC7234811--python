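# Methods

## The kinetic model

The package models recognition between a folded enzyme (P, observed only in
its active, nucleotide-saturated form P\*) and an intrinsically disordered
inhibitor (I) as a five-species scheme that couples conformational selection
with induced fit:

```
I   <=[ k1 / k-1 ]=>   I*                 (pre-binding conformational exchange)
P* + I*  <=[ kb / k-b ]=>  P*I*           (encounter complex, second order)
P*I*  <=[ kr / k-r ]=>  (PI)*             (rearrangement / folding-upon-binding)
```

Mass-action differential equations follow directly; two conservation laws
(total enzyme, total inhibitor) hold exactly, so the five species reduce to a
three-dimensional ODE system.  Internal units are molar and seconds
everywhere; the six rates span roughly ten orders of magnitude in natural
units, so a single unit convention is enforced throughout the internal API.

**Stiffness and integrators.**  With realistic parameters the relaxation
rates span ~0.1 s⁻¹ to ~3×10⁴ s⁻¹, i.e. the system is stiff.  The reference
integrator is scipy's implicit LSODA/BDF with the analytic Jacobian at
rtol 1e-8 / atol 1e-13 M.  The global fit instead uses a package-internal
Rosenbrock(2,3) stepper (the L-stable `ode23s` pair) compiled with numba on
the reduced three-variable system, because a fit evaluates thousands of
integrations; the two integrators are cross-checked against each other in the
test suite.  Negative-concentration excursions beyond 10·atol abort the
integration rather than being clipped — clipping would mask stiffness
failures during fitting.

**Equilibrium.**  The equilibrium state is computed algebraically: detailed
balance gives I\*/I = k1/k−1, enc = (kb/k−b)·P\*·I\* and final = (kr/k−r)·enc,
which closes to a single quadratic in the total bound concentration.  The
long-time ODE limit is retained only as a test oracle.  Degenerate cases:
kb = 0 or k−b = 0 with material present raises an error (the observation
model's normalisation would be 0/0); k−r = 0 with kr > 0 makes the final
complex absorbing and is reported as a warning with all bindable material in
(PI)\*.

**Initial condition.**  Mixing starts the reaction with no complex present.
By default the free inhibitor is pre-partitioned between I and I\* at the
k1/(k1+k−1) equilibrium, since the inhibitor equilibrates in the syringe
before mixing; a flag starts all material in I instead.

## The observation model

Stopped-flow intensity follows the equilibrium-normalised two-complex form

FI(t) = (c·[P\*I\*](t) + c\*·[(PI)\*](t)) / (c·[P\*I\*]eq + c\*·[(PI)\*]eq) · SC + Baseline.

The (c, c\*) pair is identifiable only up to a common scale (FI is invariant
under (c, c\*) → (λc, λc\*)), so c ≡ 1 during fitting and c\*, SC and
Baseline carry the remaining freedom.  The equilibrium normalisation is
computed from the model, never from the trace's plateau, so noise does not
couple into the normalisation.

## Synthetic data

The titration generator emulates the two experimental designs: the labelled
kinase fixed at 100 nM with the inhibitor titrated over a 0–250-fold excess,
and the double-labelled inhibitor fixed at 100 nM with unlabelled kinase
titrated over 0–800-fold.  Default concentration grids are log-spaced over
those ranges with a zero-titrant control (emitted as a flagged baseline-only
trace).  Noise is i.i.d. additive Gaussian with sigma expressed as a fraction
of the scale factor SC, default 1%; a mixing dead time (default 1.5 ms, a
typical instrument value) is discarded from the front of each trace.  All
generators are pure functions of (parameters, seed).

What the generator does *not* emulate: photobleaching, inner-filter effects,
donor/acceptor crosstalk, photon-counting statistics, correlated drift.
Passing recovery tests on these data therefore demonstrate estimator
correctness under the stated noise model, not robustness to instrument
systematics.

The NMR peak-table generator builds per-residue intensities from
mono-exponential decays, I(T) = I₀·exp(−R·T), with the channel-appropriate
rate (Γ₂ added for paramagnetic rows, Rex added for low refocusing-frequency
CPMG rows) plus Gaussian spectral noise.  A peak whose true intensity falls
below the spectral noise rms, or that cannot be drawn positive within a
retry cap, is reported "undetectable", mirroring resonances broadened beyond
detection.  The Markov generator samples integer state sequences from a
row-stochastic matrix with a uniform initial state.

## Transient phase analysis

Each transient is fit to offset + Σ Aᵢ·exp(−kobsᵢ·t) for 1–3 phases.  The
rates are optimised in log space with amplitudes and offset profiled out
linearly (variable projection), multi-started from log-spaced rate guesses
spanning the window resolvable by the trace (0.5/span to 0.5/dt).  Model
order is selected by AIC; the analysis that produced the published
per-construct table tried 1–3 exponentials without stating a rule, and AIC is
the standard choice.  Phases are ordered fast-to-slow by magnitude; rates
within 5% of each other raise a degenerate-phases warning rather than a
silent assignment.

Concentration-dependence laws: the fast phase follows the pseudo-first-order
line kobs = kon·[L] + koff (ordinary least squares; a negative intercept is
reported as-is with its standard error), with Kd_app ≡ koff/kon and its
error by first-order propagation.  The slow phase follows the saturating
hyperbola kobs = kslow·[L]/(K0.5+[L]) with no additive offset, matching the
published parameterisation; an optional offset exists behind a flag.
Concentrations below 5× the fixed-partner concentration are flagged (weak
pseudo-first-order regime) but not excluded.

## Global fit

All six rate constants are shared across every trace of every dataset; c\*
is shared per labelling scheme; SC and Baseline are free per trace.  Rates
and c\* are searched in log10 space with box bounds [−2, 9] (first order,
s⁻¹) and [3, 10] (second order, M⁻¹s⁻¹).  Because FI is affine in
(SC, Baseline), the per-trace pair is profiled out by exact linear least
squares at every objective evaluation (variable projection); this is jointly
optimal and shrinks the search to 6 + n_schemes dimensions while the stored
result still carries the full parameter set.  Solver failures map to a large
finite penalty so the optimiser can traverse stiff parameter regions.
Residuals are unweighted (plain SSR).

**Protocol.**  (1) n dispersed multi-start Nelder–Mead searches, each
followed by a bounded trust-region least-squares descent into its basin;
(2) a real-coded genetic algorithm (population 50; tournament selection of
size 3, blend crossover, Gaussian log-space mutation annealed over the
generations, two-member elitism, best-ever bookkeeping) seeded with the
local optima; (3) trust-region least-squares polish of the best candidates;
(4) sloppy-mode profile refinement.  The desk-scale default of the recovery
benchmark is 3 starts, 300 simplex iterations, 15 generations, 3 valley-walk
rounds and up to four coordinate-profile rounds, under an optional wall-clock
budget that skips remaining refinement scans once exceeded and returns the
current polished optimum; the full-scale protocol (10⁴ simplex steps, 10⁴
generations) is available through the same interface.

Stage (4) exists because the problem is classically "sloppy": several rate
combinations (kb·φ with φ = k1/(k1+k−1); k−b·k−r/kr; kr+k−r; the
rearrangement ratio against the FRET weights) are pinned orders of
magnitude more strongly than the individual rates, and the flat valleys
host chains of mirror optima in which plain descent reliably stalls.  Three
tools run at a fine integration tolerance (rtol 10⁻¹⁰), at which the
residual floor sits below the curvature separating the true optimum from
its mirrors (the Gauss–Newton Jacobian is decomposed by SVD each round;
modes with singular values below 3×10⁻³ of the largest count as soft).
First, valley walks: the softest mode's dominant coordinate is stepped in
0.3-decade increments while the remaining parameters follow by warm-started
continuation at a cheaper medium tolerance, and the farthest point still
near the walk's own floor is re-descended at the fine tolerance — this is
the workhorse for mid-range descent out of entirely wrong basins, and a
coordinate that yields no improvement is retired for later rounds.
Second, a branch scan: the dominant coordinate of the softest mode is
displaced over a wide log grid (up to ±1.6 and +2.4 decades — the
coordinate can sit parked at a bound, where local directions mislead) and
a full free refit is started from every displacement; all displacements
restart from the same entry point, and the best restart wins.  Third,
coordinate-profile rounds: the residual mirror optima sit a fraction of
a decade from the true optimum along the soft modes, and a full refit
started from a displaced point slides straight back into the mirror.
Every coordinate carrying at least 0.2 of a soft mode is a candidate
(the escape coordinate need not dominate the softest mode); in
participation order, each is frozen at ±0.05–0.55-decade offsets while
the remaining parameters are refit by warm-started continuation — a
genuine traversal of the curved valley.  Walks are aborted early when the
profile climbs past 3× the current optimum (stiff direction), rises past
4× its own minimum (basin passed), or stays flat (sliding along the
valley); far above the fine-tolerance floor they run at the cheaper
medium tolerance.  If the profile dips below the current optimum, its
minimum seeds a full fine-tolerance refit on the far side of the
barrier, repeating for up to four rounds while it improves, with the
full candidate list rescanned after every large crossing.  Each profile round
opens with a re-descent guarded by a seeded ~10⁻⁴-decade micro-kick: a
trust-region solve restarted from its own terminal point reproduces its
first step and stops immediately, and the kick breaks that fixed point so
the descent can continue along the valley.  Finally, because
the trust-region solver exits at its evaluation budget long before the
curved valley bottoms out, the fine descent is chained — restarted from
its own endpoint until the objective stops improving.  The benchmark data
are generated at rtol 10⁻¹¹ so the floor is set by the estimator, not by
the oracle curves.  Standard errors come from a finite-difference Hessian
of the profiled objective in log10 space, scaled by the residual variance.

**Identifiability and the recovery benchmark.**  With a realistic 1.5 ms
dead time the exchange mode (k1+k−1, τ ≈ 30 µs) and the rearrangement mode
(kr+k−r, τ ≈ 0.3 ms) relax inside the dead time, and only kb·φ and kr/k−r
are well determined — individual recovery of all six rates is then
impossible in principle.  The parameter-recovery benchmark therefore
augments the two titration designs with 3 ms burst traces sampled at
200 kHz and zero dead time, so every kinetic mode is represented in the
data; the long (5 s / 200 Hz) and intermediate (0.2–0.5 s) traces carry the
equilibrium approach and the binding phase.  The benchmark is an
estimator-validation experiment; it is not a claim about what a stopped-flow
instrument with a millisecond dead time can resolve.  Problem size: 16
traces, ~15,000 points, two labelling schemes, six concentrations per
scheme spanning 1–250× (fixed kinase) and 2–800× (fixed inhibitor).

## NMR observables

Compounded CSP: Δδ = sqrt(Δδ_HN² + (0.154·Δδ_N)²), with the table mean and
standard deviation reported for threshold lines.  Heteronuclear NOE:
Isat/Iunsat with the standard quadrature error.  CPMG: R2,eff = ln(I0/I)/T
with T = 40 ms; ΔRex is defined as R2,eff at the lowest nonzero refocusing
frequency (12.5 Hz) minus at the highest (1000 Hz) — the measurement grid
includes 0 Hz but the low-minus-high convention is standard.  PRE:
two-time-point Γ₂ over delays of 4 and 14 ms with four-term error
propagation; any non-positive intensity maps to "undetectable".  The σ-band
classification of a PRE profile bands each residue by its z-score against
the table's own mean and σ: weak < 1σ, medium [1σ, 2σ), elevated [2σ, 3σ),
strong ≥ 3σ.  The "elevated" band fills the 2σ–3σ gap left open by the
conventional strong/medium/weak wording so the classification is total; it
is invariant under affine rescaling of the table.  R1/R2 relaxation series
are fit mono-exponentially with two parameters.  Difference profiles
(bound − free) match residues by integer residue number; unmatched residues
are listed, never silently dropped.

## Markov-model statistics

Transition matrices are estimated from pre-discretised integer trajectories
by sliding-window counts at the chosen lag and row-normalised; empty rows
receive a self-transition and a disconnected-state warning.  Microstate
construction (dimensionality reduction and clustering) is out of scope; the
module consumes its output.  Stationary distributions come from the leading
left eigenvector with a linear-solve fallback; reducible chains return
empirical state frequencies with a warning.  Coarse-graining labels each
microstate by the mean helical fraction of the two terminal motifs
(threshold 0.5, the natural midpoint, as no cutoff is stated in the source
analyses): helix-loop-helix (HLH), coil-loop-coil (CLC) and the two mixed
states, with the central segment always a loop.  MFPTs solve the standard
hitting-time linear system with source microstates weighted by the
stationary distribution restricted to the source set, scaled by the lag
time; unreachable targets report infinity.  Bootstrap uncertainty resamples
whole trajectories with replacement (default 150 rounds) and re-estimates
everything per round; rounds with disconnected chains are recorded as failed
and excluded.  Re-clustering per round — part of the original full pipeline
— is not reproduced here since clustering is out of scope; the bootstrap
therefore quantifies estimation noise given the fixed discretisation.

## Numerical choices and degenerate inputs

- Exponential-fit model selection needs ≥ 5·(2n+1) samples for n phases.
- The fast-phase line requires ≥ 3 concentrations (2 give the exact line
  with undefined errors); the hyperbola requires ≥ 2 and warns below 4 or
  when K0.5 leaves the sampled range.
- A flat trace selects one phase with ~zero amplitude and a no-decay
  warning; identical kobs across concentrations give kon = 0 with Kd_app
  undefined-flagged.
- classify_pre refuses tables with σ = 0 (bands undefined) and fewer than 3
  finite values.
- All error propagations vanish exactly at zero noise.

## Known limitations

- The global fit's recovered k1 and k−1 degrade to their ratio when the
  data lack sub-dead-time information (see identifiability above); with one
  labelling scheme only, c\* becomes nearly unidentifiable as well because
  the rearrangement equilibrates quasi-statically.
- The observed slow phase of the transient analysis (~24 s⁻¹, saturating at
  micromolar K0.5) and the fitted rearrangement rates of the global ODE fit
  (kr = 2400 s⁻¹) describe different quantities and are deliberately not
  reconciled; both analyses are implemented as published.
- Bootstrap SDs understate the full pipeline uncertainty of the original
  Markov analysis (no re-clustering, see above).
- The hyperbolic slow-phase fit reports the covariance-based standard
  errors of a nonlinear fit; for strongly saturated designs these are
  optimistic and the K0.5 ill-determination warning should be heeded.
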
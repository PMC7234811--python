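# kinbind

Multi-state binding kinetics of an intrinsically disordered inhibitor
binding a protein kinase, from stopped-flow FRET transients to Markov-model
statistics.

Recognition between the cAMP-dependent protein kinase catalytic subunit
(PKA-C) and its disordered inhibitor PKIα proceeds through multiple states:
the free inhibitor exchanges between binding-incompetent and competent
conformations (conformational selection), forms an encounter complex with
the nucleotide-bound kinase, and rearranges into the final folded-upon-bound
complex (induced fit).  `kinbind` implements the quantitative machinery of
that analysis as a reusable, tested package:

* **Kinetic core** — the five-species scheme

  ```
  I  <=[k1/k-1]=>  I*;   P* + I*  <=[kb/k-b]=>  P*I*;   P*I*  <=[kr/k-r]=>  (PI)*
  ```

  with stiff ODE integration, an algebraic equilibrium solution, and exact
  conservation laws (`kinbind.kinetics`).
* **FRET observation model** — the equilibrium-normalised intensity
  FI(t) = (c·enc + c\*·final)/(c·enc_eq + c\*·final_eq)·SC + Baseline
  (`kinbind.fret`).
* **Transient phase analysis** — 1–3-exponential fits with AIC model
  selection, the fast-phase line kobs = kon[L] + koff (Kd_app = koff/kon)
  and the slow-phase hyperbola kobs = kslow[L]/(K0.5+[L])
  (`kinbind.transients`).
* **Global fit** — all six rate constants shared across every trace of
  every labelling scheme, per-scheme FRET weights, per-trace scale/baseline,
  optimised by multi-start simplex, a genetic algorithm, and trust-region
  refinement with sloppy-mode profiling (`kinbind.globalfit`,
  statsmodels-style `GlobalBindingModel.fit() -> GlobalBindingResults`).
* **NMR observables** — compounded CSP (0.154 nitrogen scaling),
  heteronuclear NOE with propagated error, CPMG R2,eff and ΔRex,
  two-time-point PRE-Γ₂ with error propagation and σ-band classification,
  bound-minus-free profiles (`kinbind.nmr`).
* **Markov-model statistics** — transition-matrix estimation from discrete
  trajectories, stationary populations, helix/coil macrostate
  coarse-graining (HLH/CLC/HLC/CLH), mean first-passage times, bootstrap
  uncertainty (`kinbind.msm`).
* **Synthetic data** — seeded generators for stopped-flow titrations, NMR
  peak tables and discrete trajectories with retained ground truth
  (`kinbind.synthetic`), so the whole pipeline is testable without any
  downloads.

See `docs/methods.md` for the model assumptions, parameter conventions,
identifiability analysis and known limitations.

## Worked example

Generate a titration from the published global-fit constants
(kb = 1.5×10⁷ M⁻¹s⁻¹, k₋b = 0.5 s⁻¹, kr = 2400 s⁻¹, k₋r = 720 s⁻¹,
k1 = 1.9×10⁴ s⁻¹, k₋1 = 1.5×10⁴ s⁻¹) with the labelled kinase fixed at
100 nM and 1% Gaussian noise, then run the per-construct phase analysis:

```python
import kinbind as kb

series = kb.generate_titration(
    kb.GLOBAL_FIT_RATES,
    kb.FretCalibration(c=1.0, c_star=0.35, sc=-0.8, baseline=1.0),
    kb.TitrationDesign(seed=0, titrant_multiples=(10, 25, 63, 100, 160, 250),
                       duration=1.0, sample_rate=2000, noise_sigma=0.01),
)
print(kb.TitrationAnalysis(series).fit().summary())
```

```
Phase summary [ACCEPTOR-3]
  fast phase : kon  = 8.3e+06 +/- 1.2e+05 M^-1 s^-1
               koff = 2.54 +/- 1.6 s^-1
               Kd_app = 3.07e-07 +/- 1.9e-07 M
  slow phase : kslow = 76.6 +/- inf s^-1
               K0.5  = 9.08e-06 +/- inf M
  warning: fewer than 4 concentrations: hyperbola weakly constrained
  warning: K0.5 = 9.08e-06 M lies outside the sampled range
```

Reading the numbers: the dominant observed rate grows linearly with titrant
concentration; its slope recovers the *effective* association rate of the
scheme, kb·k1/(k1+k₋1) ≈ 0.84×10⁷ M⁻¹s⁻¹ — the bimolecular rate discounted
by the fraction of inhibitor in the binding-competent conformation.  Only a
minority of transients resolve a second phase at this noise level, so the
slow-phase hyperbola is honestly reported as weakly constrained, with its
half-saturation point outside the sampled range.

The global fit runs the other way around — from data to rate constants:

```python
from kinbind.benchmarks import fit_recovery_problem
result, truth = fit_recovery_problem(seed=1)
print(result.summary())
```

## Command line

```
kinbind simulate       --rates rates.yml --calib calib.yml --design design.yml --out dir/
kinbind fit-transients --in dir/ --out summary.json
kinbind fit-global     --in dirA/ --in dirB/ --seed 1 --out fit.json
kinbind nmr-metrics    --mode pre --in peaks.csv --out gamma2.csv
kinbind msm            --traj traj.csv --helicity helicity.csv --lag 1 --out msm.json
```
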
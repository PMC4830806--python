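# schoenersim

Simulation and certification toolkit for a two-species Schoener competition
model with pure delays and impulsive (multiplicative jump) perturbations,
driven by quasi-periodic coefficients.

The package has three layers:

* **Model & integration** — quasi-periodic coefficients with certified
  inf/sup bounds, finite impulse schedules, and a fixed-step RK4 integrator
  with method-of-steps Hermite history interpolation and exact jump handling
  (`schoenersim.model`, `schoenersim.integrator`). Integration runs in log
  space by default, which guarantees positivity; linear space is kept for
  cross-validation.
* **Theory** — the scalar impulsive-logistic machinery (Cauchy transition
  factor, closed-form recurrent orbit, delayed upper/lower bound constants)
  and the two-species permanence/stability certificates: bound constants
  `M_i`, `N_i`, condition H1, contraction constants `alpha_i`/`beta_i`, and
  the closed-form H2 feasibility test (`schoenersim.logistic`,
  `schoenersim.theory`).
* **Diagnostics** — trajectory-level verification: tail extrema, invariant
  set membership, trajectory-pair convergence, and numerical evaluation of
  the certifying Lyapunov functional including jump-invariance and
  monotonicity checks (`schoenersim.diagnostics`).

## CLI

```bash
# full pipeline on the packaged demonstration scenario
schoenersim example1 --out out/ --horizon 200 --step 0.01

# user scenarios (JSON or YAML config)
schoenersim simulate --config scenario.json --out out/
schoenersim bounds   --config scenario.json --out out/
schoenersim check    --config scenario.json --out out/
schoenersim diagnose --config scenario.json --out out/
```

A config file provides `coefficients` (name → `{constant, harmonics:
[{amp, freq, phase, waveform}]}` for `a10..a22`, `m1`, `m2`, `c1`, `c2`),
`delays` (`tau10..tau22`), `schedule` (`base_period`, `jitter_amplitude`,
`jitter_frequency`, `h1`, `h2`), `horizon`, `initial_history`, and optional
`simulation`/`analysis` blocks; see `schoenersim.cli.example_scenario()` for
a complete programmatic example. Trajectories are exported as CSV
(`t,x1,x2,is_jump`) with a JSON sidecar of jump records; the round-trip
reader reproduces values bit-exactly.

## Notes on the certificates

With nonnegative jump coefficients the counting exponent
`xi = ln sup_k 1/(1+h_k)` is nonpositive; it enters the lower-bound formulas
only through its nonnegative part (see the `schoenersim.logistic` module
docstring for why the raw value would overstate the bound). Consequently a
scenario can satisfy H1 formally while its certified lower bounds `N_i` are
nonpositive — the certification report flags this as `strict_growth: false`
and treats the lower bound as vacuous rather than claiming one.
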
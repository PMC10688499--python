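# Methods

## Model

The chip is discretised into `M` boxes along its length; each box is
well mixed. Counts of unbound and bound protein are continuous
non-negative reals — a mean-field reading of the kinetics with no
stochastic birth–death dynamics. Binding is strictly irreversible (no
unbinding term), matching the quasi-irreversible antibody-trap chemistry
the model describes. Three rate parameters govern the dynamics:

| parameter   | meaning                                   | units                      |
|-------------|-------------------------------------------|---------------------------|
| `alpha_syn` | synthesis rate per source box             | proteins / [t] (or / step) |
| `kappa_bin` | binding affinity, mean-field second-order coefficient on `N_u * (N_b_max - N_b)` | 1 / (protein · trap · [t]) |
| `D_tilde`   | inter-box hopping rate, `D / l**2`        | 1 / [t]                    |

`kappa_bin` is deliberately interpreted as a second-order coefficient
multiplying `N_u * (free traps)`, not as a plain per-protein probability:
that is the form the rate equations take, and it makes the capacity
ceiling `N_b <= N_b_max` an absorbing bound.

Rates may be supplied per unit time (`rate_units: per_time`, with `dt` in
the same time unit) or per Euler step (`per_dt`, the natural convention
for dimensionless chip-scale runs); internally everything is advanced on
the per-step scale.

Only the 1-D box index carries geometry. The chamber height enters no
equation (it is small against the box length) and is not represented.

## One-box closed forms

For one box with constant synthesis the bound count has a closed form in
terms of the Gauss error function, with
`lam = sqrt(kappa/(2 alpha))`, `eta = 1 - N_b(0)/N_b_max` and
`C_zeta(t) = -N_b_max + N_b(0) + N_u(0) + alpha t`:

    N_b(t)/N_b_max = 1 - eta * exp(-lam^2 C(t)^2) /
        ( exp(-lam^2 C(0)^2)
          + N_b_max eta lam sqrt(pi) (erf(lam C(t)) - erf(lam C(0))) )

Direct evaluation is numerically treacherous: `erf` saturates to ±1 in
double precision already at |x| ≈ 6, so for `lam*C` in roughly (−26, −6)
the difference of error functions cancels to exactly zero while the
numerator underflows. The implementation therefore evaluates the ratio
piecewise by argument sign through the scaled complementary error
function `erfcx` (multiplying numerator and denominator by `exp(x1^2)` or
`exp(x0^2)`), which is cancellation-free; for `lam*C(t) >= 26` the system
is saturated to machine precision and the capacity is returned directly.
The implementation agrees with a stiff adaptive reference integration
(LSODA, rtol 1e-11) to ~1e-13 relative across ramp, knee, and plateau.

With `alpha_syn = 0` the parametrisation above degenerates. The
zero-synthesis problem conserves `N0 = N_u(0) + N_b(0)` and reduces to
`dN_b/dt = kappa (N0 - N_b)(cap - N_b)`, whose two-fixed-point solution

    N_b(t) = (cap*h - N0) / (h - 1),
    h(t) = (N_u(0)/(cap - N_b(0))) * exp(kappa (N0 - cap) t)

is provided separately (`onebox_bound_pure_binding`), with the algebraic
`1/(1/(cap-N_b0) + kappa t)` form for the degenerate balance `N0 == cap`.

## Integrator

Fixed-step explicit Euler is the production integrator by design — it is
the discretisation whose behaviour the package characterises — and the
adaptive integrator appears only as an independent oracle in the tests.
Guards are enforced as hard errors before stepping:

- `D_tilde * dt <= 1/2` (explicit-diffusion stability),
- `kappa_bin * dt * max(capacity) <= 1` (per-step binding depletion).

At run time each step additionally checks the physical bounds: a bound
count may exceed its capacity only by ≤ 1e-12 of the capacity (clamped,
as pure floating-point dust); larger overshoot, or a negative unbound
count, aborts with a "time step too large" error. The two static guards
do not jointly exclude such states (diffusion and binding can drain a box
together), hence the run-time check; the affinity-fitting grid ceiling
uses the combined headroom `(1 - 2 D_tilde dt)/(dt * max cap)` for the
same reason.

Box indexing is 1-based in all user-facing I/O (configs, observation
tables, trajectory exports), matching the `i = 1..M` convention; storage
is 0-based.

Recording stores every `record_every`-th step plus the final step, with
times stored explicitly. Regime detection requires `record_every = 1`
(transitions are read off the recorded grid without interpolation, ties
to the earliest time); the asymptotic-tail analysis accepts an externally
supplied `t*` so that long tail runs can be recorded with decimation.

The mass ledger `sum(N_u + N_b) = N(0) + alpha_syn |sources| t` is exact
up to rounding for the Euler scheme (binding moves mass between pools;
synthesis adds a known amount per step); `audit_mass` reports the maximal
relative violation, ≤ 1e-11 on all shipped presets. Rounding accumulates
like a random walk with step count, so extremely long runs (≳ 1e8 steps)
can drift above 1e-9 without indicating a defect.

The inner loop is JIT-compiled with numba when importable; the identical
loop runs as plain Python otherwise (slower, bit-compatible update
order).

## Efficiency and regimes

`f_b(t)` and the per-box `f_ib(t)` use the convention 0/0 → 0 for an
empty system — the model never evaluates the efficiency of zero protein,
and 0 is the natural continuous extension from the empty initial state.
Boxes without traps have no binding-dominated phase and are excluded from
the transition bookkeeping; boxes whose efficiency is still rising at the
horizon are reported as "not reached" (NaN / None) rather than clamped.
A detail worth knowing: shortly after the last per-box transition the
global efficiency can still show a small secondary bump (a downstream box
keeps absorbing fast enough to briefly outpace the 1/t dilution); strict
monotone decay sets in once that box approaches saturation.

## Presets and chosen parameters

Presets bundle the published chip-scale rates where they exist; the
remaining quantities are package choices, picked so every preset passes
the guards and completes its regime structure on a desk-scale budget
(seconds per run, ≤ ~100 MB of records):

- `fig2` (one box): `alpha = 1e-3/s`, `kappa = 0.1/s`, capacity 100,
  `dt = 0.1 s`, horizon 1.3e5 s — past the transition at
  `t* = cap/(2 alpha) ≈ 5e4 s`.
- `fig3_left/right` (two boxes, `D_tilde = 0.001` vs `0.1 /s`):
  `alpha = 0.1/s`, `kappa = 0.1/s`, capacity 100 per box. The synthesis
  rate is chosen so trap filling competes with the slow exchange time
  `1/D = 1000 s`; only then is the transition lag of box 2
  diffusion-limited and the three-regime structure clearly separated.
- `fig4` (100 boxes, sources 12..19): `alpha = 2e-4`, `kappa = 2e-3`,
  `D = 0.045` per step; capacity 2 per box so that even the box most
  distant from the sources transitions within 6e4 steps.
- `fig5` (pattern imprinting): `kappa = 2e-4`, `D = 8.3e-2`,
  `alpha = 2e-4` per step with the package's documented staircase
  capacity pattern at base 2 per box — small enough that
  `kappa * cap << D_tilde`, i.e. binding reaction-limited spreading, the
  regime in which the trap pattern imprints on the bound-protein profile
  long before saturation.
- `fig6` (restricted binding domain): `kappa = 2e-2`, `D = 9.8e-3`,
  `alpha = 2e-4` per step; 8 trap boxes at anchor 15 + `k_dist`,
  capacity 25, sources 7..14. The `k_dist` range convention is half-open:
  exactly `k_width` consecutive boxes carry traps.
- `fig7`/`fig8a,c,e` (validation-style runs): `kappa = 2e-3`,
  `D = 0.045` per step, horizons 2.1e4 / 3.9e4 steps; the three `fig8`
  trap layouts (near-source only; chip-wide; chip-wide at doubled trap
  count) are documented package choices standing in for layouts that are
  only available graphically.

## Well-mixed limit

Merging the two boxes of a fast-diffusion two-box system yields a one-box
system with doubled capacity, the same total synthesis, **and half the
binding coefficient**: the pooled count spreads over twice the volume, so
the per-count encounter rate halves. The comparison runs use
`kappa/2` accordingly; the residual discrepancy then falls monotonically
with `D_tilde` down to ~1e-6 at the stability-limited diffusion rate.

## Synthetic observations and affinity inference

`generate_synthetic_observations` emulates normalised fluorescence
read-outs: forward-model bound counts (totals or per box) at sample times
snapped to the recorded grid, plus i.i.d. additive Gaussian noise
truncated at zero. Real fluorescence data differ in ways the generator
does not model — multiplicative shot noise, optical point-spread mixing
between neighbouring positions, background drift, and normalisation
error — so passing recovery tests demonstrate correctness of the
inference machinery under the stated noise model, not robustness to
microscopy artefacts.

`fit_binding_affinity` minimises the sum of squared differences between
simulated and observed bound counts over `kappa_bin` alone
(`alpha_syn`, `D_tilde` known), on a 25-point log grid refined by bounded
Brent minimisation in log-kappa; deterministic by construction. The grid
profile is returned for identifiability inspection, a flat profile raises
an explicit non-identifiability error, and a minimum pinned to a grid
edge is flagged rather than refined.

Identifiability depends strongly on the observation design. When the
trap region is a perfect absorber (high affinity, slow diffusion — e.g.
capacity 25 with `kappa = 2e-2`, `D = 9.8e-3` per step), the *total*
bound count is transport-limited and varies by only ~0.1% per doubling of
`kappa`; no noisy-data fit can resolve the affinity there. The packaged
recovery experiment therefore observes the **per-box penetration profile**
of a restricted trap domain (capacity 5, `D = 0.4` per step, 10 sample
times): the absorption length `sqrt(D/(kappa*cap))` pins the affinity,
giving exact recovery on noiseless data and a median error of ~4% over 20
replicates at 5%-of-maximum Gaussian noise.

## Known limitations

- No unbinding, no 2-D/3-D resolution, no mechanistic
  transcription–translation detail, no stochasticity: the model is the
  deterministic 1-D mean-field compartment chain described above.
- `t*` is grid-resolved; no root-finding on the closed form's derivative.
- The explicit scheme, not an implicit one, is the product; very stiff
  parameter corners must reduce `dt` rather than switch integrator.
- Mass-ledger accuracy degrades with the square root of the step count
  (floating-point accumulation), relevant only beyond ~1e8 steps.
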
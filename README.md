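# chipbind

Compartmental reaction–diffusion modelling of cell-free protein synthesis,
diffusion, and finite-capacity trap binding on quasi-twodimensional
biochips.

## The problem

On silicon biochips, surface-immobilised DNA brushes drive cell-free
synthesis of a protein that then diffuses through the flat reaction chamber
and is captured quasi-irreversibly by surface-tethered molecular traps
(antibody-anchored partner proteins). Each trap binds one protein, so the
trap density is a finite resource. Practitioners who design such chips —
for directed self-assembly of protein nanomachines, on-chip expression
assays, or spatial sensing — need to know how the synthesis rate, the
diffusion constant, and the trap-binding affinity together set *where* and
*when* synthesised protein ends up bound.

`chipbind` models the chip as `M` well-mixed boxes along its length. With
`N_u[i]`, `N_b[i]` the unbound/bound counts in box `i` and `N_b_max[i]`
the local trap capacity:

    dN_b[i]/dt = kappa_bin * N_u[i] * (N_b_max[i] - N_b[i])
    dN_u[i]/dt = D_tilde * (N_u[i+1] + N_u[i-1] - 2 N_u[i])
                 - kappa_bin * N_u[i] * (N_b_max[i] - N_b[i])
                 + alpha_syn * [i in sources]

with no-flux ends (the boundary boxes couple to their single neighbour),
`D_tilde = D / l**2` the diffusion constant scaled by the box length, and
`[i in sources]` an indicator for the DNA-brush boxes. The total count
obeys the mass ledger `sum_i (N_u + N_b) = N(0) + alpha_syn * |sources| * t`.

The **trap-binding efficiency** `f_b(t) = sum_i N_b[i] / sum_i N_i(t)` is
the fraction of all protein that sits on traps. Each trap-carrying box
passes from a *binding-dominated* phase (efficiency rising) to a
*synthesis-dominated* phase (efficiency decaying like
`N_b_max / (alpha_syn t)`) at its transition time `t*_i`; spatially
inhomogeneous systems show a *mixed* regime between the first and last
per-box transition.

The package provides

- the one-box closed-form solution (error-function form for
  `alpha_syn > 0`, logistic-type form for pure binding),
- a fixed-step explicit-Euler simulator for the `M`-box system with strict
  stability/overshoot guards and a conservation audit,
- efficiency and regime-transition analysis,
- trap-pattern builders (homogeneous, explicit vectors, spatially
  restricted binding domains at a distance `k_dist` from the sources),
- least-squares inference of the binding affinity `kappa_bin` from
  (synthetic or measured) bound-protein observations with known
  `alpha_syn` and `D_tilde`,
- YAML run configurations, named experiment presets, and a CLI.

## Worked example

```python
from chipbind import get_preset, simulate, detect_regimes, audit_mass

preset = get_preset("fig4")          # 100 boxes, sources at boxes 12..19
traj = simulate(preset.config, preset.traps, preset.sources)
rep = detect_regimes(traj)
print(f"mass audit (relative):      {audit_mass(traj):.3g}")
print(f"first transition t*_1:      {rep.t_star_first:.0f} steps")
print(f"last transition t*_100:     {rep.t_star_last:.0f} steps")
print(f"max trap-binding efficiency f_b_max = {rep.f_b_max:.4f} at t = {rep.t_f_b_max:.0f}")
```

prints

```
mass audit (relative):      2.43e-14
first transition t*_1:      12778 steps
last transition t*_100:     26736 steps
max trap-binding efficiency f_b_max = 0.9615 at t = 14841
```

The source boxes saturate their traps first (`t*_1`, end of the pure
binding-dominated regime); the box farthest from the sources transitions
last (`t*_100`, start of the pure synthesis-dominated regime in which
`f_b` decays like `1/t`). The audit confirms the mass ledger holds to
rounding.

The same run from the shell:

```sh
chipbind preset fig4 -o fig4.yaml
chipbind simulate fig4.yaml -o fig4_run        # fig4_run.tsv + fig4_run.json
chipbind analyze fig4_run -o fig4_regimes.json
```

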
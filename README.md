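# gcncmc

Grand canonical nonequilibrium candidate Monte Carlo (GCNCMC) on
self-contained toy molecular systems: the move engine, the Adams-value /
concentration machinery, binding-affinity estimation by occupancy titration,
occupancy-grid site mapping, and binding-mode population analysis.

## What problem this addresses

Sampling the binding and unbinding of small molecules (water, fragments,
ligands) in molecular simulation is notoriously slow when the site is
occluded from solvent: molecules must find their way in and out by diffusion.
Grand canonical Monte Carlo sidesteps diffusion by *inserting* and
*deleting* molecules directly, with acceptance controlled by a dimensionless
chemical-potential parameter, the **Adams value** `B`.  Instantaneous
insertions into condensed phases almost always clash sterically, so the
nonequilibrium candidate Monte Carlo variant switches the molecule on/off
*gradually* — a sequence of `n_pert` alchemical perturbations interleaved
with `n_prop` steps of Langevin dynamics (switching time
`τ = (n_pert + 1)·n_prop·δt`) — and accepts on the accumulated protocol
work `w`:

    P_insert = min[1, e^{B}  e^{-βw} / N_T]
    P_delete = min[1, N_0 e^{-B} e^{-βw}]

where `N_0`/`N_T` count molecules in the (optionally spherical) GCMC region
at the start/end of the move.  The Adams value encodes the reference-solution
concentration `c` through

    B_eq(c) = β μ'_sol + ln(V_GCMC / V(c)),    V(c) = 1 / (N_A c),

with `μ'_sol` the excess chemical potential (here measured by Widom test
insertion).  Scanning `B` titrates the occupancy of a binding site; the
midpoint `B_50` of the fitted logistic

    N(B) = 1 / (1 + exp[k (B_50 − B)])

maps to the dissociation constant `K_D` and the standard binding free energy
`ΔG° = kT ln(K_D / c°)`.

This package implements the full workflow at desk scale.  Instead of
all-atom force fields it provides toy systems (ideal gas, dilute
Lennard-Jones fluid, Gaussian/square binding wells with single-occupancy
exclusion) whose grand-canonical behaviour is known exactly, so every layer
— acceptance rules, protocol work, Adams conversions, titration fits, grid
and mode analyses — is validated against closed-form or enumerable oracles.
It is aimed at method developers and students who want a transparent,
fully-checkable reference implementation of the GCNCMC machinery.

## Worked example

Titrate the built-in single-well binder (a Gaussian well of depth
3 kcal/mol, width 2 Å, in a 16 Å box, with hard single-occupancy exclusion —
its exact `K_D` is 0.237 M):

```python
import numpy as np
from gcncmc.adams import AdamsSpec
from gcncmc.engine import ChainSchedule, GCNCMCSampler, instantaneous_protocol
from gcncmc.fixtures import make_single_well
from gcncmc.titration import aggregate, fit_b_scale, run_titration

system, state, region, truth = make_single_well()
b_values = truth["b50"] + np.linspace(-3, 3, 12)
schedule = ChainSchedule(n_cycles=1700, md_steps_per_cycle=0,
                         species_move_pattern=["ligand"], n_equil_cycles=200)

def make_sampler(b, rng):
    return GCNCMCSampler(system, state.copy(), region, {"ligand": b},
                         {"ligand": instantaneous_protocol()}, rng)

table = run_titration(make_sampler, b_values, repeats=4,
                      schedule=schedule, base_seed=107, frozen_dynamics=True)
spec = AdamsSpec(mu_ex=0.0, temperature=298.0, v_gcmc=system.box.volume)
fit = aggregate(fit_b_scale(table), spec, table)
print(f"B50 = {fit.b50:.3f} +/- {fit.b50_err:.3f}")
print(f"K_D = {fit.kd:.3f} M, dG = {fit.dg:.3f} +/- {fit.dg_err:.3f} kcal/mol")
print(f"analytic dG = {truth['dg']:.3f} kcal/mol, tau = {fit.kendall_tau:.2f}")
```

prints

```
B50 = -0.559 +/- 0.081
K_D = 0.234 M, dG = -0.860 +/- 0.048 kcal/mol
analytic dG = -0.852 kcal/mol, tau = 0.93
```

i.e. 48 short chains (12 Adams values × 4 repeats) recover the enumerated
binding free energy within its standard error.  The same workflow is
available from the shell:

```sh
gcncmc fixtures --name single_well --out-prefix well
gcncmc titrate --config well_config.yaml --b-values="-4,-3,-2,-1,0,1" --seed 1
gcncmc adams --v-gcmc 62000 --mu-ex -6.09 --concentration 55.5
```

Other subcommands: `simulate` (one chain with CSV move log and XYZ
trajectory), `muex` (Widom insertion), `grid` (OpenDX occupancy grid),
`modes` (binding-mode clustering).

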
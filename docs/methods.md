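# Methods

## Toy systems

All systems live in an orthorhombic periodic box (minimum-image convention).
Species are rigid and by default single-site; multi-site rigid species are
supported in the data model but the validation suite deliberately uses
single-site species, where every energy routine takes a fully vectorized
path.  Units: Å, kcal/mol, ps, amu, elementary charge; `N_A` is the defined
CODATA value and `kT` comes from the molar gas constant in kcal/(mol K), so
all conversion targets are bit-stable.

Interactions:

- **Lennard-Jones**, Lorentz–Berthelot mixed, plainly truncated at the
  cutoff (default 12 Å) with no switching function and no long-range
  dispersion correction.  During alchemical switching the pair term uses
  the Beutler-style 1-1-6 soft core
  `U = 4 ε λ [ (α(1−λ) + (r/σ)^6)^{-2} − (α(1−λ) + (r/σ)^6)^{-1} ]`
  with `α = 0.5`; it is finite at `r = 0` for `λ < 1` and reduces to plain
  LJ at `λ = 1`.  The pair coupling is the product of the two molecules'
  λ values (only one molecule is ever fractional).
- **Coulomb** (optional), linearly scaled by `λ_elec` on the
  cutoff-truncated `q_i q_j / r` term.  Insertions complete the LJ stage
  before any charge is turned on, so no naked charges appear at partial
  steric coupling; deletions run the exact reverse path.  The λ waypoints
  are uniform within each stage and the stage split defaults to half the
  perturbation steps each; the within-stage spacing and α are conventions,
  not derived quantities.
- **External binding wells** standing in for occluded pockets:
  `gaussian` (`U = −ε_w e^{−r²/2s²}`, smooth forces — the default whenever
  Langevin dynamics runs) and `square` (`U = −ε_w` for `r ≤ s`), which
  exerts zero force and is reserved for enumeration fixtures sampled by
  pure Monte Carlo; running MD across a square-well edge would simply
  ignore the wall.
- **Single-occupancy exclusion**: a flat 10⁴ kcal/mol penalty between real
  molecules of the excluded species.  It is *global* by default so that the
  grand partition function of a well fixture is exactly two-state
  (`Ξ = 1 + e^B q`, `q = ⟨e^{−βU}⟩`), which makes the titration curve an
  exact logistic with slope 1 and `B_50 = −ln q`; a within-radius variant
  is available when multiple far-apart binders are wanted.

Dynamics is Langevin with the BAOAB splitting (default 2 fs step, 1 ps⁻¹
friction; several tests raise the friction so samples decorrelate inside a
short run).  Ghost (fully decoupled) molecules are parked in place: they are
excluded from force loops, from kinetic-energy accounting and from
propagation.

## The GCNCMC chain

A cycle is a block of MD followed by one or more moves per the species move
pattern.  A move picks insert/delete with equal probability.  Insertion
places a ghost uniformly in the GCMC region (uniform random orientation for
multi-site species), draws its velocities from Maxwell–Boltzmann, then runs
the forward λ schedule; deletion picks uniformly among real molecules whose
membership point (center of geometry) is inside the region at move start
(that count is `N_0`) and runs the reverse schedule.  Every move starts and
ends with a propagation segment, giving `n_pert + 1` segments and
`τ = (n_pert + 1)·n_prop·δt`.

The protocol work is the sum of potential-energy changes at fixed
configuration across the λ jumps; the thermostatted relaxation between
jumps is heat and is excluded, as is the bracketing propagation.  Because
every term not involving the tagged molecule cancels in each jump, the work
is accumulated from the tagged molecule's interaction energy only (an O(N)
computation, verified against full-energy differences).

Acceptance follows the sphere-corrected grand canonical rules
(`P_insert = min[1, e^B e^{−βw}/N_T]`, `P_delete = min[1, N_0 e^{−B} e^{−βw}]`),
with region counts always recomputed from geometry.  A move whose switched
molecule ends outside the sphere is rejected unconditionally, since the
reverse proposal would be impossible.  On rejection the saved pre-move state
(positions and velocities) is restored and velocities are resampled from
Maxwell–Boltzmann — valid under Langevin dynamics and simpler than
momentum-reversal bookkeeping.  The proposal and main-chain randomness come
from one seeded generator per sampler; the thermostat stream inside a switch
is not required to be shared with anything else.

`n_prop = 0` with `n_pert = 1` is instantaneous GCMC: the work reduces to
the bare ΔU, and a GCNCMC chain with this protocol is *definitionally*
identical to classic GCMC on the same random stream (tested).  The
consecutive-reject termination heuristic counts post-equilibration move
attempts, with unproposable deletions (empty region) counted as rejections.

## Oracles used for validation

- **Ideal gas** (no interactions): the whole-box region count is Poisson
  with mean `e^B`; both the instantaneous and the full NCMC chain must
  reproduce mean and variance.
- **Square-well fixture**: with single occupancy the state space collapses
  to {empty, in-well, outside-well} with exact weights
  `1 : e^B f_w e^{βε} : e^B (1 − f_w)`; sampled frequencies are compared
  with block-averaged standard errors.
- **Closed loop**: Widom insertion on canonical frames of the dilute LJ
  fluid gives `μ'`; running the chain at `B_eq(c*)` built from that `μ'`
  must recover the imposed concentration `c*` within combined errors.
  The fluid is kept dilute (ρσ³ ≈ 0.03) so the canonical-vs-grand-canonical
  finite-size mismatch in `μ'` stays below the statistical resolution.
- **Single-well titration**: `q` (hence `B_50`, `K_D`, ΔG°) is computed by
  radial quadrature of the well Boltzmann factor, independently
  cross-checked by a Riemann sum and by uniform-sampling Monte Carlo.
- **Double-well modes**: two equal-volume square wells with a depth gap of
  `ΔF·kT` give an exact `e^{ΔF}` population ratio between modes; the
  default gap 0.79 kT corresponds to a 69:31 split.  Fixed anchor points
  map well membership onto the sign of a four-point dihedral, so the
  dihedral-binning and RMSD-clustering analyses can be checked against the
  same truth.

## Parameter choices

- **Single-well fixture defaults** (depth 3 kcal/mol, width 2 Å, box 16 Å):
  chosen so the well dominates the bound weight (`q ≈ 4.2`, `K_D ≈ 0.24 M`,
  a fragment-scale binder) while entry/exit events occur every few tens of
  cycles.  A deep narrow well would make the well mode's relaxation time
  comparable to a whole chain, and occupancies from finite chains started
  empty would be systematically low; the broad shallow default keeps the
  occupancy autocorrelation time two orders of magnitude below the default
  1700-cycle chains (verified against the exact curve at several B).
- **Double-well fixture** (wells ±3 Å from center, radius 1.5 Å, base depth
  3 kT, GCMC sphere radius 5 Å in a 12 Å box): the sphere keeps the well
  volume fraction high enough that the chain switches modes every ~10²
  moves; the chains sample at `B_50` where insertion/deletion traffic is
  maximal.
- **Chain defaults**: 1700 cycles with the first 200 discarded, and
  termination after 200 consecutive rejections.  Equilibration is a fixed
  count (exposed as a flag), not automatic detection.
- **Titration protocol**: 12 B values spanning `B_50 ± 3` × 4 repeats; fits
  are per-repeat nonlinear least squares of the logistic with `k > 0`
  enforced, `B_50` seeded at the interpolated half-occupancy crossing and
  bounded within the scanned range ± its width.  Repeats with degenerate
  data (all empty or all saturated) are excluded.  Per-repeat `B_50` values
  are converted to `K_D` and *then* averaged; ΔG° comes from the mean `K_D`
  and its error from the s.e.m. of the `K_D` values (the alternative —
  averaging per-repeat ΔG° — differs at second order in the spread).
  Kendall's τ of occupancy vs B across all repeats is reported as a
  data-quality indicator.  Occupancy is the mean molecule count in the
  region, not capped at one.
- **Problem sizes** in the validation studies (2–6 × 10⁴ move chains, 200
  Widom frames × 200 trials, 48 titration chains) are chosen so each
  stochastic check resolves its target at the 3-standard-error level in
  minutes on one CPU core.

## Error estimation

Chain averages use block averaging (20 blocks) so standard errors include
autocorrelation; variance targets use the spread of per-block variances.
Titration errors are standard errors of the mean over repeats; the ΔG°
error from a `B_50` uncertainty is `kT·σ(B_50)` combined in quadrature with
`σ(μ')`.  Widom errors are block averages over frames, and the closed-loop
comparison combines the chain error with `β c σ(μ')` in quadrature.

## What the toys do and do not show

Passing oracles here demonstrates that the move engine, work accumulation,
acceptance rules, Adams conversions, fits and analyses are internally
consistent and target the correct grand canonical measure.  The toys do not
emulate force-field energetics: no solvent granularity, no PME
electrostatics, no conformational coupling between receptor and switch, no
barostat.  Square wells cannot be mixed with MD, gaussian wells cannot model
steric anisotropy, and μ' here is cheap because the fluids are dilute —
production use on condensed-phase systems would need hydration free-energy
machinery and much longer switches.  Degenerate inputs are handled
conservatively: non-finite work auto-rejects with the record flagged, empty
deletion candidates are skipped-as-rejected, empty trajectories error, and
all-overlapping Widom trials report +∞ with a warning.
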
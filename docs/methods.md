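# Methods

## Model structure

Both models are SI-type compartmental systems for the *fractions* of a
constant-turnover population (inflow = outflow = `mu`), so every admissible
state lies on the probability simplex and the right-hand sides sum to zero
identically. Infection has an acute stage (mean duration
`theta_A = 1/(gamma + mu)`, transmissibility `beta_A = xi * beta_C`) followed
by a chronic stage. During acute infection the host carries only the founding
strain; during chronic infection the within-host population has relaxed to an
average composition given by column `j` of the mutation matrix `A` for a host
founded by strain `j`. `A` is column stochastic with strictly positive
diagonal (a founder never vanishes from its own host). Treatment is started
only from the chronic stage (rate `u_T`) — appropriate for infections whose
acute phase is short relative to the diagnosis delay — and in the baseline
model is perfect and absorbing apart from mortality.

The extended model adds per-strain chronic transmissibilities `beta_Ci`
(acute ones remain proportional with the shared factor `xi`), per-strain
treatment failure (`T_i` reverts to `I_Ci` at rate `zeta_i`), and a
prophylaxed class `P` entered from `S` at rate `u_P`, left at rate `delta`
(inverse cycle duration), and infected by strain `i` at the reduced rate
`(1 - psi_i) phi_i`.

## Strain space

Two structured parametrizations of `A` keep the `n^2` entries identifiable
from `n` parameters:

* **uniform** — founder `i` retains `pi_i`, the lost mass spreads evenly over
  the other `n - 1` strains. The stationary distribution is closed-form:
  `v_i ∝ prod_{j != i} (1 - pi_j)`, hence the endemic ratio law
  `v_i / v_j = (1 - pi_j) / (1 - pi_i)`.
* **nearest-neighbor** — strains ordered by genetic similarity; founder `j`
  loses `(1 - pi_j)/2` to each neighbor, and the two boundary strains give
  their whole lost mass to their single neighbor. This boundary convention is
  the one under which the inverse parametrization
  (`pi_1 = 1 - (1-pi_n) v_n/v_1`, `pi_j = 1 - 2 (1-pi_n) v_n/v_j` for
  interior `j`) reproduces the target eigenvector exactly; the round trip
  frequencies → retentions → matrix → eigenvector is tested to 1e-9.

Because `v` fixes only `n - 1` degrees of freedom, one retention (`pi_n`) is
free. The inversion can leave the unit interval for nearly uniform targets
with small `pi_n`; this is checked eagerly and reported with the offending
index rather than clipped.

Dominant eigenpairs are computed by dense eigendecomposition
(`scipy.linalg.eig`) rather than power iteration: the unit eigenvalue of a
stochastic matrix can have near-degenerate companions that stall iteration.
Intended for `n` up to a few hundred, far beyond the reference `n = 4`.
Right eigenvectors are normalized to sum 1, left ones so that `w·v = 1`.
Irreducibility is decided by strong connectivity of the sparsity digraph
(edge `j -> i` when `alpha_ij > 1e-14`, networkx); the block-triangular
normal form orders strongly connected components in reverse topological
order of the condensation, and the eigenvalue-1 eigenspace is extracted with
an SVD null space at `rcond = 1e-9`.

## Reproduction numbers and sensitivities

The baseline closed form and the extended spectral-radius form are each
validated against an independent next-generation construction: `F` collects
the Jacobian of new-infection inflows (`phi_i S`, plus `(1-psi_i) phi_i P`
in the extended model) and `V` the remaining transitions over the infected
compartments `[I_A, I_C(, T)]` at the model's disease-free equilibrium
(`S_DFE = (delta+mu)/(delta+mu+u_P)`); `R0 = rho(F V^-1)`. Agreement is
required to 1e-8 over seeded random parameter draws spanning
`n in {1, 2, 4, 8}`.

The first-order expansion around zero control uses the left/right dominant
eigenvectors `w0, v0` of `Q(0)N(0) = B_bar @ A_bar`, where
`A_bar = (xi*mu*E + gamma*A)/(gamma + xi*mu)` is a convex combination of the
identity and `A` — so for uniform transmissibility `w0` is the all-ones
vector and `v0` the stationary strain distribution. The treatment
coefficient is implemented as

```
R1_T = - w0' [R0*E - (xi/(gamma+mu)) * B_C] inv(Z + mu*E) v0
```

the reading that is dimensionally consistent, reduces to
`-R0 * gamma/(gamma+xi*mu) * w0' inv(Z+mu*E) v0` for uniform `beta`, and
matches second-order one-sided finite differences of the full spectral
formula to better than 1e-4 relative (asserted in the tests). Interpretation:
each coefficient is a sum over strains of (mean duration of the
intervention) x (protection it confers against that strain), weighted by
`w0i * v0i`. Both coefficients are always non-positive (unconditional local
efficiency); *global* efficiency — the existence of finite control rates with
R0 = 1 — additionally requires the large-control floor
`xi/(gamma+mu) * max_i beta_Ci (1 - psi_i) < 1`, i.e. it is decided by the
least-controllable strain alone.

`critical_control` inverts the monotone map `u -> R0(u)` by Brent's method on
a geometrically expanded bracket (tolerance 1e-12) and also reports the first
crossing on a 0.01 grid, the resolution used by the scenario sweeps.

## Equilibria

Baseline, irreducible `A`, R0 > 1: the unique endemic equilibrium is fully
explicit (see README); the implementation verifies `||rhs|| < 1e-10`,
components summing to 1, and the fixed-point identity `I_C* = A I_C*` at
every construction. Derived quantities: prevalence `Pi = (R0-1)/R0` and the
acute/chronic transmission ratio `r_AC = xi*(u_T+mu)/gamma`, which together
identify `xi` and `beta_C` from equilibrium observations.

Reducible `A`: each unit eigenvalue (at most one per closed irreducible
block) contributes a basis equilibrium; general members are combinations,
renormalized to sum 1. Combinations with negative strain frequencies are
rejected explicitly rather than projected, and no stability claims are made
for family members.

The extended model has no closed form. `endemic_extended_numeric` seeds a
root solve (scipy `hybr`, tolerance 1e-12, conservation law substituted for
the redundant equation) from the collapsed baseline closed form when the
parameters reduce, otherwise from a long-time integration; if the root solve
fails to reach `||rhs|| < 1e-9` the integration state is returned and
flagged via `source`.

## Integration

Default solver is implicit Radau (`rtol 1e-8`, `atol 1e-11`): the rate
separation `gamma = 3` vs `mu = 0.025` makes the system mildly stiff.
Trajectories are monitored for the structural invariants — components
non-negative and summing to 1 within 1e-7 — and negative excursions smaller
than 1e-12 are clipped and counted; anything larger raises.
`steady_state` integrates in chunks of 2000 time units until
`||rhs|| < 1e-10` or `t_max = 5e4` (long enough for `exp(-mu t)` transients
at `mu = 0.025` to decay below 1e-9). Scenario runs start, by this package's
convention, from 1% of the population acutely infected with strain 1.

## Reference scenarios

The four-strain fixtures use `mu = 0.025`, `gamma = 3`, `xi = 5`,
`u_T = 0.4` (rates per year: four-month acute stage, 2.5 years to
treatment) and a nearest-neighbor `A` inverted from stationary frequencies
with adjacent ratios 3 (Case 1) or 7 (Case 2). Three transmissibility
choices are exposed: `calibrated` solves the baseline closed form for
R0(u_T = 0.4) = 1.2 exactly (`beta_C ≈ 0.301024`, the default), `figure1`
is the uniform rate 0.3 under which R0 = 1.196 and the Case-1 prophylaxis
threshold lands on the 0.88 grid point, and `printed` is 0.25 (R0 < 1 at
u_T = 0.4; no endemic state — kept for completeness). Case 2's quoted
retention values (0.9985, 0.9796, 0.8571) follow from the inverse
parametrization only with `pi_4 = 0.5`; both that variant (`as_printed`)
and the `pi_4 = 0.25` variant (`eq22_consistent`) are available and the
choice is always explicit.

Sweeps (transmissibility multiplier `a` of strain 4 over [0.7, 2];
prophylaxis `u_P` with `psi = (1,1,1,0)`, `delta = 4`; treatment failure
`zeta_4` with no prophylaxis) compute the endemic state per grid point with
warm-started continuation along the grid. Default grid steps are 0.01
(`u_P`) and 0.05 (`a`, `zeta_4`). Relative strain frequencies are
`f_i = (I_Ai + I_Ci) / sum_j (I_Aj + I_Cj)`; `total_infected` includes
treated hosts; grid points with R0 <= 1 report zero infection.

## What the fixtures do and do not show

All inputs are parameter sets; there is no sequence or surveillance data
anywhere in the pipeline, and the models are deterministic (seeds only feed
randomized property tests). The four-strain fixtures exercise every analytic
result at a size where dense linear algebra is exact to machine precision;
they do not probe demographic stochasticity, contact heterogeneity,
coinfection/superinfection, or time-varying controls, all of which are out
of scope. Passing tests therefore validate the mathematics and the
implementation, not the fit of the model to any particular epidemic.

## Known limitations

* The semi-analytic structure of the extended endemic equilibrium is not
  exploited; the numeric solver is the only route.
* Stability of reducible-family equilibria is unknown and unreported.
* Controls are constant rates; optimal time-varying policies are out of
  scope.
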
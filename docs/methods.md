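# Methods

## Model and assumptions

The package treats metabolism as a constraint-based steady-state
system: fluxes `v` satisfy `S·v = 0` within bounds, and enzyme activity
is made explicit by expanding every reaction with a GPR rule into
nonnegative usage variables, one per isozyme and allowed direction.
The expansion is conservative in both directions: the usage columns
repeat the reaction's stoichiometry (negated for backward usage), each
usage is bounded by the magnitude of the corresponding reaction bound,
and the original reaction bounds are re-imposed on the signed usage sum
— so the extended system's feasible flux set equals the plain model's.

The two-condition fit assumes that between two otherwise comparable
cell states, the *ratio* of an enzyme's usage tracks the ratio of its
gene expression. No assumption links absolute transcript level to
absolute rate; enzymes without measured (significantly changed)
expression are left to the constraints and the parsimony objective.
Step 1 minimizes the total absolute disagreement
`Σ_i |u_i^b − r_i·u_i^a|`; Step 2 minimizes total usage
`Σu^a + Σu^b` subject to keeping that disagreement within
`obj1·(1+ε)`. Both are pure LPs: absolute values are linearized with
one nonnegative deviation variable and two inequality rows per term,
and reversible enzymes get direction-split nonnegative usages with no
binary exclusivity — simultaneous forward+backward usage is feasible in
principle but suppressed by Step-2 parsimony. This keeps the method a
two-step linear optimization rather than a MILP.

The strict activation conditions ("usage above u_min when expression is
positive") are implemented as `≥ u_min`, since strict inequalities are
not LP-representable and u_min is itself a tolerance. The Step-2 cap is
`≤ obj1·(1+ε) + 1e−9`; the absolute slack makes the frequent `obj1 = 0`
case robust to solver feasibility tolerance.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `u_min` | 0.001 flux units | activation floor per expressed enzyme, per condition |
| `epsilon` (`step2_tol`) | 0.1 | relative relaxation of the Step-1 optimum in Step 2 |
| `growth_frac_a/b` | 0.8 | optional biomass floor as a fraction of each condition's FBA maximum (computed under that condition's own exchange floors, without the cross-condition ratio rows) |
| `total_flux_budget` | off | optional equality `Σu = budget` per condition (constant-total-flux assumption) |
| `tau` | 0.5 | deviation tolerance widening exometabolome fold-change intervals |
| `phi` | 0.01 | exchange-magnitude floors as a fraction of per-exchange max uptake |
| `n_perm` | 10,000 | reporter permutation background size |
| infinite bounds | ±1000 | sentinel magnitude replacing ±inf so all LPs stay bounded |
| tolerances | 1e−6 | mass-balance/bound checks; solver cap slack 1e−9 |

`growth_frac` floors and the constant-total-flux budget answer two
different experimental situations: when growth rates are measurable,
the floors anchor each condition near its optimum; when they are not
(e.g. slow or dormant populations), the budget mode makes only the
*distribution* of flux between pathways interpretable, not its absolute
scale. Both are provided and compatible; the package default keeps the
0.8 growth floors, while the synthetic scenario runs with neither (its
planted biomass is deliberately far below the FBA maximum, which an
0.8 floor would contradict).

## Exometabolome constraints

Direction calls compare each condition's abundance against the pure
medium, gated by caller-supplied significance flags (significance
testing is upstream and deliberately replaceable). Fold changes are
computed on baseline-subtracted magnitudes; endpoint concentration
differences stand in for rates because the cultivation interval is
equal across conditions. Two documented choices where the procedure is
otherwise underdetermined:

- opposite direction calls (uptake in one condition, secretion in the
  other) keep their absolute floors but receive no ratio constraint — a
  signed magnitude ratio has no linear encoding; the skip is logged.
- "maximum uptake rate" is computed per exchange by FVA under the
  model's bounds (minimizing the exchange flux), not from a global
  default bound.

Ratio intervals are linearized as two rows on the direction-signed
magnitudes: `mag_b − FC(1+τ)·mag_a ≤ 0` and `mag_b − FC(1−τ)·mag_a ≥ 0`.

## Gene-to-enzyme aggregation

Isozymes (OR-terms of the GPR DNF) are independent usage groups; the
expression ratio of a multi-gene complex is the geometric mean of its
members' fold changes (symmetric in log space), with a limiting-subunit
minimum rule available as `ratio_method="min"`. Only enzymes with at
least one measured member gene enter the Step-1 objective and receive
activation floors; applying floors genome-wide would make most
realistic inputs infeasible. A config flag (`unit_ratio_for_unmeasured`)
instead assigns ratio 1 to all unmeasured enzymes.

Infeasibility is handled in stages: activation floors are dropped first
(logged in the solution), then the builder bisects the constraint
groups (mass balance/bounds, exchange, growth floors, budget,
expression coupling) and names the first one that breaks.

## Reporter metabolites

The raw statistic is `Z = (1/√k)·Σ Φ⁻¹(1−p_g)` over a metabolite's
GPR-neighboring genes; p-values are clipped to `[1e−10, 1−1e−10]`
before the quantile transform. Directional classes follow the usual
convention: the distinct-directional class maps p to one-tailed values
by fold-change sign (`p/2` on the sign side), the mixed classes score
the up- and down-regulated subsets separately with their `p/2`. The
permutation background draws gene sets of matched size without
replacement from the class's tested gene pool; the background mean and
standard deviation are estimated per exact set size up to k = 50 and in
bins of 10 above (toy networks never leave the exact regime).
Permutation p-values are upper-tail with the `(1 + #{Z* ≥ Z})/(n+1)`
correction, Benjamini–Hochberg is applied within each class, and the
significance flag additionally caps reported hits at the top 5% of the
tested metabolite list per class.

## Synthetic study conditions

The generator emulates a two-state experiment on the toy network:
condition *b* doubles the fermentative branch (LDH → lactate export)
and scales the oxidative branch to 0.8×, with glucose uptake following
stoichiometrically; glutamine flux is unchanged. Gene log2 fold changes
equal the planted reaction flux ratios plus Gaussian noise (σ = 0.1
log2 units); q-values are synthesized rank-based so regulated genes
pass the q < 0.1 convention (differential-expression testing is out of
scope). Extracellular abundances integrate the true exchange fluxes
over one time unit from the medium baseline (glucose 20, lactate 0,
glutamine 5 a.u.) with multiplicative log-normal noise (σ = 0.1), and
significance flags fire when a delta exceeds twice the noise scale.
The planted flux pair is validated at generation time (exact mass
balance, bounds), so every planted shift is realizable.

What the generator does *not* emulate: measurement batch effects,
compositional normalization of GC-MS intensities, growth dilution of
the medium, intracellular pools, or any kinetic saturation — passing
the recovery tests shows the optimization recovers planted *relative*
shifts under idealized noise, not that fluxes in real cultures would be
predicted at this accuracy.

## Numerical choices

- LPs are assembled sparsely and solved with HiGHS (scipy); variables
  are ordered by (reaction, isozyme, direction), making degenerate
  optima reproducible for a fixed solver.
- The test suite cross-checks Step-1/Step-2 optima against a separately
  coded GLPK encoding (explicit flux variables tied to usage sums;
  absolute values as p/m split pairs) to 1e−5 relative, on randomized
  structural variants of the toy network.
- Pathway shares divide summed |flux| per pathway by the mapped total
  per condition; an all-zero mapped condition is an error rather than a
  0/0.

## Problem sizes

Tests and the acceptance script run the full pipeline on the 13-reaction
toy network and variants (17 LP columns per condition before deviation
variables), 20-seed recovery batches, and reporter backgrounds of
1,000–10,000 permutations over ~100 gene sets — sizes chosen so the
whole suite documents the method's properties in seconds while staying
well inside the regime where the GLPK cross-check is exact.

## Known limitations

- Two conditions only; multi-condition designs must be run pairwise.
- Expression ratios are per-enzyme scalars; no isoform kinetics,
  proteomics, or post-translational regulation.
- The LP-pure reversibility treatment can in principle return futile
  forward+backward usage when parsimony pressure is removed (e.g. a
  binding total-flux budget).
- Exchange constraints assume equal sampling intervals across
  conditions; growth dilution and evaporation are ignored.
- The reporter background conditions on the tested gene pool, so
  heavily unbalanced sign distributions make the mixed-class pools
  small and their backgrounds coarse.
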
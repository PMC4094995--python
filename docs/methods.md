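# Methods

## Model and problem statement

A metabolic model is a stoichiometric matrix `S` (metabolites ×
reactions), flux bounds, a biomass pseudo-reaction consuming the growth
precursors, and a growth environment given as nutrient uptake caps and
permitted secretions. All fluxes are in mmol/gDW/h. Gap-filling takes
such a model `N` that cannot grow (max `f_b = 0` under FBA) plus a
candidate pool `M` with non-negative costs `c_r`, and proposes subsets
`R ⊆ M` whose addition makes `f_b > 0`.

Two solvers are implemented over the same LP skeleton:

1. **LP binary search** (the package's core). One LP over `N ∪ M ∪
   exchanges` with objective `δ·f_b − Σ_{r∈M} c_r f_r`, maximized
   subject to `S v = 0`, `0 ≤ v ≤ ub`. The constraint matrix and the
   penalty vector are assembled once (sparse CSR); only the biomass
   objective coefficient changes between solves. `δ` starts at `|M|`
   (large enough that many candidates can be profitable at once) and is
   halved on a bracket `(lo, hi] ⊆ (0, |M|]`: growth at `δ` records the
   active candidates and moves `hi ← δ`; no growth moves `lo ← δ`; the
   loop stops at bracket width ≤ 1. The solve count is therefore at most
   `⌈log₂|M|⌉ + 1` (probe included); `iteration_count` computes this and
   the driver asserts nothing beyond it. Recorded sets are deduplicated
   (keeping the smallest-δ occurrence's fluxes) and returned sorted by
   set size, then total cost, then ids — a deterministic order.

2. **MILP oracle** (exact baseline). Binary `y_r` per candidate, linking
   `f_r ≤ M_r·y_r`, hard growth constraint `f_b ≥ growth_floor`,
   objective `min Σ c_r y_r`. The full biomass is enforced as a
   constraint rather than traded against a per-metabolite gain; the
   gain-based soft-biomass formulation (each producible biomass
   metabolite worth `biomass_gain = 500` against candidate costs) is a
   documented alternative used by curation suites for the wider problem
   of also gap-filling the biomass list, which is out of scope here.

Both run on HiGHS through `scipy.optimize.linprog` / `milp`.

## Numerical choices

- `eps_balance = 1e-6`: steady-state residual tolerance; solutions
  report their actual residual. Coefficients are doubles — LP arithmetic
  sets the accuracy floor, so exact rationals would buy nothing.
- `eps_growth = 1e-6` / `eps_active = 1e-8`: "non-zero" thresholds for
  biomass and candidate fluxes. The method defines neither numerically;
  both are arguments everywhere they matter and CLI flags.
- Unbounded exchanges get a finite sentinel bound `FLUX_CAP = 1e6` so
  every LP is bounded and ineffective arbitrarily-high fluxes are cut.
- MILP big-M: per-candidate `M_r = min(ub_r, FLUX_CAP)`, the tightest
  valid constant. A uniform big-M of `1e6` interacts badly with the
  solver's integrality tolerance (~1e-6): a relaxation value `y ≈ 1e-6`
  counts as integral yet licenses up to one unit of flux, enough to fake
  the growth floor. Defensively, every MILP answer is re-verified by
  plain FBA; if it fails, a combinatorial cut `Σ_{r∉R} y_r ≥ 1` is added
  and the program re-solved. The cut is exact, not heuristic: a set that
  does not restore growth has no restoring subset (adding reactions
  never removes feasibility), so no true solution is excluded.
- MILP growth floor default `1e-4`, not `eps_growth`: the floor must sit
  clearly above LP feasibility tolerances once big-M linking is in play,
  and clearly below any real growth rate; it is a parameter.
- LP degeneracy: optima need not be unique, and the recorded active set
  is whichever vertex the solver returns. Runs are deterministic for
  fixed inputs (HiGHS is), but alternative optima with equal objective
  may exist; the verifier judges sets by what they enable, not by which
  vertex produced them.

## Preprocessing

- Reversible reactions are split into two opposed irreversible ones
  (`_fwd`/`_rev` suffixes; derived-id collisions are errors), so all
  fluxes are non-negative. Splitting preserves the FBA optimum — tested
  against a free-sign LP oracle. Each split candidate direction inherits
  the full parent cost: directions are independent suggestions, and the
  search can then name the productive direction in its answer.
- Generic (compound-class) reactions are expanded against a
  user-supplied class→members map. Distinct classes combine by Cartesian
  product; classes declared *linked* substitute positionally in lockstep
  (a class and its phosphorylated counterpart, say). A class appearing
  with one net coefficient is substituted once — the same member on both
  conceptual sides. An empty class makes the reaction uninstantiable; it
  is dropped with a warning.
- The growth environment becomes boundary exchanges `EX_<m>_in` (bounded
  by the uptake cap) and `EX_<m>_out`; attachment is idempotent.

## Default cost scheme

`spontaneous = 1 ≤ in_range = 5 ≤ unknown = 10 ≤ out_of_range = 15`,
`biomass_gain = 500`. A spontaneous reaction can occur in any organism;
a reaction never observed in the organism's taxonomic range is the least
plausible suggestion. Only relative values matter; the gain/in-range
ratio of 100 means (in the soft-biomass MILP variant) one more
producible biomass metabolite outweighs up to 100 in-range additions.
Enzymatic candidates must carry a taxonomic status to be costed;
explicit costs always win.

## What the synthetic generator emulates — and what it does not

`make_chain_model` builds a branched pathway: a linear backbone fed by
one capped nutrient (default 10 mmol/gDW/h), one branch reaction per
biomass precursor, biomass coefficients of 0.01 mmol/gDW per precursor
(real biomass equations use small fractional coefficients; this also
keeps every candidate's per-unit-biomass cost far below the initial
weight `δ = |M|`, the regime the method is designed for — with
database-sized pools `|M|` dwarfs any cost). Every reaction is essential
by construction, so any knockout prohibits growth and the removed set is
the unique minimal completion — which is what makes oracle comparisons
crisp. `knockout` asserts growth is actually prohibited; `add_decoys`
dilutes the pool with reactions tied to fresh dead-end metabolites,
which steady state pins to zero flux, so decoys are never usable — the
pool's *size* is realistic, its distractors are maximally harmless.

Two purpose-built fixtures cover behaviors the essential-chain design
cannot show: `make_multi_solution_fixture` (a flux-capped cheap
candidate vs an uncapped pricier one, biomass coefficient 1.0 so the
activation thresholds land inside the searched δ range) makes the search
record several distinct sets; `make_low_flux_fixture` (a side substrate
capped at 0.001 mmol/gDW/h feeding a biomass-boosting shortcut) makes
the LP over-suggest a non-essential candidate at ~1e-4 relative flux.

Consequences for interpretation: passing tests show the algorithm's
contracts (soundness of returned sets, the solve-count bound, oracle
dominance, directional recovery) on networks whose completions are
unambiguous. They do not show recovery rates on realistic topologies —
redundant pathways, cofactor coupling, compartments, or decoys that
*partially* help are all absent, and with them the harder identifiability
questions a genome-scale database pool raises.

## Verification and pruning

`verify_solution` re-solves plain FBA on `N ∪ R` with candidates
unpenalized: the only claim a suggested set makes. `prune_low_flux`
drops candidates below a relative flux threshold (default 0.01 of the
set's maximum candidate flux — the notion is inherently relative, an
absolute cutoff would not transfer across models), re-verifies, refreshes
fluxes from the verifying solve and repeats; it returns the input
unchanged if the reduction breaks growth, so its output always verifies
and is always a subset of its input. This is a greedy batch procedure;
exact minimal-subset extraction is the MILP's job.

## Problem sizes used in the shipped protocol

The benchmark sweep runs 50 generated instances spanning 1–14 knockouts
with pools from 3 to ~5,000 candidates; oracle comparisons use pools of
at most ~10 candidates so exhaustive subset enumeration stays exact.
These sizes exercise the log-bound and soundness claims across three
orders of magnitude of pool size while keeping the whole protocol a
matter of seconds on one CPU.

## Known limitations

- Heuristic only: the LP search can return supersets of the minimum
  (the low-flux exhibit is the canonical case) and may report
  infeasibility whenever no candidate subset produces *every* biomass
  metabolite; the standing advice then is to reduce the biomass
  reaction's metabolite list. Nutrients, secretions and biomass
  composition are taken as given, never searched.
- Single-compartment semantics: compartment tags are carried, not
  interpreted; no transport modeling, thermodynamics, or gene–protein–
  reaction rules.
- The bracket search never probes δ < 1 (width-1 termination), so
  candidate regimes whose activation thresholds lie entirely below 1
  are invisible to it — irrelevant at database pool sizes, visible on
  toy pools with unit biomass coefficients.
- Native I/O is the package's JSON dialect only; no SBML reader.
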
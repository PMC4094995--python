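# fastgapfill

LP-only gap-filling of steady-state metabolic reaction networks, with an
exact minimum-cost MILP oracle for small instances.

## The problem

Flux balance analysis (FBA) models an organism's metabolism as a linear
program: find per-reaction fluxes `v ≥ 0` satisfying the steady-state
mass balance `S v = 0` (one equality per metabolite) and flux bounds,
maximizing the flux `f_b` of a biomass pseudo-reaction that consumes the
organism's growth precursors. A freshly reconstructed network is usually
*incomplete*: `f_b = 0` under the intended growth medium because some
biosynthesis step is missing. **Gap-filling** selects reactions from a
candidate pool `M` (typically a large reaction database) whose addition
restores `f_b > 0` — without claiming the organism actually has the
enzymes, only proposing candidates for curation.

The standard formulation is a mixed-integer program (one binary
inclusion variable per candidate, minimize total cost subject to
growth), which is exact but can take hours on database-sized pools. This
package implements the LP-only alternative: solve

```
maximize   δ·f_b − Σ_{r∈M} c_r·f_r
subject to S v = 0,  0 ≤ v ≤ ub
```

over the network *plus all candidates*, where `c_r ≥ 0` is each
candidate's cost (how implausible it is for the organism) and the
biomass weight `δ` is tuned by **binary search over (0, |M|]**, starting
at `δ = |M|`. Whenever a solve yields growth, the candidates carrying
flux above a threshold are recorded as one suggested set and the search
presses `δ` down; the whole run takes at most `⌈log₂|M|⌉ + 1` LP solves.
The method is a heuristic — it returns several growth-restoring sets,
smallest first, but does not guarantee the global minimum; the bundled
MILP oracle provides that ground truth on small pools.

Default candidate costs encode curation plausibility: 1 for spontaneous
(non-enzymatic) reactions, 5 / 10 / 15 for enzymatic reactions inside /
of unknown / outside the organism's taxonomic range, with a biomass gain
of 500 for the soft-biomass MILP variant (gain : in-range cost = 100).
Only the relative values matter.

Audience: people building or curating constraint-based metabolic models,
and anyone who wants a transparent, solver-backed reference
implementation of LP gap-filling with a verifiable benchmark protocol.

## Worked example

```python
from fastgapfill import (
    DEFAULT_SCHEME, add_decoys, fast_gap_filling, knockout,
    make_chain_model, milp_gap_fill, prepare, verify_solution,
)

complete = make_chain_model(3, 1, seed=0)     # grows: nutrient M0 -> ... -> biomass
incomplete, pool = knockout(complete, {"B_M2"})   # remove the terminal step
pool = add_decoys(pool, incomplete, 2, seed=7)    # dilute it among decoys
model, pool = prepare(incomplete, pool, scheme=DEFAULT_SCHEME)

run = fast_gap_filling(model, pool)
print(run.n_lp_solves)                  # 3   (pool of 3: probe + 2 halvings)
best = run.best
print(sorted(best.active_set))          # ['B_M2']
print(best.total_cost)                  # 5.0  (enzymatic, in taxonomic range)
print(best.biomass_flux)                # 1000.0 mmol/gDW/h at the recording delta
print(verify_solution(model, pool, best))   # True: adding B_M2 alone restores growth

oracle = milp_gap_fill(model, pool)
print(sorted(oracle.active_set), oracle.total_cost)   # ['B_M2'] 5.0 — LP matched MILP
```

The search recovered exactly the removed reaction in 3 LP solves, at
cost 5, and the exact oracle agrees that no cheaper completion exists.

The same pipeline is available from the shell, reading and writing a
small JSON model dialect (see `fastgapfill/model.py`):

```sh
fastgapfill fixtures generate --n-metabolites 8 --knockouts 2 --decoys 5 \
    --seed 3 --out-model m.json --out-pool p.json
fastgapfill fgf --model m.json --pool p.json --prune 0.01 --out solutions.json
fastgapfill milp --model m.json --pool p.json --out exact.json
```

`fgf` exits 3 with a recommendation to reduce the biomass reaction when
no candidate subset can produce every biomass metabolite — the method's
known failure mode.

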
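# Methods

## Model

The simulator implements a stochastic cellular automaton of surface-bound
replicators. Sites of an `L × L` torus are empty (state 0) or hold one
replicator of type `i ∈ {1..n}`. Types are *metabolic* (they jointly
catalyse the monomer-producing metabolism) or *parasitic* (they consume
monomers but catalyse nothing). The model assumes error-free replication on
the ecological timescale (no mutation), identical sister strands, and no
explicit metabolite particles or network stoichiometry: the metabolic
neighbourhood radius is the phenomenological proxy for how far metabolites
diffuse on the surface before desorption or consumption.

### Elementary updates

One generation is `L²` elementary site updates at positions drawn uniformly
with replacement ("updated once per time unit *on average*"; a
random-permutation variant — every site exactly once per generation — is
available via `update_sampling="permutation"`). Updates are applied in
place, so later updates within a generation see earlier outcomes — the
standard asynchronous-automaton contract.

* Occupied site → empty with probability `p_d` (default 0.2), else unchanged.
* Empty site: every replicator `f` inside the replication window `r`
  centred on the empty site bids `C_f = k_f · M_f`, with

      M_f = ( ∏_{i ∈ metabolic} x_i(f) )^(1/n_m)

  over `f`'s own metabolic window `h` (the focal replicator counts itself;
  the empty centre contributes nothing). The site stays empty with
  probability `C_e / (C_e + Σ_m C_m)` (default `C_e = 2.0`), else the copy
  of claimant `f` wins with probability `C_f / (C_e + Σ_m C_m)`. The parent
  keeps its site; the copy lands on the updated empty site.

The geometric mean is the implemented reading of the metabolic function (a
raw-product mode, `metabolic_function="product"`, is retained for
sensitivity checks); under either, `M_f = 0` exactly when some metabolic
type is absent from the window, which is the gating that produces local
advantage-of-the-rare regulation. Parasites use the same `M` over metabolic
types only; their own abundance never enters any `M`.

### Diffusion

Replicator mobility follows the Toffoli–Margolus scheme: a uniformly random
2×2 block (any anchor, toroidal wrap) rotates a quarter turn, left or right
with equal probability. `round(D · L²/4)` rotations per generation realise
an average of `D` single-site steps per site per generation (each rotation
displaces four sites by one step). By default rotation events are shuffled
uniformly at random among the site updates of the generation
(`schedule="interleaved"`, implemented by choosing the next event type with
probability proportional to events remaining — exactly a uniform random
interleaving); `schedule="diffusion_after"` performs all rotations after
the site updates. Even `D = 0` retains the intrinsic mixing of offspring
placement into adjacent sites.

### Initialisation, stopping, classification

`init_grid` occupies exactly `round(init_occupancy · L²)` sites (default
80 %), chosen uniformly without replacement, each with a uniformly random
type; the count is exact rather than Bernoulli so the stated occupancy is
reproduced precisely. The run classification at `t_max` (default 1000):
**coexistent** iff every metabolic type has at least one copy; **collapsed**
if nothing survives; **partial** otherwise. Parasite extinction is reported
separately and does not make a run partial. Once any metabolic type is
globally extinct the metabolic product is zero everywhere, no replication
can ever occur again and the lattice decays geometrically (factor
`1 − p_d` per generation); runs therefore stop early at that point
(`early_stop`, on by default) and are classified collapsed with final
counts extrapolated to zero — exact for any remaining horizon beyond ~100
generations at `p_d = 0.2`.

## Randomness and determinism

All stochastic choices of a run consume one PCG32 stream seeded from
`params.seed` (initial occupancy uses a separate PCG64 stream from the same
seed). The draw order is fixed and documented in the kernel module:
interleave choice, event position, then the event's own draws; the lottery
uses a single uniform against the cumulative claim vector with the
empty-site claim first and claimants in row-major window order (the order
is irrelevant in distribution but pinned for reproducibility). Identical
seed and parameters give bit-identical grids, censuses and snapshots.
Experiment drivers derive per-cell seeds by hashing the base seed with the
cell labels (SHA-256, 31-bit), so sweep cells are independent of execution
order and stable across processes.

## Numerical implementation

The update engine is JIT-compiled (numba). Two mathematically identical
claim-evaluation routes exist, chosen by a cost model: a direct scan of each
claimant's metabolic window, and an incrementally maintained per-site table
of metabolic-window counts (`hcounts`), updated by boundary strips when a
rotation moves a replicator and by whole-window increments on birth/decay.
The table route wins for large replication windows (many claimants per
lottery); the direct route wins when diffusion is intense relative to the
lottery rate. A property test asserts the two routes produce bit-identical
trajectories, and that the incremental table equals a from-scratch recount
after heavily mixed runs. Integer claim products use a precomputed
`p → p^(1/n_m)` table when the largest reachable product is small, falling
back to floating-point `pow`; products that could overflow 64-bit integers
switch to float accumulation. Claim ties and floating-point edge cases:
with zero total claim mass (no claimant and `C_e = 0`) the site stays empty
with probability one.

## Parameters that matter

| parameter | meaning | default | notes |
|---|---|---|---|
| `L` | lattice side (sites) | 300 | experiments accept desk-scale overrides (100–150) |
| `p_d` | decay probability /site /update | 0.2 | sets turnover rate |
| `C_e` | empty-site claim | 2.0 | replication threshold scale |
| `D` | diffusion steps /site /generation | 0 | 0–100 studied |
| `r` | replication window | — | `N`, 3, 5, 7, 25, 37 |
| `h` | metabolic window | — | same labels, plus `MF` |
| `k_i` | replication rates | 3,5,7,9 | ladders `3 + 2i` for size searches |
| `init_occupancy` | initial filled fraction | 0.8 | exact count |
| `t_max` | generations | 1000 | populations equilibrate well before this |

## Experiment drivers

`run_replicates` runs seeds `base .. base+n−1`. `run_sweep` crosses
`(r, h, D)` levels, five replicates per cell by default, and reports
coexistent/extinct/partial counts, parasite extinctions, mean final density
and metabolic:parasite abundance ratios as a tidy table.
`parasite_experiment` appends parasitic types to a metabolic community.
`mean_field_control` sets `h` to the whole lattice. `max_system_size`
searches the largest `n` with rates `k_i = 3 + 2i` that a cell keeps
coexistent under a majority rule (default ≥3 of 5 replicates; the paper-style
report prints x/5 counts without fixing a threshold, so the majority is a
package choice and configurable). Search strategies: `increment` (default;
n = 2, 3, … until first failure, monotonicity assumed), `scan_all` (every n
up to a cap, detects non-monotone cases), and `bracket` (single-replicate
probes at a stride, bisection refinement, then majority confirmation at the
boundary — the same verdict as `increment` under monotonicity at a fraction
of the runs; probe runs are cached as replicate zero). A one-type community
is checked before reporting q = 0.

## Desk-scale study sizes

Full-scale study conditions (`L = 300`) are the defaults throughout the
library. The shipped end-to-end checks and the acceptance search run at
`L = 100` with `t = 1000` generations and 5 replicates per condition — sizes
chosen so the whole battery executes on a single CPU in well under an hour
while reproducing every qualitative regime (dense coexistence, mean-field
collapse, the interior h-optimum, parasite expulsion/regulation, and a
maximum community size of 13 at the most favourable tested cell, matching
the full-scale value). At `L = 100` the per-type population at `n = 13` is
still ≈600 copies, large enough that drift-driven misclassification under
the majority rule is rare.

## What the checks do and do not show

The acceptance battery certifies the implemented dynamics: the exact
structural identities (claim normalisation, metabolic gating, diffusion
count conservation, event budgets), distribution-level agreement of the
elementary lottery with the closed-form probabilities, and the qualitative
phase structure of the model at desk scale. It does not validate the model
against laboratory chemistry: the MRM is a phenomenological abstraction in
which metabolite transport is a window radius, replication is error-free,
and metabolic stoichiometry is unmodelled. Conclusions about real
mineral-surface RNA systems inherit those assumptions.

## Known limitations

* Square torus and the two window families only; no hexagonal or
  off-lattice geometry, no non-periodic boundaries.
* No mutation/sequence evolution, no complementary-strand bookkeeping, no
  explicit metabolite transport or desorption energetics.
* Communities larger than the metabolic window are structurally impossible
  (`q ≤ h-window size`); searches respect but do not exploit this bound.
* The q-search assumes coexistence is monotone decreasing in community
  size; `scan_all` exists to audit that assumption on small grids.
* Moore windows larger than the lattice are rejected rather than allowed to
  wrap onto themselves.
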
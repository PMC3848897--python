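"""MRM update rules: metabolic function, replication claims, decay,
Toffoli-Margolus diffusion, and the generation/run drivers.

The model couples two stochastic processes on the toroidal lattice:

* **Replication/decay.** An occupied site empties with probability ``p_d``.
  An empty site runs a lottery among the replicators in its replication
  neighbourhood: replicator f bids the claim C_f = k_f * M_f, where M_f is
  the geometric mean of the copy numbers of all *metabolic* types inside f's
  own metabolic neighbourhood (zero whenever any metabolic type is locally
  absent -- metabolism, and hence monomer supply, breaks down). The empty
  state itself bids the constant C_e; bids are normalised to probabilities.

* **Diffusion.** Replicators mix by Toffoli-Margolus rotations: randomly
  anchored 2x2 blocks turn 90 degrees left or right with equal probability.
  D sets the mean number of diffusion steps per site per generation.

One generation consists of L**2 elementary site updates at uniformly random
positions plus round(D * L**2 / 4) rotations, interleaved at random.
"""

from __future__ import annotations

import math
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

from . import _kernels
from .core import (
    Census,
    ConfigurationError,
    LatticeState,
    MEAN_FIELD,
    Neighborhood,
    RunResult,
    SimulationParams,
    init_grid,
    local_type_counts,
    neighborhood_offsets,
)

__all__ = [
    "metabolic_function",
    "claim",
    "occupancy_probabilities",
    "update_empty_site",
    "update_occupied_site",
    "tm_rotate_block",
    "diffusion_events_per_generation",
    "run_generation",
    "run_simulation",
]


# ---------------------------------------------------------------------------
# Local fitness components (pure reference implementations)


def metabolic_function(
    x: Sequence[int] | np.ndarray,
    metabolic_ids: Iterable[int],
    mode: str = "geometric_mean",
) -> float:
    """Metabolic function M of a replicator with local type counts ``x``.

    M is the geometric mean (or, in "product" mode, the raw product) of the
    copy numbers of the metabolic types within the replicator's metabolic
    neighbourhood; M = 0 as soon as any metabolic type is absent. Parasite
    counts never enter M.
    """
    met = list(metabolic_ids)
    if not met:
        raise ConfigurationError("metabolic_ids must not be empty")
    x = np.asarray(x)
    counts = x[np.asarray(met, dtype=np.intp)]
    if np.any(counts <= 0):
        return 0.0
    prod = float(np.prod(counts.astype(np.float64)))
    if mode == "product":
        return prod
    return prod ** (1.0 / len(met))


def claim(k: float, M: float) -> float:
    """Replication claim C = k * M of a replicator bidding for an empty site."""
    return k * M


def occupancy_probabilities(
    claims: Sequence[float], C_e: float
) -> tuple[float, np.ndarray]:
    """Normalise claims: p_f = C_f / (C_e + sum C_m), p_e = C_e / (...).

    Returns (p_e, p_f array). With no claimants and C_e = 0 the site stays
    empty with probability 1 by convention.
    """
    claims = np.asarray(claims, dtype=np.float64)
    if np.any(claims < 0):
        raise ValueError("claims must be non-negative")
    total = C_e + claims.sum()
    if total <= 0.0:
        return 1.0, np.zeros_like(claims)
    return C_e / total, claims / total


def diffusion_events_per_generation(D: float, L: int) -> int:
    """Number of 2x2 rotations per generation: round(D * L**2 / 4). Each
    rotation displaces 4 sites by one step, so this realises an average of D
    diffusion steps per site per generation."""
    if D < 0:
        raise ConfigurationError(f"D must be >= 0, got {D}")
    return int(round(D * L * L / 4.0))


# ---------------------------------------------------------------------------
# Kernel argument packing


class _Packed:
    """Immutable numba-ready views of a SimulationParams."""

    def __init__(self, params: SimulationParams):
        self.params = params
        self.r_off = neighborhood_offsets(params.r_spec)
        self.mean_field = params.h_spec.is_mean_field
        if self.mean_field:
            self.h_off = np.zeros((0, 2), dtype=np.int64)
            h_window = params.L * params.L
        else:
            self.h_off = neighborhood_offsets(params.h_spec)
            h_window = self.h_off.shape[0]
        self.kvec = params.k_by_type
        self.met_ids = np.array(params.metabolic_ids, dtype=np.int64)
        self.met_slot = np.full(params.n_types + 1, -1, dtype=np.int64)
        for slot, tid in enumerate(self.met_ids):
            self.met_slot[tid] = slot
        self.inv_nm = 1.0 / len(self.met_ids)
        self.geo_mode = params.metabolic_function == "geometric_mean"
        n_m = len(self.met_ids)
        base, rem = divmod(h_window, n_m)
        self.max_prod = (base + 1) ** rem * base ** (n_m - rem) if base or rem else 0
        self.int_safe = self.max_prod < 2 ** 62
        self.mtab = _root_table(self.max_prod, n_m) if (
            self.geo_mode and not self.mean_field
        ) else np.zeros(0, dtype=np.float64)
        offs = [self.r_off] if self.mean_field else [self.r_off, self.h_off]
        # +1 margin so one-step rotation moves of border windows stay in range
        self.pad = int(max(int(np.abs(o).max()) for o in offs)) + 1
        self.wrap = np.arange(-self.pad, params.L + self.pad, dtype=np.int64) % params.L
        self.n_rot = diffusion_events_per_generation(params.D, params.L)
        self.h_is_moore = params.h_spec.kind == "moore"
        self.h_u = (params.h_spec.size - 1) // 2 if self.h_is_moore else 0
        # maintain the per-site count table only where it pays: its rotation
        # upkeep (boundary strips per move) must undercut the direct window
        # scans it replaces (rough op-count model at ~30% empty sites)
        if self.mean_field:
            self.use_counts = False
        else:
            h_n = self.h_off.shape[0]
            n_m = len(self.met_ids)
            upkeep = self.n_rot * (20 + (16 * self.h_u if self.h_is_moore else 8 * h_n))
            scan_extra = 0.3 * params.L ** 2 * self.r_off.shape[0] * max(
                2 * h_n - n_m, 1
            )
            self.use_counts = upkeep < scan_extra
        # scratch buffers (claims indexed in row-major replication-offset order)
        self.cnt_buf = np.zeros(params.n_types + 1, dtype=np.int64)
        self.cnt_slot_buf = np.zeros(len(self.met_ids), dtype=np.int64)
        self.claim_buf = np.zeros(self.r_off.shape[0], dtype=np.float64)
        self.claim_type_buf = np.zeros(self.r_off.shape[0], dtype=np.int64)
        self.perm_buf = (
            np.zeros(params.L * params.L, dtype=np.int64)
            if params.update_sampling == "permutation"
            else np.zeros(1, dtype=np.int64)
        )

    def hcounts(self, grid: np.ndarray) -> np.ndarray:
        """Per-site metabolic-window count table for the current grid (an
        empty dummy in the mean-field limit, which reads global counts)."""
        if not self.use_counts:
            return np.zeros((1, 1, 1), dtype=np.int8)
        return _kernels.recount_hcounts(
            grid, self.h_off, self.met_slot, self.met_ids.shape[0],
            self.wrap, self.pad,
        )

    def run(self, state, gcounts, n_gens, census_out, early_stop, hcounts=None):
        if hcounts is None:
            hcounts = self.hcounts(state.grid)
        p = self.params
        out = _kernels.run_generations(
            state.grid, state.rng_state, gcounts, n_gens,
            self.r_off, self.h_off, self.mean_field, self.kvec, self.met_ids,
            self.met_slot, self.inv_nm, self.geo_mode, self.mtab,
            p.p_d, p.C_e, self.n_rot,
            p.schedule == "interleaved",
            p.update_sampling == "permutation",
            early_stop, self.wrap, self.pad, census_out, self.perm_buf,
            self.cnt_buf, self.cnt_slot_buf, self.claim_buf,
            self.claim_type_buf, hcounts, self.use_counts, self.int_safe,
            self.h_is_moore, self.h_u,
        )
        return out


@lru_cache(maxsize=128)
def _packed(params: SimulationParams) -> _Packed:
    """Cached kernel views: params are frozen, scratch buffers are reused
    sequentially (the engine is single-threaded)."""
    return _Packed(params)


def _root_table(max_prod: int, n_m: int, cap: int = 1 << 20) -> np.ndarray:
    """Lookup table p -> p**(1/n_m) up to the largest count product reachable
    in the metabolic window, or an empty array when too large (the kernel
    then falls back to pow)."""
    if max_prod > cap:
        return np.zeros(0, dtype=np.float64)
    tab = np.arange(max_prod + 1, dtype=np.float64) ** (1.0 / n_m)
    tab[0] = 0.0
    return tab


# ---------------------------------------------------------------------------
# Elementary updates (operate on LatticeState, consuming its RNG stream)


def update_empty_site(
    state: LatticeState, pos: tuple[int, int], params: SimulationParams
) -> int:
    """Sample the next state (0 or a winning type_id) of the empty site at
    ``pos``. Claimants are the replicators within the replication
    neighbourhood of pos; each bids k * M evaluated over its own metabolic
    neighbourhood. The grid is not modified; the RNG state advances."""
    if state.grid[pos] != 0:
        raise ValueError(f"site {pos} is not empty")
    pk = _packed(params)
    gcounts = state.type_counts(params.n_types).astype(np.int64)
    return int(
        _kernels.update_empty_site(
            state.grid, pos[0], pos[1], state.rng_state, pk.r_off, pk.h_off,
            pk.mean_field, pk.kvec, pk.met_ids, pk.inv_nm, pk.geo_mode, pk.mtab,
            params.C_e, pk.wrap, pk.pad, gcounts, pk.cnt_buf, pk.claim_buf,
            pk.claim_type_buf,
        )
    )


def update_occupied_site(
    state: LatticeState, pos: tuple[int, int], params: SimulationParams
) -> int:
    """Sample the next state of the occupied site at ``pos``: 0 (decay, with
    probability p_d) or the unchanged type. The grid is not modified."""
    t = int(state.grid[pos])
    if t == 0:
        raise ValueError(f"site {pos} is empty")
    u = _kernels._rand01(state.rng_state)
    return 0 if u < params.p_d else t


def tm_rotate_block(
    state: LatticeState, anchor: tuple[int, int], direction: str
) -> LatticeState:
    """Rotate the 2x2 block anchored at ``anchor`` a quarter turn in place
    ("right" = clockwise, "left" = counter-clockwise) and return the state."""
    if direction not in ("left", "right"):
        raise ValueError(f"direction must be 'left' or 'right', got {direction!r}")
    _kernels.rotate_block(
        state.grid, state.L, anchor[0] % state.L, anchor[1] % state.L,
        direction == "right",
    )
    return state


# ---------------------------------------------------------------------------
# Generation and run drivers


def _census_from_gcounts(t: int, gcounts: np.ndarray) -> Census:
    return Census(t=t, counts=gcounts[1:].copy(), empties=int(gcounts[0]))


def run_generation(
    state: LatticeState, params: SimulationParams, t: int = 0
) -> tuple[LatticeState, Census]:
    """Advance the lattice by one generation in place and return its census.

    Executes exactly L**2 elementary site updates plus round(D*L**2/4)
    Toffoli-Margolus rotations, interleaved per params.schedule.
    """
    pk = _packed(params)
    gcounts = state.type_counts(params.n_types).astype(np.int64)
    census_out = np.zeros((1, params.n_types + 1), dtype=np.int64)
    pk.run(state, gcounts, 1, census_out, early_stop=False)
    return state, _census_from_gcounts(t + 1, census_out[0])


def run_simulation(
    params: SimulationParams,
    snapshot_times: Sequence[int] = (),
    census_every: int = 1,
) -> RunResult:
    """Run a full MRM simulation: init_grid, then t_max generations.

    Stops early once any metabolic type is globally extinct (if
    params.early_stop; always once all are): local monomer production is then
    impossible everywhere, only decay remains, and the run is classified
    collapsed with final counts extrapolated to zero.

    Returns the per-generation census series (strided by ``census_every``;
    generation 0 and the last recorded generation always included), outcome
    label, final density and per-type counts, and optional grid snapshots.
    """
    state = init_grid(params)
    pk = _packed(params)
    n_states = params.n_types + 1
    gcounts = state.type_counts(params.n_types).astype(np.int64)
    hcounts = pk.hcounts(state.grid)
    L2 = params.L * params.L

    snapshots: dict[int, np.ndarray] = {}
    snap_times = sorted(set(int(s) for s in snapshot_times))
    for s in snap_times:
        if not 0 <= s <= params.t_max:
            raise ConfigurationError(f"snapshot time {s} outside [0, t_max]")
    if 0 in snap_times:
        snapshots[0] = state.grid.copy()

    series = [_census_from_gcounts(0, gcounts)]
    census_buf = np.zeros((max(params.t_max, 1), n_states), dtype=np.int64)
    t = 0
    stopped = False
    n_site_updates = 0
    n_rotations = 0
    # run in segments between requested snapshot times
    boundaries = [s for s in snap_times if s > 0]
    if not boundaries or boundaries[-1] != params.t_max:
        boundaries.append(params.t_max)
    for b in boundaries:
        if stopped or t >= b:
            if b in snap_times and not stopped:
                snapshots[b] = state.grid.copy()
            continue
        n_gens = b - t
        done, seg_stopped, su, rot = pk.run(
            state, gcounts, n_gens, census_buf[t : t + n_gens],
            params.early_stop, hcounts=hcounts,
        )
        for g in range(int(done)):
            tg = t + g + 1
            if tg % census_every == 0 or g == int(done) - 1:
                series.append(_census_from_gcounts(tg, census_buf[t + g]))
        t += int(done)
        n_site_updates += int(su)
        n_rotations += int(rot)
        stopped = bool(seg_stopped)
        if b in snap_times and t == b:
            snapshots[b] = state.grid.copy()

    met_ids = list(params.metabolic_ids)
    par_ids = list(params.parasite_ids)
    if stopped and t < params.t_max:
        # doomed: a metabolic type is gone, M = 0 everywhere, decay only
        per_type_final = np.zeros(params.n_types, dtype=np.int64)
        final_density = 0.0
    else:
        per_type_final = gcounts[1:].copy()
        final_density = float(gcounts[1:].sum()) / L2
    met_alive = [per_type_final[i - 1] > 0 for i in met_ids]
    if all(met_alive):
        outcome = "coexistent"
    elif not any(per_type_final > 0):
        outcome = "collapsed"
    else:
        outcome = "partial"
    parasite_extinct = {i: bool(per_type_final[i - 1] == 0) for i in par_ids}
    return RunResult(
        outcome=outcome,
        census_series=series,
        final_density=final_density,
        per_type_final=per_type_final,
        parasite_extinct_flags=parasite_extinct,
        params=params,
        stopped_at=t if stopped and t < params.t_max else None,
        snapshots=snapshots,
        n_site_updates=n_site_updates,
        n_rotations=n_rotations,
    )
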
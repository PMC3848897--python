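"""Numba kernels driving the MRM stochastic cellular automaton.

All stochastic choices consume a single PCG32 stream carried in a uint64[2]
array (state word, odd increment), in a fixed documented order:

  per generation: [permutation shuffle if enabled], then per event either an
  interleave draw (site update vs diffusion rotation, proportional to events
  remaining) followed by the event's own draws, or -- under the
  "diffusion_after" schedule -- all site updates then all rotations.

  site update: one position draw; occupied site: one uniform for decay;
  empty site: one uniform against the cumulative claim vector (empty-site
  claim C_e first, then claimants in row-major replication-offset order).

  rotation: one anchor draw, one direction bit (1 = clockwise).

Grid entries are int8 (0 = empty, i >= 1 = type i). Per-type global counts
(gcounts, index 0 = empties) are maintained incrementally, and -- except in
the mean-field limit -- so is a per-site table ``hcounts[i, j, m]`` of the
copy number of each metabolic type within the metabolic neighbourhood
centred on (i, j), which makes a claimant's metabolic function a contiguous
n_m-element product. Rotations update hcounts by boundary strips (a content
moved one step shifts its influence window by one row/column).
"""

import numpy as np
from numba import njit

_MULT = np.uint64(6364136223846793005)
_U32 = np.uint64(0xFFFFFFFF)


@njit(cache=True, inline="always")
def _pcg32(rng):
    old = rng[0]
    rng[0] = old * _MULT + rng[1]
    xorshifted = np.uint32((((old >> np.uint64(18)) ^ old) >> np.uint64(27)) & _U32)
    rot = np.uint32(old >> np.uint64(59))
    return np.uint32(
        (xorshifted >> rot) | (xorshifted << ((np.uint32(32) - rot) & np.uint32(31)))
    )


@njit(cache=True, inline="always")
def _rand01(rng):
    # 32 random bits -> double in [0, 1)
    return np.float64(_pcg32(rng)) * (1.0 / 4294967296.0)


@njit(cache=True, inline="always")
def _randbelow(rng, n):
    # Lemire multiply-shift; bias < 2**-32, negligible at lattice scales
    return np.int64((np.uint64(_pcg32(rng)) * np.uint64(n)) >> np.uint64(32))


# ---------------------------------------------------------------------------
# Metabolic-neighbourhood count table


@njit(cache=True)
def _fill_hcounts(counts, grid, h_off, met_slot, wrap, pad):
    L = grid.shape[0]
    for i in range(L):
        for j in range(L):
            for hh in range(h_off.shape[0]):
                t = grid[wrap[i + h_off[hh, 0] + pad], wrap[j + h_off[hh, 1] + pad]]
                m = met_slot[t]
                if m >= 0:
                    counts[i, j, m] += 1


def recount_hcounts(grid, h_off, met_slot, n_m, wrap, pad):
    """Brute-force hcounts: per-site copy numbers of each metabolic type
    within the metabolic neighbourhood centred on the site.

    int16 when window counts can exceed int8.
    """
    L = grid.shape[0]
    dtype = np.int8 if h_off.shape[0] <= 127 else np.int16
    counts = np.zeros((L, L, int(n_m)), dtype=dtype)
    _fill_hcounts(counts, grid, h_off, met_slot, wrap, pad)
    return counts


@njit(cache=True, inline="always")
def _hcounts_add(hcounts, h_off, wrap, pad, i, j, m, delta):
    # site (i, j) gained/lost one copy of metabolic slot m: every site whose
    # metabolic window covers (i, j) -- the mirrored window -- is affected
    for hh in range(h_off.shape[0]):
        hcounts[wrap[i + h_off[hh, 0] + pad], wrap[j + h_off[hh, 1] + pad], m] += delta


@njit(cache=True, inline="always")
def _hcounts_move(hcounts, h_is_moore, h_off, u, wrap, pad, fi, fj, di, dj, m):
    """Content of metabolic slot m moved one step from (fi, fj) to
    (fi+di, fj+dj); for Moore windows only two boundary strips change."""
    if not h_is_moore:
        _hcounts_add(hcounts, h_off, wrap, pad, fi, fj, m, -1)
        _hcounts_add(hcounts, h_off, wrap, pad, fi + di, fj + dj, m, 1)
        return
    if di != 0:
        lose_r = wrap[(fi - u if di > 0 else fi + u) + pad]
        gain_r = wrap[(fi + di + (u if di > 0 else -u)) + pad]
        for c in range(fj - u, fj + u + 1):
            cc = wrap[c + pad]
            hcounts[lose_r, cc, m] -= 1
            hcounts[gain_r, cc, m] += 1
    else:
        lose_c = wrap[(fj - u if dj > 0 else fj + u) + pad]
        gain_c = wrap[(fj + dj + (u if dj > 0 else -u)) + pad]
        for r in range(fi - u, fi + u + 1):
            rr = wrap[r + pad]
            hcounts[rr, lose_c, m] -= 1
            hcounts[rr, gain_c, m] += 1


# ---------------------------------------------------------------------------
# Elementary updates


@njit(cache=True)
def update_empty_site(
    grid, i, j, rng, r_off, h_off, mean_field, kvec, met_ids, inv_nm,
    geo_mode, mtab, C_e, wrap, pad, gcounts, cnt_buf, claim_buf, claim_type_buf,
):
    """Sample the next state of empty site (i, j): 0 (stays empty) or the
    type_id of the winning claimant, scanning metabolic neighbourhoods
    directly (reference path, used by the single-site API)."""
    n_m = met_ids.shape[0]
    use_tab = mtab.shape[0] > 0
    total = C_e
    nc = 0
    M_mf = 0.0
    if mean_field:
        pf = 1.0
        for q in range(n_m):
            pf *= gcounts[met_ids[q]]
            if pf == 0.0:
                break
        if pf > 0.0:
            M_mf = pf ** inv_nm if geo_mode else pf
    for m in range(r_off.shape[0]):
        ci = wrap[i + r_off[m, 0] + pad]
        cj = wrap[j + r_off[m, 1] + pad]
        t = grid[ci, cj]
        if t == 0:
            continue
        if mean_field:
            M = M_mf
        else:
            for q in range(cnt_buf.shape[0]):
                cnt_buf[q] = 0
            for hh in range(h_off.shape[0]):
                hr = wrap[ci + h_off[hh, 0] + pad]
                hc = wrap[cj + h_off[hh, 1] + pad]
                cnt_buf[grid[hr, hc]] += 1
            if use_tab:
                p = np.int64(1)
                for q in range(n_m):
                    p *= cnt_buf[met_ids[q]]
                    if p == 0:
                        break
                M = mtab[p]
            else:
                pf = 1.0
                for q in range(n_m):
                    pf *= cnt_buf[met_ids[q]]
                    if pf == 0.0:
                        break
                if pf == 0.0:
                    M = 0.0
                else:
                    M = pf ** inv_nm if geo_mode else pf
        C = kvec[t] * M
        if C > 0.0:
            claim_buf[nc] = C
            claim_type_buf[nc] = t
            nc += 1
            total += C
    return _sample_claims(rng, total, C_e, claim_buf, claim_type_buf, nc)


@njit(cache=True, inline="always")
def _sample_claims(rng, total, C_e, claim_buf, claim_type_buf, nc):
    if total <= 0.0:
        # no claimant and zero empty-site claim: stays empty by convention
        _pcg32(rng)  # keep one draw per empty update for a stable stream
        return np.int64(0)
    u = _rand01(rng) * total
    if u < C_e:
        return np.int64(0)
    acc = C_e
    for m in range(nc):
        acc += claim_buf[m]
        if u < acc:
            return claim_type_buf[m]
    return claim_type_buf[nc - 1] if nc > 0 else np.int64(0)


@njit(cache=True)
def _update_empty_direct(
    grid, i, j, rng, r_off, h_off, h_is_moore, h_u, kvec, met_slot, n_m,
    inv_nm, geo_mode, mtab, C_e, wrap, pad, cnt_slot_buf, claim_buf,
    claim_type_buf,
):
    """Empty-site lottery scanning each claimant's metabolic window directly
    (no count table); metabolically equivalent to update_empty_site but
    counting into metabolic slots with an interior fast path."""
    L = grid.shape[0]
    use_tab = mtab.shape[0] > 0
    total = C_e
    nc = 0
    for m in range(r_off.shape[0]):
        ci = wrap[i + r_off[m, 0] + pad]
        cj = wrap[j + r_off[m, 1] + pad]
        t = grid[ci, cj]
        if t == 0:
            continue
        for q in range(n_m):
            cnt_slot_buf[q] = 0
        if h_is_moore and h_u <= ci < L - h_u and h_u <= cj < L - h_u:
            for dr in range(-h_u, h_u + 1):
                row = grid[ci + dr]
                for dc in range(-h_u, h_u + 1):
                    mm = met_slot[row[cj + dc]]
                    if mm >= 0:
                        cnt_slot_buf[mm] += 1
        else:
            for hh in range(h_off.shape[0]):
                mm = met_slot[
                    grid[wrap[ci + h_off[hh, 0] + pad], wrap[cj + h_off[hh, 1] + pad]]
                ]
                if mm >= 0:
                    cnt_slot_buf[mm] += 1
        if use_tab:
            p = np.int64(1)
            for q in range(n_m):
                p *= cnt_slot_buf[q]
                if p == 0:
                    break
            M = mtab[p]
        else:
            pf = 1.0
            for q in range(n_m):
                pf *= cnt_slot_buf[q]
                if pf == 0.0:
                    break
            if pf == 0.0:
                M = 0.0
            else:
                M = pf ** inv_nm if geo_mode else pf
        C = kvec[t] * M
        if C > 0.0:
            claim_buf[nc] = C
            claim_type_buf[nc] = t
            nc += 1
            total += C
    return _sample_claims(rng, total, C_e, claim_buf, claim_type_buf, nc)


@njit(cache=True)
def _update_empty_hcounts(
    grid, hcounts, i, j, rng, r_off, kvec, n_m, inv_nm, geo_mode, mtab,
    int_safe, C_e, wrap, pad, claim_buf, claim_type_buf,
):
    """Empty-site lottery reading claimant metabolic functions from the
    incrementally maintained hcounts table (fast path)."""
    use_tab = mtab.shape[0] > 0
    total = C_e
    nc = 0
    for m in range(r_off.shape[0]):
        ci = wrap[i + r_off[m, 0] + pad]
        cj = wrap[j + r_off[m, 1] + pad]
        t = grid[ci, cj]
        if t == 0:
            continue
        if int_safe:
            p = np.int64(1)
            for q in range(n_m):
                p *= hcounts[ci, cj, q]
                if p == 0:
                    break
            if use_tab:
                M = mtab[p]
            elif p == 0:
                M = 0.0
            else:
                M = np.float64(p) ** inv_nm if geo_mode else np.float64(p)
        else:
            pf = 1.0
            for q in range(n_m):
                pf *= hcounts[ci, cj, q]
                if pf == 0.0:
                    break
            if pf == 0.0:
                M = 0.0
            else:
                M = pf ** inv_nm if geo_mode else pf
        C = kvec[t] * M
        if C > 0.0:
            claim_buf[nc] = C
            claim_type_buf[nc] = t
            nc += 1
            total += C
    return _sample_claims(rng, total, C_e, claim_buf, claim_type_buf, nc)


@njit(cache=True, inline="always")
def rotate_block(grid, L, a, b, clockwise):
    """Quarter-turn rotation of the 2x2 block anchored at (a, b), wrapping."""
    a2 = a + 1 if a + 1 < L else 0
    b2 = b + 1 if b + 1 < L else 0
    tl = grid[a, b]
    tr = grid[a, b2]
    bl = grid[a2, b]
    br = grid[a2, b2]
    if clockwise:
        grid[a, b] = bl
        grid[a, b2] = tl
        grid[a2, b2] = tr
        grid[a2, b] = br
    else:
        grid[a, b] = tr
        grid[a2, b2] = bl
        grid[a, b2] = br
        grid[a2, b] = tl


@njit(cache=True)
def _rotate_maint(
    grid, L, a, b, clockwise, hcounts, h_is_moore, h_off, u, wrap, pad, met_slot
):
    """hcounts strip maintenance for the 2x2 rotation at (a, b), applied
    before the grid itself is rotated."""
    a2 = a + 1 if a + 1 < L else 0
    b2 = b + 1 if b + 1 < L else 0
    tl = grid[a, b]
    tr = grid[a, b2]
    bl = grid[a2, b]
    br = grid[a2, b2]
    if tl == tr and tr == bl and bl == br:
        return
    # clockwise content moves: tl->right, tr->down, br->left, bl->up
    if clockwise:
        moves = ((a, b, 0, 1, tl), (a, b2, 1, 0, tr),
                 (a2, b2, 0, -1, br), (a2, b, -1, 0, bl))
    else:
        moves = ((a, b, 1, 0, tl), (a2, b, 0, 1, bl),
                 (a2, b2, -1, 0, br), (a, b2, 0, -1, tr))
    for fi, fj, di, dj, t in moves:
        m = met_slot[t]
        if m >= 0:
            _hcounts_move(
                hcounts, h_is_moore, h_off, u, wrap, pad, fi, fj, di, dj, m
            )


# ---------------------------------------------------------------------------
# Generation driver


@njit(cache=True)
def run_generations(
    grid, rng, gcounts, n_gens,
    r_off, h_off, mean_field, kvec, met_ids, met_slot, inv_nm, geo_mode, mtab,
    p_d, C_e, n_rot, interleaved, permutation, early_stop,
    wrap, pad, census_out, perm_buf, cnt_buf, cnt_slot_buf,
    claim_buf, claim_type_buf, hcounts, use_counts, int_safe,
    h_is_moore, h_u,
):
    """Advance the lattice by up to n_gens generations.

    One generation = L**2 elementary site updates plus n_rot block rotations,
    interleaved uniformly at random (or rotations after updates).  Census rows
    (gcounts copies) are written to census_out[g]. Returns (generations
    completed, stopped flag, site updates done, rotations done); stops after
    a generation leaves some metabolic type extinct (when early_stop) or all
    metabolic types extinct (always: the system is then inert up to decay).
    """
    L = grid.shape[0]
    L2 = np.int64(L) * np.int64(L)
    n_m = met_ids.shape[0]
    tot_updates = np.int64(0)
    tot_rot = np.int64(0)
    for g in range(n_gens):
        if permutation:
            for q in range(L2):
                perm_buf[q] = q
            for q in range(L2 - 1, 0, -1):
                w = _randbelow(rng, q + 1)
                tmp = perm_buf[q]
                perm_buf[q] = perm_buf[w]
                perm_buf[w] = tmp
        s_u = L2
        s_r = np.int64(n_rot)
        p_next = np.int64(0)
        while s_u + s_r > 0:
            if s_u == 0:
                do_site = False
            elif s_r == 0 or not interleaved:
                do_site = True
            else:
                do_site = _randbelow(rng, s_u + s_r) < s_u
            if do_site:
                if permutation:
                    idx = perm_buf[p_next]
                    p_next += 1
                else:
                    idx = _randbelow(rng, L2)
                i = idx // L
                j = idx - i * L
                t = grid[i, j]
                if t == 0:
                    if use_counts:
                        w = _update_empty_hcounts(
                            grid, hcounts, i, j, rng, r_off, kvec, n_m,
                            inv_nm, geo_mode, mtab, int_safe, C_e, wrap, pad,
                            claim_buf, claim_type_buf,
                        )
                    elif mean_field:
                        w = update_empty_site(
                            grid, i, j, rng, r_off, h_off, mean_field, kvec,
                            met_ids, inv_nm, geo_mode, mtab, C_e, wrap, pad,
                            gcounts, cnt_buf, claim_buf, claim_type_buf,
                        )
                    else:
                        w = _update_empty_direct(
                            grid, i, j, rng, r_off, h_off, h_is_moore, h_u,
                            kvec, met_slot, n_m, inv_nm, geo_mode, mtab, C_e,
                            wrap, pad, cnt_slot_buf, claim_buf, claim_type_buf,
                        )
                    if w > 0:
                        grid[i, j] = np.int8(w)
                        gcounts[w] += 1
                        gcounts[0] -= 1
                        if use_counts:
                            ms = met_slot[w]
                            if ms >= 0:
                                _hcounts_add(
                                    hcounts, h_off, wrap, pad, i, j, ms, 1
                                )
                else:
                    if _rand01(rng) < p_d:
                        grid[i, j] = 0
                        gcounts[t] -= 1
                        gcounts[0] += 1
                        if use_counts:
                            ms = met_slot[t]
                            if ms >= 0:
                                _hcounts_add(
                                    hcounts, h_off, wrap, pad, i, j, ms, -1
                                )
                s_u -= 1
                tot_updates += 1
            else:
                idx = _randbelow(rng, L2)
                a = idx // L
                b = idx - a * L
                clockwise = (_pcg32(rng) & np.uint32(1)) == np.uint32(1)
                if use_counts:
                    _rotate_maint(
                        grid, L, a, b, clockwise, hcounts, h_is_moore,
                        h_off, h_u, wrap, pad, met_slot,
                    )
                rotate_block(grid, L, a, b, clockwise)
                s_r -= 1
                tot_rot += 1
        for q in range(gcounts.shape[0]):
            census_out[g, q] = gcounts[q]
        # stopping: any metabolic extinction dooms the run (M = 0 everywhere)
        n_alive = 0
        for q in range(n_m):
            if gcounts[met_ids[q]] > 0:
                n_alive += 1
        if n_alive == 0 or (early_stop and n_alive < n_m):
            return g + 1, True, tot_updates, tot_rot
    return n_gens, False, tot_updates, tot_rot
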
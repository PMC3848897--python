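"""Independent brute-force oracle for the empty-site occupancy lottery.

Reimplements the claim arithmetic from scratch with plain Python loops and
its own neighbourhood enumeration, so tests can compare the simulator
against an implementation that shares no code with the package kernels.
"""

from __future__ import annotations

import numpy as np


def offsets(kind: str, size: int | None = None) -> list[tuple[int, int]]:
    if kind == "von_neumann":
        return [(-1, 0), (0, -1), (0, 0), (0, 1), (1, 0)]
    assert size is not None and size % 2 == 1
    u = (size - 1) // 2
    return [(dr, dc) for dr in range(-u, u + 1) for dc in range(-u, u + 1)]


def window_counts(grid, pos, kind, size, n_types):
    L = grid.shape[0]
    x = [0] * (n_types + 1)
    for dr, dc in offsets(kind, size):
        x[grid[(pos[0] + dr) % L, (pos[1] + dc) % L]] += 1
    return x


def metabolic_M(counts, metabolic_ids, mode="geometric_mean"):
    prod = 1.0
    for i in metabolic_ids:
        if counts[i] == 0:
            return 0.0
        prod *= counts[i]
    if mode == "product":
        return prod
    return prod ** (1.0 / len(metabolic_ids))


def empty_site_distribution(grid, pos, params):
    """Probability vector over next states {0, 1, ..., n} of the empty site
    at ``pos``: claims C_f = k_f * M_f for every replicator in the
    replication window (focal empty centre contributes nothing), normalised
    against C_e."""
    n = params.n_types
    L = grid.shape[0]
    k = {t.type_id: t.k for t in params.types}
    met = [t.type_id for t in params.types if t.is_metabolic]
    r = params.r_spec
    h = params.h_spec
    claims = []  # (type_id, C)
    for dr, dc in offsets(r.kind, r.size):
        ci, cj = (pos[0] + dr) % L, (pos[1] + dc) % L
        t = int(grid[ci, cj])
        if t == 0:
            continue
        if h.is_mean_field:
            counts = [int(np.sum(grid == s)) for s in range(n + 1)]
        else:
            counts = window_counts(grid, (ci, cj), h.kind, h.size, n)
        M = metabolic_M(counts, met, params.metabolic_function)
        claims.append((t, k[t] * M))
    total = params.C_e + sum(c for _, c in claims)
    probs = np.zeros(n + 1)
    if total <= 0:
        probs[0] = 1.0
        return probs
    probs[0] = params.C_e / total
    for t, c in claims:
        probs[t] += c / total
    return probs
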
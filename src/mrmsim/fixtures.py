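"""Small deterministic lattices for oracle tests and demonstrations.

All fixtures are 8x8 tori in a four-type context and are generated
programmatically; :func:`fixture_params` returns the matching parameters.
"""

from __future__ import annotations

import numpy as np

from .core import (
    LatticeState,
    Neighborhood,
    ReplicatorType,
    SimulationParams,
    default_types,
    rng_state_from_seed,
)

__all__ = ["make_fixture", "fixture_params", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("complete_vn", "incomplete", "uniform_t1", "parasite_pocket")

_L = 8


def make_fixture(name: str, seed: int = 0) -> LatticeState:
    """Return a named deterministic 8x8 lattice.

    complete_vn
        One empty focal site at (4, 4); the interleaved type pattern
        ((i + 2j) mod 4) + 1 puts all four types in every 3x3 window, so
        every von Neumann claimant of the focal site has a metabolically
        complete 3x3 metabolic neighbourhood.
    incomplete
        Types 1-3 only (type 4 absent everywhere, plus a few empties): in a
        four-type community every claim is zero.
    uniform_t1
        Every site type 1.
    parasite_pocket
        A 2x2 cluster of the parasite (type 4) inside a dense patch of the
        three metabolic types.
    """
    if name == "uniform_t1":
        grid = np.ones((_L, _L), dtype=np.int8)
    elif name == "complete_vn":
        i, j = np.meshgrid(np.arange(_L), np.arange(_L), indexing="ij")
        grid = (((i + 2 * j) % 4) + 1).astype(np.int8)
        grid[4, 4] = 0
    elif name in ("incomplete", "parasite_pocket"):
        i, j = np.meshgrid(np.arange(_L), np.arange(_L), indexing="ij")
        grid = (((i + 2 * j) % 3) + 1).astype(np.int8)
        if name == "incomplete":
            for pos in ((0, 0), (2, 5), (6, 3)):
                grid[pos] = 0
        else:
            grid[3:5, 3:5] = 4
    else:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    return LatticeState(grid, rng_state_from_seed(seed))


def fixture_params(name: str, **overrides) -> SimulationParams:
    """Parameters matching a fixture: 8x8 lattice, n = 4 community with
    k = 3, 5, 7, 9 (type 4 parasitic for parasite_pocket), von Neumann
    replication and 3x3 Moore metabolic neighbourhoods."""
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    types = default_types(4)
    if name == "parasite_pocket":
        types = default_types(3, parasite_ks=[9.0])
    kwargs = dict(
        L=_L,
        types=types,
        r_spec=Neighborhood("von_neumann"),
        h_spec=Neighborhood("moore", 3),
        t_max=10,
    )
    kwargs.update(overrides)
    return SimulationParams(**kwargs)
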
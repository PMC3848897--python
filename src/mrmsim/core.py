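"""Domain types and lattice geometry for the Metabolic Replicator Model (MRM).

The MRM represents a mineral surface as an L x L toroidal lattice of sites,
each empty or occupied by a single macromolecular replicator. Replicators
carry a type-specific replication rate ``k`` and a role: *metabolic* types
jointly catalyse a monomer-producing metabolism, *parasites* consume the
monomers without contributing. Two site windows govern the dynamics: the
*metabolic neighbourhood* ``h`` (the range over which metabolites diffuse, so
all metabolic types must be present within it for local monomer supply) and
the *replication neighbourhood* ``r`` (the range from which replicators
compete to copy themselves into an empty site).
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ReplicatorType",
    "Neighborhood",
    "MEAN_FIELD",
    "SimulationParams",
    "LatticeState",
    "Census",
    "RunResult",
    "ConfigurationError",
    "neighborhood_offsets",
    "local_type_counts",
    "init_grid",
    "default_types",
    "stable_seed",
]


class ConfigurationError(ValueError):
    """Raised for invalid model configuration (bad neighborhood, rates, ...)."""


# ---------------------------------------------------------------------------
# Replicator types


@dataclass(frozen=True)
class ReplicatorType:
    """One replicator species.

    Parameters
    ----------
    type_id : int
        Positive site-state index (1..n); 0 is reserved for the empty state.
    k : float
        Type-specific replication rate (dimensionless, > 0).
    is_metabolic : bool
        True for metabolic cooperators (enter the metabolic function M),
        False for parasites (consume monomers, never enter M).
    """

    type_id: int
    k: float
    is_metabolic: bool = True

    def __post_init__(self) -> None:
        if self.type_id < 1:
            raise ConfigurationError(f"type_id must be >= 1, got {self.type_id}")
        if not self.k > 0:
            raise ConfigurationError(f"replication rate k must be > 0, got {self.k}")


def default_types(
    n_metabolic: int, parasite_ks: Sequence[float] = ()
) -> tuple[ReplicatorType, ...]:
    """Build the standard community: metabolic rates k_i = 3 + 2*i, i = 0..n-1,
    optionally followed by parasites with the given rates."""
    if n_metabolic < 1:
        raise ConfigurationError("need at least one metabolic type")
    mets = [ReplicatorType(i + 1, 3.0 + 2.0 * i, True) for i in range(n_metabolic)]
    pars = [
        ReplicatorType(n_metabolic + 1 + j, float(kp), False)
        for j, kp in enumerate(parasite_ks)
    ]
    return tuple(mets + pars)


# ---------------------------------------------------------------------------
# Neighborhoods


@dataclass(frozen=True)
class Neighborhood:
    """A named site-offset template on the torus.

    ``kind`` is one of ``"von_neumann"``, ``"moore"`` or ``"mean_field"``.
    For Moore windows ``size`` is the odd side length (3, 5, 7, 25, 37, ...).
    ``mean_field`` is the whole-lattice sentinel (h = L limit).
    """

    kind: str
    size: int | None = None

    _KINDS = ("von_neumann", "moore", "mean_field")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ConfigurationError(f"unknown neighborhood kind {self.kind!r}")
        if self.kind == "moore":
            if self.size is None or self.size < 1 or self.size % 2 == 0:
                raise ConfigurationError(
                    f"moore neighborhood size must be odd and positive, got {self.size}"
                )
        elif self.size is not None:
            raise ConfigurationError(f"{self.kind} neighborhood takes no size")

    @property
    def is_mean_field(self) -> bool:
        return self.kind == "mean_field"

    @property
    def label(self) -> str:
        """Axis label as used in the sweep figures: N, 3, 5, ..., MF."""
        if self.kind == "von_neumann":
            return "N"
        if self.kind == "mean_field":
            return "MF"
        return str(self.size)

    @classmethod
    def from_label(cls, label: str | int | "Neighborhood") -> "Neighborhood":
        """Parse the figure-axis labels: "N" (von Neumann), odd integers
        ("3", "5", "37", ...) for Moore windows, "MF" for mean field."""
        if isinstance(label, Neighborhood):
            return label
        s = str(label).strip().upper()
        if s in ("N", "VN", "VON_NEUMANN"):
            return cls("von_neumann")
        if s in ("MF", "MEAN_FIELD", "L"):
            return cls("mean_field")
        try:
            size = int(s)
        except ValueError:
            raise ConfigurationError(f"invalid neighborhood label {label!r}") from None
        return cls("moore", size)

    def offsets(self) -> np.ndarray:
        return neighborhood_offsets(self)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


MEAN_FIELD = Neighborhood("mean_field")


def neighborhood_offsets(spec: Neighborhood) -> np.ndarray:
    """Row-major (dr, dc) offsets of a neighborhood, center (0,0) included.

    von Neumann: the focal cell plus its 4 orthogonal neighbors (5 sites).
    Moore s: the full s x s window (s**2 sites).
    """
    if spec.is_mean_field:
        raise ConfigurationError("mean-field neighborhood has no finite offset set")
    if spec.kind == "von_neumann":
        return np.array([(-1, 0), (0, -1), (0, 0), (0, 1), (1, 0)], dtype=np.int64)
    half = (spec.size - 1) // 2
    rng = np.arange(-half, half + 1, dtype=np.int64)
    dr, dc = np.meshgrid(rng, rng, indexing="ij")
    return np.column_stack([dr.ravel(), dc.ravel()])


# ---------------------------------------------------------------------------
# Simulation parameters


@dataclass(frozen=True)
class SimulationParams:
    """Full parameterization of one MRM run.

    Defaults follow the standard study conditions: 300 x 300 torus, decay
    probability p_d = 0.2, empty-site claim C_e = 2.0, 80% initial occupancy,
    1000 generations, four metabolic types with k = 3, 5, 7, 9.
    """

    L: int = 300
    types: tuple[ReplicatorType, ...] = field(default_factory=lambda: default_types(4))
    p_d: float = 0.2
    C_e: float = 2.0
    D: float = 0.0
    r_spec: Neighborhood = Neighborhood("moore", 3)
    h_spec: Neighborhood = Neighborhood("moore", 3)
    init_occupancy: float = 0.8
    t_max: int = 1000
    seed: int = 0
    schedule: str = "interleaved"  # or "diffusion_after"
    metabolic_function: str = "geometric_mean"  # or "product"
    update_sampling: str = "with_replacement"  # or "permutation"
    early_stop: bool = True

    def __post_init__(self) -> None:
        if self.L < 4 or self.L % 2 != 0:
            raise ConfigurationError(f"L must be even and >= 4, got {self.L}")
        if not 0.0 <= self.p_d <= 1.0:
            raise ConfigurationError(f"p_d must lie in [0,1], got {self.p_d}")
        if self.C_e < 0:
            raise ConfigurationError(f"C_e must be >= 0, got {self.C_e}")
        if self.D < 0:
            raise ConfigurationError(f"D must be >= 0, got {self.D}")
        if not 0.0 <= self.init_occupancy <= 1.0:
            raise ConfigurationError(
                f"init_occupancy must lie in [0,1], got {self.init_occupancy}"
            )
        if self.t_max < 0:
            raise ConfigurationError(f"t_max must be >= 0, got {self.t_max}")
        if self.schedule not in ("interleaved", "diffusion_after"):
            raise ConfigurationError(f"unknown schedule {self.schedule!r}")
        if self.metabolic_function not in ("geometric_mean", "product"):
            raise ConfigurationError(
                f"unknown metabolic_function {self.metabolic_function!r}"
            )
        if self.update_sampling not in ("with_replacement", "permutation"):
            raise ConfigurationError(
                f"unknown update_sampling {self.update_sampling!r}"
            )
        if not self.types:
            raise ConfigurationError("at least one replicator type is required")
        ids = [t.type_id for t in self.types]
        if ids != list(range(1, len(ids) + 1)):
            raise ConfigurationError(
                f"type_ids must be contiguous from 1, got {ids}"
            )
        if not any(t.is_metabolic for t in self.types):
            raise ConfigurationError("at least one metabolic type is required")
        if self.r_spec.is_mean_field:
            raise ConfigurationError("replication neighborhood cannot be mean-field")
        for spec in (self.r_spec, self.h_spec):
            if spec.kind == "moore" and spec.size > self.L:
                raise ConfigurationError(
                    f"moore neighborhood {spec.size} exceeds lattice size {self.L}"
                )

    # convenience views -----------------------------------------------------

    @property
    def n_types(self) -> int:
        return len(self.types)

    @property
    def metabolic_ids(self) -> tuple[int, ...]:
        return tuple(t.type_id for t in self.types if t.is_metabolic)

    @property
    def parasite_ids(self) -> tuple[int, ...]:
        return tuple(t.type_id for t in self.types if not t.is_metabolic)

    @property
    def k_by_type(self) -> np.ndarray:
        """k indexed by site state; entry 0 (empty) is 0."""
        k = np.zeros(self.n_types + 1, dtype=np.float64)
        for t in self.types:
            k[t.type_id] = t.k
        return k

    def replace(self, **kwargs) -> "SimulationParams":
        return dataclasses.replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Lattice state and RNG

_SPLITMIX_GAMMA = np.uint64(0x9E3779B97F4A7C15)


def _splitmix64(x: np.uint64) -> np.uint64:
    with np.errstate(over="ignore"):
        z = np.uint64(x) + _SPLITMIX_GAMMA
        z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        return z ^ (z >> np.uint64(31))


def rng_state_from_seed(seed: int) -> np.ndarray:
    """PCG32 state (state word, odd increment) derived from an integer seed."""
    s1 = _splitmix64(np.uint64(seed & 0xFFFFFFFFFFFFFFFF))
    s2 = _splitmix64(s1)
    with np.errstate(over="ignore"):
        inc = (np.uint64(s2) << np.uint64(1)) | np.uint64(1)
        state = np.uint64(0)
        state = state * np.uint64(6364136223846793005) + inc
        state = state + np.uint64(s1)
        state = state * np.uint64(6364136223846793005) + inc
    return np.array([state, inc], dtype=np.uint64)


@dataclass
class LatticeState:
    """L x L toroidal grid (0 = empty, i >= 1 = type i) plus the PCG32 RNG
    state that drives every stochastic choice of the run."""

    grid: np.ndarray
    rng_state: np.ndarray

    @property
    def L(self) -> int:
        return self.grid.shape[0]

    def copy(self) -> "LatticeState":
        return LatticeState(self.grid.copy(), self.rng_state.copy())

    def type_counts(self, n_types: int) -> np.ndarray:
        """Per-type site counts (index 0 = empty count)."""
        return np.bincount(self.grid.ravel(), minlength=n_types + 1)


# ---------------------------------------------------------------------------
# Census and run results


@dataclass(frozen=True)
class Census:
    """Per-generation abundance snapshot: counts[i] is the number of sites
    occupied by type i+1; empties + sum(counts) = L**2."""

    t: int
    counts: np.ndarray
    empties: int

    def total(self) -> int:
        return int(self.empties + self.counts.sum())


@dataclass
class RunResult:
    """Outcome of one simulation.

    outcome is "coexistent" iff every metabolic type has count >= 1 at t_max,
    "collapsed" if no replicator (or no metabolic type, extrapolated) remains,
    "partial" if some but not all metabolic types survive.
    """

    outcome: str
    census_series: list[Census]
    final_density: float
    per_type_final: np.ndarray
    parasite_extinct_flags: dict[int, bool]
    params: SimulationParams
    stopped_at: int | None = None
    snapshots: dict[int, np.ndarray] = field(default_factory=dict)
    n_site_updates: int = 0
    n_rotations: int = 0

    @property
    def coexistent(self) -> bool:
        return self.outcome == "coexistent"


# ---------------------------------------------------------------------------
# Operations


def local_type_counts(
    state: LatticeState | np.ndarray,
    pos: tuple[int, int],
    spec: Neighborhood,
    n_types: int | None = None,
) -> np.ndarray:
    """Count replicators of each type within a neighborhood of ``pos``.

    Returns x with x[i] = number of sites in state i (including i = 0, the
    empty count) among the neighborhood offsets applied at pos with toroidal
    wrap; the focal site itself is included. With the mean-field sentinel the
    counts cover the whole grid.
    """
    grid = state.grid if isinstance(state, LatticeState) else state
    if n_types is None:
        n_types = int(grid.max())
    if spec.is_mean_field:
        return np.bincount(grid.ravel(), minlength=n_types + 1)
    L = grid.shape[0]
    off = neighborhood_offsets(spec)
    rows = (pos[0] + off[:, 0]) % L
    cols = (pos[1] + off[:, 1]) % L
    return np.bincount(grid[rows, cols], minlength=n_types + 1)


def init_grid(params: SimulationParams) -> LatticeState:
    """Random initial community: exactly round(init_occupancy * L**2) sites
    occupied (uniform positions without replacement), each occupied site given
    a uniformly random type. Deterministic given params.seed."""
    L = params.L
    n_occ = int(round(params.init_occupancy * L * L))
    rng = np.random.Generator(np.random.PCG64(np.uint64(params.seed)))
    grid = np.zeros(L * L, dtype=np.int8)
    positions = rng.choice(L * L, size=n_occ, replace=False)
    grid[positions] = rng.integers(1, params.n_types + 1, size=n_occ, dtype=np.int8)
    # the update engine draws from a separate stream, decorrelated from init
    return LatticeState(grid.reshape(L, L), rng_state_from_seed(params.seed))


def stable_seed(base_seed: int, *parts) -> int:
    """Deterministic 31-bit seed derived from a base seed and arbitrary
    labels; stable across processes (unlike hash())."""
    h = hashlib.sha256(repr((int(base_seed),) + tuple(map(str, parts))).encode())
    return int.from_bytes(h.digest()[:4], "big") & 0x7FFFFFFF
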
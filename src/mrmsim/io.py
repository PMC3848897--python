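"""Persistence: census CSV round-trip and lattice snapshot images."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .core import Census, LatticeState

__all__ = [
    "write_census",
    "read_census",
    "write_snapshot",
    "DEFAULT_PALETTE",
]

#: white = empty, then the standard snapshot colours for types 1..4
#: (green, blue, red, yellow), extended with distinct hues for larger
#: communities.
DEFAULT_PALETTE: tuple[tuple[int, int, int], ...] = (
    (255, 255, 255),  # empty
    (0, 170, 0),      # type 1
    (0, 80, 255),     # type 2
    (220, 0, 0),      # type 3
    (240, 210, 0),    # type 4
    (160, 0, 200),
    (0, 200, 200),
    (255, 130, 0),
    (120, 70, 20),
    (255, 105, 180),
    (90, 90, 90),
    (0, 90, 60),
    (180, 180, 60),
    (100, 140, 255),
    (200, 120, 120),
    (60, 60, 160),
)


def write_census(series: list[Census], path: str | Path) -> Path:
    """Write a census series as CSV: t, empties, count_1, count_2, ...

    Round-trips losslessly via :func:`read_census`.
    """
    if not series:
        raise ValueError("census series is empty")
    n_types = len(series[0].counts)
    rows = []
    for c in series:
        row = {"t": c.t, "empties": c.empties}
        for i in range(n_types):
            row[f"count_{i + 1}"] = int(c.counts[i])
        rows.append(row)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_census(path: str | Path) -> list[Census]:
    """Read a census CSV written by :func:`write_census`."""
    df = pd.read_csv(path)
    count_cols = sorted(
        (c for c in df.columns if c.startswith("count_")),
        key=lambda c: int(c.split("_")[1]),
    )
    return [
        Census(
            t=int(row["t"]),
            counts=np.array([int(row[c]) for c in count_cols], dtype=np.int64),
            empties=int(row["empties"]),
        )
        for _, row in df.iterrows()
    ]


def write_snapshot(
    state: LatticeState | np.ndarray,
    path: str | Path,
    palette: tuple[tuple[int, int, int], ...] = DEFAULT_PALETTE,
) -> Path:
    """Write the lattice as an indexed PNG (PGM fallback via the .pgm
    suffix), one pixel per site, using the standard palette (white empty,
    green/blue/red/yellow for types 1-4). Byte-stable for a given grid."""
    grid = state.grid if isinstance(state, LatticeState) else state
    n_states = int(grid.max()) + 1
    if n_states > len(palette):
        raise ValueError(
            f"grid has {n_states} states but palette only {len(palette)} "
            "entries; pass an extended palette"
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".pgm":
        # plain greymap: empty -> 255, types spread down from 0
        levels = np.linspace(0, 200, max(n_states - 1, 1), dtype=np.uint8)
        img = np.full(grid.shape, 255, dtype=np.uint8)
        for t in range(1, n_states):
            img[grid == t] = levels[t - 1]
        with open(path, "wb") as fh:
            fh.write(f"P5\n{grid.shape[1]} {grid.shape[0]}\n255\n".encode())
            fh.write(img.tobytes())
        return path
    im = Image.fromarray(grid.astype(np.uint8), mode="P")
    flat = [c for rgb in palette for c in rgb]
    im.putpalette(flat + [0] * (768 - len(flat)))
    im.save(path, format="PNG")
    return path
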
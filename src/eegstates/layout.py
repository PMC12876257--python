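"""Spatial sensor layout: mapping dense-array EEG channels onto a scalp grid.

A 128-channel sensor net is represented on a 12 x 12 matrix whose rows run
from the front of the head (row 1) to the back (row 12), with columns 1-6
covering the left hemisphere and 7-12 the right.  Two cells, (1, 3) and
(1, 10), are deliberately left empty as a prefrontal reference marker, so
142 cells carry a channel.  Because 142 > 128, fourteen electrodes are
"doubled": they occupy two grid cells each so the matrix fills symmetrically.

The exact channel-to-cell assignment is data, not code: it ships as a
delimited table (``data/default_layout_12x12.csv``) that users can replace
with their own montage.  All indices are 1-based.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "REGIONS",
    "LayoutError",
    "SensorLayout",
    "load_layout",
    "save_layout",
    "default_layout",
    "grid_layout",
    "map_to_grid",
]

#: Recognized scalp-region labels.
REGIONS = (
    "prefrontal",
    "frontal",
    "central",
    "temporal-L",
    "temporal-R",
    "parietal",
    "occipital",
    "other",
)

_DEFAULT_EMPTY = frozenset({(1, 3), (1, 10)})


class LayoutError(ValueError):
    """Raised when a sensor layout violates its structural invariants."""


@dataclass(frozen=True)
class SensorLayout:
    """A validated channel -> grid-cell assignment.

    Parameters
    ----------
    entries
        Sequence of ``(channel_id, row, col, region)`` tuples, 1-based.
    grid_shape
        ``(n_rows, n_cols)`` of the scalp matrix.
    empty_cells
        Cells that must stay unassigned (reference positions).
    """

    entries: tuple[tuple[int, int, int, str], ...]
    grid_shape: tuple[int, int] = (12, 12)
    empty_cells: frozenset[tuple[int, int]] = _DEFAULT_EMPTY

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(tuple(e) for e in self.entries))
        object.__setattr__(self, "empty_cells", frozenset(self.empty_cells))
        self._validate()

    # -- derived views ----------------------------------------------------

    @property
    def channels(self) -> tuple[int, ...]:
        """Sorted unique channel ids."""
        return tuple(sorted({e[0] for e in self.entries}))

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def doubled_channels(self) -> tuple[int, ...]:
        """Channels assigned to more than one cell."""
        counts = Counter(e[0] for e in self.entries)
        return tuple(sorted(c for c, n in counts.items() if n > 1))

    @property
    def filled_cells(self) -> frozenset[tuple[int, int]]:
        return frozenset((e[1], e[2]) for e in self.entries)

    def cells_of(self, channel_id: int) -> list[tuple[int, int]]:
        return [(r, c) for ch, r, c, _ in self.entries if ch == channel_id]

    def region_of(self, channel_id: int) -> str:
        for ch, _, _, region in self.entries:
            if ch == channel_id:
                return region
        raise LayoutError(f"channel {channel_id} not in layout")

    def channels_in_region(self, region: str) -> tuple[int, ...]:
        return tuple(sorted({ch for ch, _, _, reg in self.entries if reg == region}))

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        nrow, ncol = self.grid_shape
        seen_cells: dict[tuple[int, int], int] = {}
        for ch, row, col, region in self.entries:
            if not (1 <= row <= nrow and 1 <= col <= ncol):
                raise LayoutError(
                    f"channel {ch}: cell ({row},{col}) outside {nrow}x{ncol} grid"
                )
            if (row, col) in self.empty_cells:
                raise LayoutError(
                    f"channel {ch} assigned to reserved empty cell ({row},{col})"
                )
            if region not in REGIONS:
                raise LayoutError(f"channel {ch}: unknown region {region!r}")
            if (row, col) in seen_cells:
                raise LayoutError(
                    f"cell ({row},{col}) assigned to both channel "
                    f"{seen_cells[(row, col)]} and channel {ch}"
                )
            seen_cells[(row, col)] = ch

        n_cells = nrow * ncol - len(self.empty_cells)
        if len(self.entries) != n_cells:
            missing = {
                (r, c)
                for r in range(1, nrow + 1)
                for c in range(1, ncol + 1)
                if (r, c) not in self.empty_cells and (r, c) not in seen_cells
            }
            raise LayoutError(
                f"{len(self.entries)} entries cover only part of the grid; "
                f"uncovered cells: {sorted(missing)[:5]}..."
                if missing
                else f"expected {n_cells} entries, got {len(self.entries)}"
            )

        expected = set(range(1, self.n_channels + 1))
        got = set(self.channels)
        if got != expected:
            unassigned = sorted(expected - got)
            if unassigned:
                raise LayoutError(f"channel {unassigned[0]} unassigned")
            raise LayoutError(f"non-contiguous channel ids: {sorted(got - expected)[:5]}")

        over = [c for c, n in Counter(e[0] for e in self.entries).items() if n > 2]
        if over:
            raise LayoutError(
                f"channels assigned to more than two cells (beyond doubling): {sorted(over)}"
            )


def _entries_from_rows(rows: Iterable[Mapping[str, str]], source: str) -> list:
    entries = []
    for i, row in enumerate(rows, start=2):  # header is line 1
        try:
            entries.append(
                (
                    int(row["channel_id"]),
                    int(row["row"]),
                    int(row["col"]),
                    str(row["region"]).strip(),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise LayoutError(f"{source}: malformed layout row at line {i}: {exc}") from exc
    return entries


def load_layout(source: str | Path) -> SensorLayout:
    """Read a layout table (CSV with columns channel_id,row,col,region).

    Lines beginning with ``#`` are comments.  Raises :class:`LayoutError`
    naming the offending row on any invariant violation.
    """
    path = Path(source)
    with path.open(newline="") as fh:
        reader = csv.DictReader(line for line in fh if not line.startswith("#"))
        entries = _entries_from_rows(reader, str(path))
    return SensorLayout(entries=tuple(entries))


def save_layout(layout: SensorLayout, path: str | Path) -> None:
    """Write a layout back to its delimited form (1-based indices)."""
    with Path(path).open("w", newline="") as fh:
        fh.write("# sensor layout: 1-based indices, row 1 = front of head\n")
        writer = csv.writer(fh)
        writer.writerow(["channel_id", "row", "col", "region"])
        for ch, row, col, region in sorted(layout.entries, key=lambda e: (e[1], e[2])):
            writer.writerow([ch, row, col, region])


def default_layout() -> SensorLayout:
    """The bundled 128-channel / 12 x 12 montage.

    The assignment respects left/right mirror symmetry of regions and fills
    the back rows by doubling 14 electrodes (each doubled electrode sits in
    two vertically adjacent cells).  The montage is a documented convention,
    not a vendor net description: users with a real digitized montage should
    supply their own table.
    """
    ref = resources.files("eegstates.data").joinpath("default_layout_12x12.csv")
    with resources.as_file(ref) as path:
        return load_layout(path)


def grid_layout(n_rows: int, n_cols: int, region: str = "other") -> SensorLayout:
    """A dense auxiliary layout with one channel per cell and no empty cells.

    Useful for simulations where spatial structure is irrelevant and a full
    128-channel montage would only cost time.
    """
    entries = []
    ch = 1
    for r in range(1, n_rows + 1):
        for c in range(1, n_cols + 1):
            entries.append((ch, r, c, region))
            ch += 1
    return SensorLayout(entries=tuple(entries), grid_shape=(n_rows, n_cols),
                        empty_cells=frozenset())


def map_to_grid(values: Mapping[int, float], layout: SensorLayout) -> np.ndarray:
    """Scatter per-channel values onto the scalp grid.

    Doubled channels write the same value into both of their cells.  Empty
    reference cells carry ``NaN`` as the sentinel.  Raises
    :class:`LayoutError` listing any channel without a value.
    """
    missing = [ch for ch in layout.channels if ch not in values]
    if missing:
        raise LayoutError(f"missing values for channels: {missing}")
    grid = np.full(layout.grid_shape, np.nan)
    for ch, row, col, _ in layout.entries:
        grid[row - 1, col - 1] = values[ch]
    return grid
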
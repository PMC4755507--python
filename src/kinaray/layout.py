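"""Spotted-array grid geometry and GAL-style layout files.

An :class:`ArrayLayout` describes where every peptide substrate sits on a
slide.  A slide carries one sub-grid ("block") per technical replicate,
stacked vertically; within a block spots lie on a regular square grid.
Positions map to substrate identifiers; a designated subset of identifiers
are control peptides used for between-slide validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

#: vertical gap between replicate blocks, in multiples of the spot pitch
BLOCK_GAP_PITCHES = 2


@dataclass(frozen=True)
class ArrayLayout:
    """Grid geometry and position -> substrate mapping for one slide.

    Parameters
    ----------
    n_block_rows, n_block_cols
        Grid dimensions of a single replicate block.
    n_blocks
        Number of replicate blocks stacked on the slide.
    pitch_px
        Center-to-center spot spacing in pixels.
    spot_radius_px
        Nominal spot radius in pixels (quantification disk radius).
    positions
        Ordered list of ``(block, row, col, substrate_id)`` tuples,
        1-based block index, 0-based row/col.
    control_ids
        Substrate identifiers designated as control spots.
    margin_px
        Distance from the image edge to the first spot center.
    """

    n_block_rows: int
    n_block_cols: int
    n_blocks: int
    pitch_px: int
    spot_radius_px: int
    positions: tuple = ()
    control_ids: frozenset = field(default_factory=frozenset)
    margin_px: int = 0

    def __post_init__(self):
        if self.margin_px == 0:
            # default margin leaves room for annuli and alignment search
            object.__setattr__(self, "margin_px", 2 * self.pitch_px)
        seen = set()
        ids = set()
        for blk, row, col, sid in self.positions:
            key = (blk, row, col)
            if key in seen:
                raise ValueError(f"duplicate layout position {key}")
            seen.add(key)
            ids.add(sid)
        missing_controls = set(self.control_ids) - ids
        if missing_controls:
            raise ValueError(
                f"control ids not present in layout: {sorted(missing_controls)}"
            )

    @property
    def n_spots(self) -> int:
        return len(self.positions)

    @property
    def substrate_ids(self):
        """Unique substrate ids in first-appearance order (block 1 order)."""
        out, seen = [], set()
        for _, _, _, sid in self.positions:
            if sid not in seen:
                seen.add(sid)
                out.append(sid)
        return out

    def block_origin_y(self, block: int) -> int:
        """y pixel of row 0 of a (1-based) block."""
        block_height = (self.n_block_rows - 1 + BLOCK_GAP_PITCHES) * self.pitch_px
        return self.margin_px + (block - 1) * (block_height + self.pitch_px)

    def spot_center(self, block: int, row: int, col: int, offset=(0, 0)):
        """(x, y) pixel center of a spot, with optional global (dx, dy)."""
        x = self.margin_px + col * self.pitch_px + offset[0]
        y = self.block_origin_y(block) + row * self.pitch_px + offset[1]
        return (x, y)

    def image_shape(self):
        """(height, width) of an image that fits the full layout + margins."""
        width = 2 * self.margin_px + (self.n_block_cols - 1) * self.pitch_px
        last = self.block_origin_y(self.n_blocks) + (self.n_block_rows - 1) * self.pitch_px
        return (last + self.margin_px, width + 1)

    def iter_centers(self, offset=(0, 0)):
        """Yield (substrate_id, block, (x, y)) for every position."""
        for blk, row, col, sid in self.positions:
            yield sid, blk, self.spot_center(blk, row, col, offset)


def make_layout(
    n_substrates: int,
    n_controls: int = 8,
    n_blocks: int = 3,
    pitch_px: int = 32,
    spot_radius_px: int = 8,
) -> ArrayLayout:
    """Build a layout placing ``n_substrates`` peptides plus controls in each
    replicate block.

    Substrates are named ``SUB0001 ...``; controls ``CTRL01 ...`` and are
    interleaved at evenly spaced grid positions so every block carries the
    full set.
    """
    if n_substrates < 1:
        raise ValueError("n_substrates must be >= 1")
    total = n_substrates + n_controls
    n_cols = int(math.ceil(math.sqrt(total)))
    n_rows = int(math.ceil(total / n_cols))

    ids = [f"SUB{i + 1:04d}" for i in range(n_substrates)]
    controls = [f"CTRL{i + 1:02d}" for i in range(n_controls)]
    # spread controls through the grid at a fixed stride
    ordered = list(ids)
    if n_controls:
        stride = max(1, total // n_controls)
        for i, cid in enumerate(controls):
            ordered.insert(min(i * stride, len(ordered)), cid)

    positions = []
    for blk in range(1, n_blocks + 1):
        for idx, sid in enumerate(ordered):
            positions.append((blk, idx // n_cols, idx % n_cols, sid))
    return ArrayLayout(
        n_block_rows=n_rows,
        n_block_cols=n_cols,
        n_blocks=n_blocks,
        pitch_px=pitch_px,
        spot_radius_px=spot_radius_px,
        positions=tuple(positions),
        control_ids=frozenset(controls),
    )


def write_gal(layout: ArrayLayout, path) -> None:
    """Write the layout as a GAL-style tab-delimited file.

    Header records carry the grid geometry; the table has Block / Row /
    Column / ID / Name columns (1-based rows and columns, GenePix
    convention).  Control spots get Name ``control``.
    """
    path = Path(path)
    lines = [
        "ATF\t1.0",
        "6\t5",
        '"Type=GenePix ArrayList V1.0"',
        f'"BlockCount={layout.n_blocks}"',
        f'"BlockRows={layout.n_block_rows}"',
        f'"BlockColumns={layout.n_block_cols}"',
        f'"PitchPx={layout.pitch_px}"',
        f'"SpotRadiusPx={layout.spot_radius_px}"',
        "Block\tRow\tColumn\tID\tName",
    ]
    for blk, row, col, sid in layout.positions:
        name = "control" if sid in layout.control_ids else sid
        lines.append(f"{blk}\t{row + 1}\t{col + 1}\t{sid}\t{name}")
    path.write_text("\n".join(lines) + "\n")


def read_gal(path) -> ArrayLayout:
    """Read a GAL-style file written by :func:`write_gal`."""
    path = Path(path)
    header = {}
    rows = []
    in_table = False
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        if line.startswith("Block\t"):
            in_table = True
            continue
        if in_table:
            blk, row, col, sid, name = line.split("\t")
            rows.append((int(blk), int(row) - 1, int(col) - 1, sid, name))
        elif "=" in line:
            key, _, val = line.strip('"').partition("=")
            header[key] = val.rstrip('"')
    controls = frozenset(sid for *_, sid, name in rows if name == "control")
    return ArrayLayout(
        n_block_rows=int(header["BlockRows"]),
        n_block_cols=int(header["BlockColumns"]),
        n_blocks=int(header["BlockCount"]),
        pitch_px=int(header["PitchPx"]),
        spot_radius_px=int(header["SpotRadiusPx"]),
        positions=tuple((b, r, c, s) for b, r, c, s, _ in rows),
        control_ids=controls,
    )


def layout_table(layout: ArrayLayout) -> pd.DataFrame:
    """Layout positions as a DataFrame (block, row, col, substrate_id)."""
    return pd.DataFrame(
        layout.positions, columns=["block", "row", "col", "substrate_id"]
    )
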
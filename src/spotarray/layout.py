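"""Spotted-array geometry: replicated probe spots on a printed grid.

The layout assigns every probe ``replicates_per_probe`` spots, filled
row-major into a rectangular grid with a fixed center-to-center pitch, and
serializes to a GAL-like TSV (Block/Row/Column/ID/Name plus physical
coordinates) so external gridding tools can consume it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .probes import ProbeSet

__all__ = ["Spot", "ArrayLayout", "build_layout", "write_layout", "read_layout"]


@dataclass(frozen=True)
class Spot:
    spot_id: str
    probe_id: str
    row: int            # 0-based grid row
    col: int            # 0-based grid column
    x_um: float         # spot-center physical coordinates
    y_um: float
    diameter_um: float


@dataclass
class ArrayLayout:
    spots: list[Spot]
    replicates_per_probe: int
    pitch_um: float
    margin_um: float

    def __post_init__(self) -> None:
        coords = {(s.x_um, s.y_um) for s in self.spots}
        if len(coords) != len(self.spots):
            raise ValueError("spot coordinates are not distinct")

    @property
    def n_rows(self) -> int:
        return max(s.row for s in self.spots) + 1

    @property
    def n_cols(self) -> int:
        return max(s.col for s in self.spots) + 1

    def probe_ids(self) -> list[str]:
        seen: list[str] = []
        for s in self.spots:
            if s.probe_id not in seen:
                seen.append(s.probe_id)
        return seen

    def spots_of(self, probe_id: str) -> list[Spot]:
        return [s for s in self.spots if s.probe_id == probe_id]

    def extent_um(self) -> tuple[float, float]:
        """(width, height) of the printed area including margins."""
        return (
            2 * self.margin_um + self.n_cols * self.pitch_um,
            2 * self.margin_um + self.n_rows * self.pitch_um,
        )


def build_layout(
    probe_set: ProbeSet | list[str],
    replicates: int = 8,
    grid_cols: int = 24,
    grid_rows: int | None = None,
    pitch_um: float = 800.0,
    diameter_um: float = 300.0,
    margin_um: float | None = None,
    shuffle_seed: int | None = None,
) -> ArrayLayout:
    """Lay out ``replicates`` spots per probe, row-major, replicate blocks
    contiguous.

    ``grid_rows`` caps the grid height (error when too small); by default the
    grid grows to fit. ``shuffle_seed`` scatters spot order reproducibly for
    robustness testing instead of printing contiguous replicate blocks.
    ``margin_um`` (default: one pitch) pads the printed area so edge spots
    keep a full background annulus.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if grid_cols < 1:
        raise ValueError("grid_cols must be >= 1")
    probe_ids = (
        [p.probe_id for p in probe_set.probes]
        if isinstance(probe_set, ProbeSet)
        else list(probe_set)
    )
    if not probe_ids:
        raise ValueError("no probes to lay out")
    order = [pid for pid in probe_ids for _ in range(replicates)]
    if shuffle_seed is not None:
        rng = np.random.default_rng(shuffle_seed)
        order = [order[i] for i in rng.permutation(len(order))]
    n_spots = len(order)
    needed_rows = -(-n_spots // grid_cols)
    if grid_rows is not None and grid_rows < needed_rows:
        raise ValueError(
            f"grid {grid_rows}x{grid_cols} too small for {n_spots} spots"
        )
    margin = pitch_um if margin_um is None else margin_um
    counters: dict[str, int] = {}
    spots = []
    for idx, pid in enumerate(order):
        row, col = divmod(idx, grid_cols)
        counters[pid] = counters.get(pid, 0) + 1
        spots.append(
            Spot(
                spot_id=f"{pid}.r{counters[pid]}",
                probe_id=pid,
                row=row,
                col=col,
                x_um=margin + (col + 0.5) * pitch_um,
                y_um=margin + (row + 0.5) * pitch_um,
                diameter_um=diameter_um,
            )
        )
    return ArrayLayout(
        spots=spots,
        replicates_per_probe=replicates,
        pitch_um=pitch_um,
        margin_um=margin,
    )


_LAYOUT_COLUMNS = [
    "Block", "Row", "Column", "ID", "Name", "X", "Y", "Dia",
]


def write_layout(layout: ArrayLayout, path) -> None:
    """Write a GAL-like TSV; coordinates printed to 0.1 um so files are
    bit-identical across runs."""
    with open(path, "w") as fh:
        fh.write(
            f"#replicates_per_probe={layout.replicates_per_probe}\t"
            f"pitch_um={layout.pitch_um:.1f}\t"
            f"margin_um={layout.margin_um:.1f}\n"
        )
        fh.write("\t".join(_LAYOUT_COLUMNS) + "\n")
        for s in layout.spots:
            fh.write(
                f"1\t{s.row + 1}\t{s.col + 1}\t{s.spot_id}\t{s.probe_id}\t"
                f"{s.x_um:.1f}\t{s.y_um:.1f}\t{s.diameter_um:.1f}\n"
            )


def read_layout(path) -> ArrayLayout:
    """Read a GAL-like TSV written by :func:`write_layout`."""
    spots: list[Spot] = []
    meta = {"replicates_per_probe": 1, "pitch_um": 0.0, "margin_um": 0.0}
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith("#"):
            raise ValueError(f"{path}:1: missing metadata line")
        for item in first.lstrip("#").split("\t"):
            key, _, value = item.partition("=")
            if key in meta:
                meta[key] = type(meta[key])(float(value))
        header = fh.readline().rstrip("\n").split("\t")
        if header != _LAYOUT_COLUMNS:
            raise ValueError(f"{path}:2: unexpected layout header {header}")
        for lineno, line in enumerate(fh, 3):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(_LAYOUT_COLUMNS):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(_LAYOUT_COLUMNS)} "
                    f"columns, got {len(parts)}"
                )
            _block, row, col, sid, pid, x, y, dia = parts
            spots.append(
                Spot(
                    spot_id=sid, probe_id=pid,
                    row=int(row) - 1, col=int(col) - 1,
                    x_um=float(x), y_um=float(y), diameter_um=float(dia),
                )
            )
    if not spots:
        raise ValueError(f"{path}: no spots")
    return ArrayLayout(
        spots=spots,
        replicates_per_probe=int(meta["replicates_per_probe"]),
        pitch_um=meta["pitch_um"],
        margin_um=meta["margin_um"],
    )
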
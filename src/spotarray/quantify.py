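"""Spot quantification: grid registration, disk integration, local background
subtraction, replicate aggregation and percent-of-total normalization.

The quantification model follows standard phosphorimager densitometry: each
spot's raw signal is the pixel sum over a disk at its expected grid position
(after a translation-only integer-pixel registration), the local background
is the median of an annulus around the disk, and the net signal is clamped at
zero because negative radioactivity is unphysical. Replicate spots of one
probe are combined by their median after flagging outliers more than 3 MAD
from it, and the per-probe signals are expressed as percent of the summed
panel signal so arrays of different exposure are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .layout import ArrayLayout

__all__ = [
    "QuantParams",
    "GridFit",
    "SpotMeasurement",
    "TrnaProfile",
    "register_grid",
    "quantify_spot",
    "aggregate_replicates",
    "normalize",
    "quantify_array",
    "write_profile_tsv",
    "read_profile_tsv",
]


@dataclass(frozen=True)
class QuantParams:
    """Quantification parameters.

    pixel_size_um   scanner resolution used to map layout um to pixels
    radius_px       integration-disk radius
    annulus_scale   outer annulus radius as a multiple of the disk radius
    search_px       half-width of the registration search window
    """

    pixel_size_um: float = 50.0
    radius_px: int = 5
    annulus_scale: float = 2.0
    search_px: int = 3

    def __post_init__(self) -> None:
        if self.radius_px < 1:
            raise ValueError("radius_px must be >= 1")
        if self.annulus_scale <= 1:
            raise ValueError("annulus_scale must be > 1")
        if self.search_px < 0:
            raise ValueError("search_px must be >= 0")


@dataclass(frozen=True)
class GridFit:
    offset_x_px: int
    offset_y_px: int
    score: float


@dataclass(frozen=True)
class SpotMeasurement:
    spot_id: str
    raw_sum: float
    background_level: float     # counts per pixel
    net_signal: float           # max(0, raw - background*n_pixels)
    n_pixels: int
    flagged: bool = False


@dataclass
class TrnaProfile:
    """Per-probe percent-of-total tRNA levels for one array."""

    level: dict[str, float]                 # probe_id -> percent of total
    net_signal: dict[str, float] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.level.values())
        if self.level and total > 0 and abs(total - 100.0) > 1e-9:
            raise ValueError("profile levels must sum to 100")

    def as_series(self) -> pd.Series:
        return pd.Series(self.level, name="percent")


def _spot_centers_px(layout: ArrayLayout, pixel_size_um: float):
    """Integer pixel centers per spot (pixel j covers [j*ps, (j+1)*ps) um)."""
    return {
        s.spot_id: (
            int(s.y_um // pixel_size_um),
            int(s.x_um // pixel_size_um),
        )
        for s in layout.spots
    }


def _disk_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    dy, dx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    mask = dy**2 + dx**2 <= radius**2
    return dy[mask], dx[mask]


def register_grid(
    image: np.ndarray, layout: ArrayLayout, params: QuantParams | None = None
) -> GridFit:
    """Integer-pixel translation maximizing total in-disk intensity.

    Ties are broken by smallest |dx|+|dy|, then lexicographic (dx, dy), so a
    featureless image registers at (0, 0).
    """
    params = params or QuantParams()
    centers = _spot_centers_px(layout, params.pixel_size_um)
    dy_off, dx_off = _disk_offsets(params.radius_px)
    ny, nx = image.shape
    best_key: tuple[float, int, int, int] | None = None
    best_fit: GridFit | None = None
    any_inside = False
    for dy in range(-params.search_px, params.search_px + 1):
        for dx in range(-params.search_px, params.search_px + 1):
            total = 0.0
            for cy, cx in centers.values():
                yy = cy + dy + dy_off
                xx = cx + dx + dx_off
                valid = (yy >= 0) & (yy < ny) & (xx >= 0) & (xx < nx)
                if valid.any():
                    any_inside = True
                    total += float(image[yy[valid], xx[valid]].sum())
            key = (-total, abs(dx) + abs(dy), dx, dy)
            if best_key is None or key < best_key:
                best_key = key
                best_fit = GridFit(offset_x_px=dx, offset_y_px=dy, score=total)
    if not any_inside:
        raise ValueError("layout lies entirely outside the image")
    assert best_fit is not None
    return best_fit


def quantify_spot(
    image: np.ndarray,
    center: tuple[int, int],
    radius_px: int,
    annulus: tuple[float, float] | None = None,
    spot_id: str = "",
) -> SpotMeasurement:
    """Integrate one spot: disk sum minus annulus-median background.

    ``center`` is (row, col). ``annulus`` gives (inner, outer) radii; by
    default inner = disk radius, outer = 2x. The disk and annulus must lie
    within the image; the annulus must contain at least one pixel.
    """
    cy, cx = center
    inner, outer = annulus if annulus is not None else (radius_px, 2 * radius_px)
    ny, nx = image.shape
    r_out = int(np.ceil(outer))
    if cy - r_out < 0 or cy + r_out >= ny or cx - r_out < 0 or cx + r_out >= nx:
        raise ValueError(
            f"spot {spot_id or center}: disk/annulus extends outside image"
        )
    dy, dx = np.mgrid[-r_out:r_out + 1, -r_out:r_out + 1]
    dist2 = dy**2 + dx**2
    patch = image[cy - r_out:cy + r_out + 1, cx - r_out:cx + r_out + 1]
    disk = dist2 <= radius_px**2
    ann = (dist2 > inner**2) & (dist2 <= outer**2)
    if not ann.any():
        raise ValueError(f"spot {spot_id or center}: empty background annulus")
    raw = float(patch[disk].sum())
    background = float(np.median(patch[ann]))
    n_pixels = int(disk.sum())
    net = max(0.0, raw - background * n_pixels)
    return SpotMeasurement(
        spot_id=spot_id,
        raw_sum=raw,
        background_level=background,
        net_signal=net,
        n_pixels=n_pixels,
    )


def aggregate_replicates(
    measurements: list[SpotMeasurement],
) -> tuple[float, list[SpotMeasurement]]:
    """Combine replicate spots of one probe.

    Replicates whose net signal deviates from the replicate median by more
    than 3 MAD (median absolute deviation) are flagged; the aggregate is the
    median of the surviving replicates. Raises when every replicate is
    flagged (with zero MAD, only values different from the median flag).
    """
    if not measurements:
        raise ValueError("no replicate measurements")
    nets = np.array([m.net_signal for m in measurements])
    med = float(np.median(nets))
    mad = float(np.median(np.abs(nets - med)))
    flags = np.abs(nets - med) > 3 * mad
    out = [
        SpotMeasurement(
            spot_id=m.spot_id, raw_sum=m.raw_sum,
            background_level=m.background_level, net_signal=m.net_signal,
            n_pixels=m.n_pixels, flagged=bool(f),
        )
        for m, f in zip(measurements, flags)
    ]
    kept = nets[~flags]
    if kept.size == 0:
        raise ValueError("all replicates flagged as outliers")
    return float(np.median(kept)), out


def normalize(
    signals: dict[str, float], metadata: dict | None = None
) -> TrnaProfile:
    """Percent-of-total normalization: level_i = 100 * s_i / sum(s)."""
    if not signals:
        raise ValueError("no probe signals")
    total = sum(signals.values())
    if total <= 0:
        raise ValueError("all probe signals are zero")
    level = {pid: 100.0 * s / total for pid, s in signals.items()}
    return TrnaProfile(
        level=level, net_signal=dict(signals), metadata=metadata or {}
    )


def quantify_array(
    image: np.ndarray,
    layout: ArrayLayout,
    params: QuantParams | None = None,
    metadata: dict | None = None,
) -> TrnaProfile:
    """Full pipeline: register grid, quantify every spot, aggregate
    replicates per probe, normalize to percent of total."""
    params = params or QuantParams()
    fit = register_grid(image, layout, params)
    centers = _spot_centers_px(layout, params.pixel_size_um)
    per_probe: dict[str, list[SpotMeasurement]] = {}
    for spot in layout.spots:
        cy, cx = centers[spot.spot_id]
        m = quantify_spot(
            image,
            (cy + fit.offset_y_px, cx + fit.offset_x_px),
            params.radius_px,
            (params.radius_px, params.annulus_scale * params.radius_px),
            spot_id=spot.spot_id,
        )
        per_probe.setdefault(spot.probe_id, []).append(m)
    aggregated: dict[str, float] = {}
    all_measurements: list[SpotMeasurement] = []
    for pid in layout.probe_ids():
        value, flagged = aggregate_replicates(per_probe[pid])
        aggregated[pid] = value
        all_measurements.extend(flagged)
    meta = dict(metadata or {})
    meta["grid_offset_px"] = (fit.offset_x_px, fit.offset_y_px)
    profile = normalize(aggregated, metadata=meta)
    profile.metadata["spot_measurements"] = all_measurements
    return profile


def write_profile_tsv(profile: TrnaProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("probe_id\tpercent\tnet_signal\n")
        for pid in profile.level:
            net = profile.net_signal.get(pid, float("nan"))
            fh.write(f"{pid}\t{profile.level[pid]:.6f}\t{net:.6f}\n")


def read_profile_tsv(path) -> TrnaProfile:
    level: dict[str, float] = {}
    net: dict[str, float] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["probe_id", "percent"]:
            raise ValueError(f"{path}: unexpected profile header {header}")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: malformed row")
            level[parts[0]] = float(parts[1])
            if len(parts) > 2:
                net[parts[0]] = float(parts[2])
    total = sum(level.values())
    if total > 0:  # re-normalize away rounding from the fixed-precision dump
        level = {k: 100.0 * v / total for k, v in level.items()}
    return TrnaProfile(level=level, net_signal=net)
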
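"""Synthetic phosphorimager arrays from ground-truth tRNA abundances.

Metabolic ³²P labeling makes the radioactivity of each tRNA species
proportional to its abundance (equal lengths, equal phosphate content), so a
hybridized array is modeled as: per-probe expected signal = summed abundance
of its targets; each spot is a symmetric 2-D Gaussian whose integral is
proportional to that signal; the phosphor screen accumulates Poisson counts
on top of a uniform background, scaled by exposure. All randomness is driven
by explicit seeds so images are byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile
import yaml
from scipy.special import ndtr

from .catalog import TrnaCatalog
from .layout import ArrayLayout
from .probes import ProbeSet

__all__ = [
    "GroundTruth",
    "SimParams",
    "sample_profile",
    "expected_probe_signal",
    "render",
    "write_image",
    "read_image",
]


@dataclass(frozen=True)
class GroundTruth:
    """Relative abundance per species; non-negative, sums to 1."""

    abundance: dict[str, float]

    def __post_init__(self) -> None:
        vals = np.array(list(self.abundance.values()), dtype=float)
        if (vals < 0).any():
            raise ValueError("abundances must be >= 0")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")


@dataclass(frozen=True)
class SimParams:
    """Rendering parameters for one exposure.

    pixel_size_um
        Scanner resolution (50 um on a typical phosphorimager).
    psf_sigma_um
        Standard deviation of the Gaussian spot profile.
    background_rate
        Expected background counts per pixel.
    exposure_scale
        Dimensionless gain: expected total counts contributed by a spot of
        unit signal. Longer phosphor-screen exposures scale it linearly.
    seed
        Seed for the Poisson draw; a fixed seed gives an identical image.
    """

    pixel_size_um: float = 50.0
    psf_sigma_um: float = 75.0
    background_rate: float = 2.0
    exposure_scale: float = 50_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pixel_size_um", "psf_sigma_um", "exposure_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")


def sample_profile(
    catalog: TrnaCatalog, lognormal_sigma: float = 1.0, seed: int = 0
) -> GroundTruth:
    """Draw a seeded log-normal abundance profile over the catalog species.

    sigma = 0 gives the uniform profile 1/n. sigma around 1 reproduces the
    order-of-magnitude spread between the most and least abundant species
    seen in real cellular tRNA pools.
    """
    if lognormal_sigma < 0:
        raise ValueError("lognormal_sigma must be >= 0")
    ids = [sp.species_id for sp in catalog.species]
    rng = np.random.default_rng(seed)
    raw = np.exp(rng.normal(0.0, lognormal_sigma, size=len(ids)))
    raw /= raw.sum()
    return GroundTruth(abundance=dict(zip(ids, raw.tolist())))


def expected_probe_signal(
    probe_set: ProbeSet, truth: GroundTruth
) -> dict[str, float]:
    """Expected signal per probe: summed abundance of its target species."""
    signals: dict[str, float] = {}
    for probe in probe_set.probes:
        total = 0.0
        for sid in probe.targets:
            if sid not in truth.abundance:
                raise KeyError(f"species {sid} missing from ground truth")
            total += truth.abundance[sid]
        signals[probe.probe_id] = total
    return signals


def render(
    layout: ArrayLayout,
    probe_signals: dict[str, float],
    params: SimParams | None = None,
    noise: bool = True,
) -> np.ndarray:
    """Render the array image (float64 counts, row-major y/x).

    Per-pixel expectation = background_rate + exposure_scale * sum over
    spots of signal * Gaussian(center, psf) integrated over the pixel (exact
    separable integral via the normal CDF). With ``noise=True`` the realized
    image is a Poisson draw from that expectation using ``params.seed``;
    with ``noise=False`` the expectation itself is returned.
    """
    params = params or SimParams()
    ps = params.pixel_size_um
    width_um, height_um = layout.extent_um()
    nx = int(np.ceil(width_um / ps))
    ny = int(np.ceil(height_um / ps))
    expected = np.full((ny, nx), float(params.background_rate))
    sigma_px = params.psf_sigma_um / ps
    half = int(np.ceil(6 * sigma_px)) + 1

    for spot in layout.spots:
        if spot.probe_id not in probe_signals:
            raise KeyError(f"no signal for probe {spot.probe_id}")
        signal = probe_signals[spot.probe_id]
        # continuous center in pixel-center coordinates
        cx = spot.x_um / ps - 0.5
        cy = spot.y_um / ps - 0.5
        if not (0 <= cx < nx and 0 <= cy < ny):
            raise ValueError(f"spot {spot.spot_id} outside image bounds")
        if signal == 0:
            continue
        x0, x1 = int(np.floor(cx)) - half, int(np.floor(cx)) + half + 1
        y0, y1 = int(np.floor(cy)) - half, int(np.floor(cy)) + half + 1
        x0, x1 = max(x0, 0), min(x1, nx)
        y0, y1 = max(y0, 0), min(y1, ny)
        xs = np.arange(x0, x1)
        ys = np.arange(y0, y1)
        # pixel j spans [j-0.5, j+0.5] in pixel-center coordinates
        fx = ndtr((xs + 0.5 - cx) / sigma_px) - ndtr((xs - 0.5 - cx) / sigma_px)
        fy = ndtr((ys + 0.5 - cy) / sigma_px) - ndtr((ys - 0.5 - cy) / sigma_px)
        expected[y0:y1, x0:x1] += (
            params.exposure_scale * signal * np.outer(fy, fx)
        )

    if not noise:
        return expected
    rng = np.random.default_rng(params.seed)
    return rng.poisson(expected).astype(np.float64)


def write_image(
    image: np.ndarray,
    path,
    params: SimParams | None = None,
    truth: GroundTruth | None = None,
) -> None:
    """Write a 16-bit grayscale TIFF (``.tif``) or plain TSV matrix.

    When ``params``/``truth`` are given, a sidecar ``<path>.yaml`` records
    them for downstream test harnesses.
    """
    path = str(path)
    if path.endswith((".tif", ".tiff")):
        clipped = np.clip(np.rint(image), 0, np.iinfo(np.uint16).max)
        tifffile.imwrite(path, clipped.astype(np.uint16))
    else:
        np.savetxt(path, image, fmt="%.6g", delimiter="\t")
    if params is not None or truth is not None:
        sidecar: dict = {}
        if params is not None:
            sidecar["sim_params"] = {
                "pixel_size_um": params.pixel_size_um,
                "psf_sigma_um": params.psf_sigma_um,
                "background_rate": params.background_rate,
                "exposure_scale": params.exposure_scale,
                "seed": params.seed,
            }
        if truth is not None:
            sidecar["truth"] = dict(truth.abundance)
        with open(path + ".yaml", "w") as fh:
            yaml.safe_dump(sidecar, fh)


def read_image(path) -> np.ndarray:
    """Read a TIFF or TSV matrix image as float64."""
    path = str(path)
    if path.endswith((".tif", ".tiff")):
        return tifffile.imread(path).astype(np.float64)
    return np.loadtxt(path, delimiter="\t", ndmin=2).astype(np.float64)
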
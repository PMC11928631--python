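"""Droplet-volume estimation from monolayer micrographs.

Droplets imaged as a monolayer appear as bright discs whose equatorial
cross-section is visible; segmentation (global threshold → fill holes →
connected components → area/circularity filters) yields per-droplet
areas, converted to an equivalent diameter d = 2·sqrt(A/π) and a sphere
volume V = (π/6)·d³ (1 nL = 10⁶ µm³).  Touching droplets or debris are
rejected by the circularity and relative-area filters rather than split.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure

UM3_PER_NL = 1.0e6


@dataclass(frozen=True)
class ImageConfig:
    """Segmentation parameters.

    ``area_filter_um2`` bounds accepted component areas; when ``None``
    the bounds default to (0.25·median, 2·median) of the detected
    components, which rejects debris and merged doublets without a
    fixed scale.  ``circularity_min`` filters non-circular components
    (circularity = 4πA/P², 1 for a perfect circle).
    """

    pixel_scale_um_per_px: float
    area_filter_um2: tuple[float, float] | None = None
    circularity_min: float = 0.8
    threshold_method: str = "otsu"
    fixed_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.pixel_scale_um_per_px <= 0:
            raise ValueError("pixel scale must be positive")
        if not (0.0 <= self.circularity_min <= 1.0):
            raise ValueError("circularity_min must be in [0, 1]")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed threshold_method requires fixed_threshold")


@dataclass(frozen=True)
class DropletMeasurement:
    """One segmented droplet in physical units."""

    area_um2: float
    equivalent_diameter_um: float
    volume_nl: float
    circularity: float


def _measure_from_area(area_um2: float, circularity: float) -> DropletMeasurement:
    diameter = 2.0 * np.sqrt(area_um2 / np.pi)
    volume_nl = (np.pi / 6.0) * diameter**3 / UM3_PER_NL
    return DropletMeasurement(
        area_um2=float(area_um2),
        equivalent_diameter_um=float(diameter),
        volume_nl=float(volume_nl),
        circularity=float(circularity),
    )


def segment_droplets(
    image: np.ndarray, config: ImageConfig
) -> list[DropletMeasurement]:
    """Segment circular droplets and measure them in physical units.

    Pipeline: global threshold (Otsu by default) → binary fill holes →
    connected-component labelling → area and circularity filters →
    per-component area/diameter/volume.  Returns an empty list (with no
    exception) when nothing survives filtering.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if img.size == 0 or np.ptp(img) == 0:
        return []
    if config.threshold_method == "otsu":
        thr = filters.threshold_otsu(img)
    else:
        thr = config.fixed_threshold
    binary = img > thr
    if not binary.any():
        return []
    binary = ndimage.binary_fill_holes(binary)
    labels = measure.label(binary)
    props = measure.regionprops(labels)
    if not props:
        return []

    scale2 = config.pixel_scale_um_per_px**2
    areas_um2 = np.array([p.area * scale2 for p in props])
    if config.area_filter_um2 is not None:
        amin, amax = config.area_filter_um2
    else:
        med = float(np.median(areas_um2))
        amin, amax = 0.25 * med, 2.0 * med

    out: list[DropletMeasurement] = []
    for p, area_um2 in zip(props, areas_um2):
        if not (amin <= area_um2 <= amax):
            continue
        perim = p.perimeter
        circ = 4.0 * np.pi * p.area / perim**2 if perim > 0 else 0.0
        circ = min(circ, 1.0)  # digitization can push 4πA/P² above 1
        if circ < config.circularity_min:
            continue
        out.append(_measure_from_area(area_um2, circ))
    return out


def volume_summary(
    measurements: Sequence[DropletMeasurement] | Sequence[float],
) -> tuple[float, float, tuple[float, float], int]:
    """Mean droplet volume (nL), sample SD, normal 95% CI of the mean, n.

    Accepts either DropletMeasurement objects or raw volumes in nL.
    The CI is mean ± 1.96·SD/√n.
    """
    vols = np.array(
        [m.volume_nl if isinstance(m, DropletMeasurement) else float(m)
         for m in measurements],
        dtype=float,
    )
    if vols.size < 2:
        raise ValueError("need >= 2 droplet measurements")
    mean = float(np.mean(vols))
    sd = float(np.std(vols, ddof=1))
    half = 1.96 * sd / np.sqrt(vols.size)
    return mean, sd, (mean - half, mean + half), int(vols.size)


def measurements_to_frame(
    measurements: Sequence[DropletMeasurement],
) -> pd.DataFrame:
    """Tabular view: id, area_um2, diameter_um, volume_nl, circularity."""
    return pd.DataFrame(
        [
            dict(
                id=i,
                area_um2=m.area_um2,
                diameter_um=m.equivalent_diameter_um,
                volume_nl=m.volume_nl,
                circularity=m.circularity,
            )
            for i, m in enumerate(measurements)
        ],
        columns=["id", "area_um2", "diameter_um", "volume_nl", "circularity"],
    )
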
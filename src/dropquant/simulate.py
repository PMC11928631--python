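"""Synthetic droplet-plate and monolayer-image generator.

Emulates a two-channel droplet digital PCR experiment with known ground
truth: ~10,000–20,000 water-in-oil droplets per well, target (FAM,
channel 1) and reference (HEX, channel 2) copies loaded independently
per droplet as Poisson(c·V_i) with per-droplet volume V_i drawn from a
truncated normal around 0.70 nL, four amplitude clusters
(double-negative, ch1+, ch2+, double-positive) with Gaussian spread, an
optional "rain" fraction of intermediate-amplitude positives, blank
control wells, dilution series on the targets-per-cell scale, and two
artifact modes seen in crude-lysate runs without the viscosity-breakdown
pre-treatment: a diagonal smear of droplets in the 2-D amplitude plot
combined with a reduced droplet count, and a double-negative cluster
shifted upward in channel 1.

It also renders monolayer micrographs of bright discs with known
diameters for testing image-based droplet-volume estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import WellData

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_well",
    "simulate_blank_well",
    "simulate_dilution_series",
    "render_monolayer_image",
]

ARTIFACTS = ("none", "no_vb_diagonal", "shifted_dn_cluster")


@dataclass(frozen=True)
class SimConfig:
    """Full generative description of one synthetic well.

    Amplitude clusters default to the QX200 scale: negatives near
    1,000 (ch1) / 800 (ch2), positives near 8,000 / 6,000, separated by
    >20 negative-cluster SDs so that blank-derived thresholds sit far
    from both clusters.  Droplet volume defaults to the microscopy value
    0.70 nL with SD 0.022 nL (crude-lysate measurement), truncated at 0.
    """

    n_droplets_mean: float = 20_000.0
    n_droplets_sd: float = 1_000.0
    droplet_volume_nl_mean: float = 0.70
    droplet_volume_nl_sd: float = 0.022
    conc_target_per_ul: float = 1.0
    conc_ref_per_ul: float = 350.0
    neg_mean_ch1: float = 1_000.0
    neg_sd_ch1: float = 100.0
    pos_mean_ch1: float = 8_000.0
    pos_sd_ch1: float = 300.0
    neg_mean_ch2: float = 800.0
    neg_sd_ch2: float = 90.0
    pos_mean_ch2: float = 6_000.0
    pos_sd_ch2: float = 250.0
    rain_fraction: float = 0.02
    artifact: str = "none"
    artifact_params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.conc_target_per_ul < 0 or self.conc_ref_per_ul < 0:
            raise ValueError("concentrations must be >= 0")
        if not (0.0 <= self.rain_fraction < 1.0):
            raise ValueError("rain_fraction must be in [0, 1)")
        if self.pos_mean_ch1 <= self.neg_mean_ch1 or self.pos_mean_ch2 <= self.neg_mean_ch2:
            raise ValueError("positive cluster mean must exceed negative cluster mean")
        if self.droplet_volume_nl_mean <= 0:
            raise ValueError("droplet volume mean must be positive")
        if self.artifact not in ARTIFACTS:
            raise ValueError(f"artifact must be one of {ARTIFACTS}")


@dataclass
class GroundTruth:
    """Per-droplet truth for one simulated well.

    A droplet is truly positive on a channel iff its copy count is >= 1.
    """

    k1: np.ndarray
    k2: np.ndarray
    volume_nl: np.ndarray
    true_conc_target_per_ul: float
    true_conc_ref_per_ul: float

    @property
    def true_targets_per_cell(self) -> float:
        """Target-to-cell ratio with the diploid reference (2 copies/cell)."""
        if self.true_conc_ref_per_ul == 0:
            return float("nan")
        return self.true_conc_target_per_ul / (self.true_conc_ref_per_ul / 2.0)

    @property
    def n_ch1_positive(self) -> int:
        return int(np.sum(self.k1 >= 1))

    @property
    def n_ch2_positive(self) -> int:
        return int(np.sum(self.k2 >= 1))


def _draw_amplitudes(
    rng: np.random.Generator,
    positive: np.ndarray,
    neg_mean: float,
    neg_sd: float,
    pos_mean: float,
    pos_sd: float,
    rain_fraction: float,
) -> np.ndarray:
    """Cluster amplitudes for one channel, with uniform rain on positives."""
    n = positive.size
    amps = rng.normal(neg_mean, neg_sd, size=n)
    pos_amps = rng.normal(pos_mean, pos_sd, size=n)
    amps[positive] = pos_amps[positive]
    if rain_fraction > 0:
        rain = positive & (rng.random(n) < rain_fraction)
        amps[rain] = rng.uniform(neg_mean, pos_mean, size=n)[rain]
    return amps


def simulate_well(
    config: SimConfig,
    well_id: str = "A01",
    role: str = "sample",
    group_id: str = "",
) -> tuple[WellData, GroundTruth]:
    """Simulate one well: droplet volumes, Poisson loading, amplitudes.

    The droplet count is ``round(Normal(mean, sd))``; each droplet's
    volume is truncated-normal (>0) in nL; channel copy counts are
    independent Poisson(conc · V_i·10⁻³ µL) draws; amplitudes come from
    the negative cluster when the copy count is 0 and the positive
    cluster otherwise, except that a ``rain_fraction`` of positives lands
    uniformly between the cluster means.  Artifact transforms are
    applied last.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(rng.normal(config.n_droplets_mean, config.n_droplets_sd)))
    if config.artifact == "no_vb_diagonal":
        reduction = float(config.artifact_params.get("reduction", 0.6))
        if not (0 < reduction < 1):
            raise ValueError("no_vb_diagonal reduction factor must be in (0, 1)")
        n = int(round(n * reduction))
    if n <= 0:
        raise ValueError(
            "degenerate config: drew a non-positive droplet count "
            f"({n}) from Normal({config.n_droplets_mean}, {config.n_droplets_sd})"
        )

    if config.droplet_volume_nl_sd > 0:
        a = -config.droplet_volume_nl_mean / config.droplet_volume_nl_sd
        vol = stats.truncnorm.rvs(
            a, np.inf,
            loc=config.droplet_volume_nl_mean,
            scale=config.droplet_volume_nl_sd,
            size=n, random_state=rng,
        )
    else:
        vol = np.full(n, config.droplet_volume_nl_mean)

    vol_ul = vol * 1e-3
    k1 = rng.poisson(config.conc_target_per_ul * vol_ul)
    k2 = rng.poisson(config.conc_ref_per_ul * vol_ul)

    ch1 = _draw_amplitudes(
        rng, k1 >= 1,
        config.neg_mean_ch1, config.neg_sd_ch1,
        config.pos_mean_ch1, config.pos_sd_ch1,
        config.rain_fraction,
    )
    ch2 = _draw_amplitudes(
        rng, k2 >= 1,
        config.neg_mean_ch2, config.neg_sd_ch2,
        config.pos_mean_ch2, config.pos_sd_ch2,
        config.rain_fraction,
    )

    if config.artifact == "no_vb_diagonal":
        frac = float(config.artifact_params.get("fraction", 0.5))
        scale = float(config.artifact_params.get("scale", 4_000.0))
        hit = rng.random(n) < frac
        offset = scale * rng.random(n)  # shared per droplet -> diagonal smear
        ch1 = np.where(hit, ch1 + offset, ch1)
        ch2 = np.where(hit, ch2 + offset, ch2)
    elif config.artifact == "shifted_dn_cluster":
        frac = float(config.artifact_params.get("fraction", 0.1))
        offset = float(config.artifact_params.get("offset", 1_200.0))
        dn = (k1 == 0) & (k2 == 0)
        hit = dn & (rng.random(n) < frac)
        ch1 = np.where(hit, ch1 + offset, ch1)

    well = WellData(
        well_id=well_id, role=role, ch1=ch1, ch2=ch2, group_id=group_id,
        metadata={"seed": config.seed, "artifact": config.artifact},
    )
    truth = GroundTruth(
        k1=k1, k2=k2, volume_nl=vol,
        true_conc_target_per_ul=config.conc_target_per_ul,
        true_conc_ref_per_ul=config.conc_ref_per_ul,
    )
    return well, truth


def simulate_blank_well(
    config: SimConfig, well_id: str = "H01", role: str = "ntc"
) -> WellData:
    """Simulate a blank control well: both concentrations forced to zero.

    All amplitudes are drawn from the negative clusters (rain disabled —
    rain requires an amplified template).
    """
    blank_cfg = replace(
        config, conc_target_per_ul=0.0, conc_ref_per_ul=0.0,
        rain_fraction=0.0, artifact="none", artifact_params={},
    )
    well, _ = simulate_well(blank_cfg, well_id=well_id, role=role)
    return well


#: Volume of the reaction actually partitioned into droplets: the mean
#: droplet count times the mean droplet volume.  Cell numbers given to
#: the dilution-series generator are genome equivalents that end up in
#: droplets, so concentrations are copies per µL of this screened volume.
def _screened_volume_ul(config: SimConfig) -> float:
    return config.n_droplets_mean * config.droplet_volume_nl_mean * 1e-3


def simulate_dilution_series(
    base: SimConfig,
    targets_per_cell: Sequence[float],
    cells_per_well: float,
    replicates: int = 3,
    ref_copies_per_cell: float = 2.0,
    merge_wells_per_replicate: int = 1,
) -> tuple[list[tuple[WellData, GroundTruth]], pd.DataFrame]:
    """Simulate a dilution series on the targets-per-cell scale.

    For each dilution level the reference concentration is set from
    ``cells_per_well`` (``ref_copies_per_cell`` genome copies each,
    default 2 for a diploid locus) and the target concentration is
    level · cells-based reference.  Each replicate consists of
    ``merge_wells_per_replicate`` wells sharing one group id (the
    rare-target merge scheme: e.g. 4 wells → ~80,000 screened droplets
    per sample).

    Returns the wells with their ground truth plus a manifest table with
    columns ``well, sample_id, role, group, dilution, replicate,
    cells_per_well``.
    """
    ratios = list(targets_per_cell)
    if not ratios:
        raise ValueError("empty dilution-ratio list")
    if any(r <= 0 for r in ratios):
        raise ValueError("dilution ratios must be positive")
    if any(b >= a for a, b in zip(ratios, ratios[1:])):
        raise ValueError("dilution ratios must be strictly decreasing")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")

    v_screened = _screened_volume_ul(base)
    conc_cells = cells_per_well / v_screened  # cells per µL screened
    wells: list[tuple[WellData, GroundTruth]] = []
    rows = []
    seed_seq = np.random.SeedSequence(base.seed)
    n_wells_total = len(ratios) * replicates * merge_wells_per_replicate
    child_seeds = seed_seq.generate_state(n_wells_total) % (2**31)
    idx = 0
    for li, ratio in enumerate(ratios, start=1):
        conc_t = ratio * conc_cells  # copies/µL so that copies/cell = ratio
        conc_r = ref_copies_per_cell * conc_cells
        for rep in range(1, replicates + 1):
            group = f"dil{li}_rep{rep}"
            for sub in range(1, merge_wells_per_replicate + 1):
                wid = f"D{li}R{rep}W{sub}"
                cfg = replace(
                    base,
                    conc_target_per_ul=conc_t,
                    conc_ref_per_ul=conc_r,
                    seed=int(child_seeds[idx]),
                )
                idx += 1
                well, truth = simulate_well(
                    cfg, well_id=wid, role="sample", group_id=group
                )
                wells.append((well, truth))
                rows.append(
                    dict(
                        well=wid, sample_id=f"Dil{li}", role="sample",
                        group=group, dilution=ratio, replicate=rep,
                        cells_per_well=cells_per_well,
                    )
                )
    manifest = pd.DataFrame(rows)
    return wells, manifest


def render_monolayer_image(
    diameters_um: Sequence[float],
    pixel_scale_um_per_px: float = 0.5,
    image_size_px: tuple[int, int] = (2048, 2048),
    seed: int = 0,
    background: float = 20.0,
    disc_intensity: float = 200.0,
    rim_intensity: float = 150.0,
    noise_sd: float = 4.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a synthetic monolayer micrograph of droplet discs.

    Discs are bright with a slightly darker rim on a dark background
    plus Gaussian read noise, mimicking a bright-field image of a droplet
    monolayer.  Placement uses a shuffled jittered grid so discs never
    touch; if the canvas cannot hold all discs an error is raised.

    Returns an 8-bit grayscale image and a ground-truth table with
    per-disc center, diameter (µm) and area in px² and µm².
    """
    diameters = np.asarray(list(diameters_um), dtype=float)
    if diameters.size and np.any(diameters <= 0):
        raise ValueError("all diameters must be positive")
    h, w = int(image_size_px[0]), int(image_size_px[1])
    rng = np.random.default_rng(seed)
    img = np.full((h, w), background, dtype=np.float64)

    rows = []
    if diameters.size:
        radii_px = diameters / (2.0 * pixel_scale_um_per_px)
        max_d_px = 2 * radii_px.max()
        cell = int(np.ceil(max_d_px + 8))  # margin keeps neighbours separated
        ny, nx = h // cell, w // cell
        if ny * nx < diameters.size:
            raise ValueError(
                f"cannot place {diameters.size} non-overlapping discs of up to "
                f"{max_d_px:.0f} px on a {h}x{w} canvas"
            )
        slots = [(iy, ix) for iy in range(ny) for ix in range(nx)]
        order = rng.permutation(len(slots))[: diameters.size]
        for di, slot_i in enumerate(order):
            iy, ix = slots[slot_i]
            r = radii_px[di]
            jitter = (cell - 2 * r - 4) / 2.0
            cy = iy * cell + cell / 2.0 + rng.uniform(-jitter, jitter)
            cx = ix * cell + cell / 2.0 + rng.uniform(-jitter, jitter)
            # rasterize within the disc's bounding box only
            y0, y1 = int(np.floor(cy - r)) - 1, int(np.ceil(cy + r)) + 2
            x0, x1 = int(np.floor(cx - r)) - 1, int(np.ceil(cx + r)) + 2
            y0, x0 = max(y0, 0), max(x0, 0)
            y1, x1 = min(y1, h), min(x1, w)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            dist = np.hypot(yy - cy, xx - cx)
            inside = dist <= r
            rim = inside & (dist > r - 2.0)
            patch = img[y0:y1, x0:x1]
            patch[inside] = disc_intensity
            patch[rim] = rim_intensity
            area_px2 = float(np.sum(inside))
            rows.append(
                dict(
                    id=di, center_y_px=cy, center_x_px=cx,
                    diameter_um=diameters[di],
                    area_px2=area_px2,
                    area_um2=np.pi * (diameters[di] / 2.0) ** 2,
                )
            )
    img += rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)
    truth = pd.DataFrame(
        rows,
        columns=["id", "center_y_px", "center_x_px", "diameter_um",
                 "area_px2", "area_um2"],
    )
    return img, truth


def config_to_dict(config: SimConfig) -> dict:
    """Flat dictionary view of a SimConfig (for TOML-style persistence)."""
    return asdict(config)
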
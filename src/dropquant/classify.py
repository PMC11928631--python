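"""Droplet amplitude classification.

Raw droplet reader output is a two-channel amplitude per droplet
(FAM-labelled target on channel 1, HEX-labelled reference on channel 2).
This module turns amplitudes into quadrant counts: thresholds are fitted
from blank wells (no-template controls and target-negative cell-lysate
controls), manual exclusion regions replay gating of artifact clusters,
wells with too few accepted droplets are dropped, and replicate wells of
one sample are merged by summing counts before Poisson estimation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Wells with at most this many accepted droplets are excluded from analysis
#: (strict ``>`` rule: exactly 10,000 droplets is not enough).
DEFAULT_QC_MIN_DROPLETS = 10_000

VALID_ROLES = ("sample", "ntc", "clc", "dna_control")


@dataclass
class WellData:
    """Per-droplet two-channel amplitudes plus well metadata.

    Parameters
    ----------
    well_id : str
        Plate position or other unique identifier.
    role : str
        One of ``sample``, ``ntc`` (no-template control), ``clc``
        (cell-lysate control) or ``dna_control``.
    ch1, ch2 : ndarray
        Per-droplet amplitudes; equal length, finite.
    group_id : str
        Replicate-merge key; wells sharing a group are summed before
        quantification.
    metadata : dict
        Free-form annotations (dilution level, cells per well, ...).
    """

    well_id: str
    role: str
    ch1: np.ndarray
    ch2: np.ndarray
    group_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ch1 = np.asarray(self.ch1, dtype=float)
        self.ch2 = np.asarray(self.ch2, dtype=float)
        if self.role not in VALID_ROLES:
            raise ValueError(
                f"unknown well role {self.role!r}; allowed: {VALID_ROLES}"
            )
        if self.ch1.shape != self.ch2.shape or self.ch1.ndim != 1:
            raise ValueError("ch1/ch2 must be 1-D arrays of equal length")
        if self.ch1.size and not (
            np.all(np.isfinite(self.ch1)) and np.all(np.isfinite(self.ch2))
        ):
            raise ValueError(f"non-finite amplitude in well {self.well_id}")

    @property
    def n_droplets(self) -> int:
        return int(self.ch1.size)

    @property
    def is_blank(self) -> bool:
        return self.role in ("ntc", "clc")


@dataclass(frozen=True)
class ThresholdPair:
    """Per-channel positivity thresholds with fitting provenance."""

    ch1_threshold: float
    ch2_threshold: float
    method: str = "blank_mean_plus_k_sd"
    k_sd: float = float("nan")
    n_blank_wells: int = 0


@dataclass(frozen=True)
class ExclusionRegion:
    """Axis-aligned amplitude rectangle removed before counting.

    Replays manual gating of artifact clusters (e.g. a double-negative
    cluster shifted upward in channel 1).  Intervals are closed.
    """

    ch1_range: tuple[float, float]
    ch2_range: tuple[float, float]
    reason: str = ""

    def __post_init__(self) -> None:
        if self.ch1_range[0] > self.ch1_range[1] or self.ch2_range[0] > self.ch2_range[1]:
            raise ValueError("exclusion region intervals must be non-empty")

    def contains(self, ch1: np.ndarray, ch2: np.ndarray) -> np.ndarray:
        return (
            (ch1 >= self.ch1_range[0])
            & (ch1 <= self.ch1_range[1])
            & (ch2 >= self.ch2_range[0])
            & (ch2 <= self.ch2_range[1])
        )


@dataclass(frozen=True)
class QuadrantCounts:
    """Classified droplet tallies for one well or merged group.

    ``n_total`` counts accepted (non-excluded) droplets and always equals
    ``n_dn + n_ch1_only + n_ch2_only + n_dp``; excluded droplets are
    tracked separately.
    """

    n_total: int
    n_dn: int
    n_ch1_only: int
    n_ch2_only: int
    n_dp: int
    n_excluded: int = 0
    well_id: str = ""
    group_id: str = ""

    def __post_init__(self) -> None:
        parts = (self.n_dn, self.n_ch1_only, self.n_ch2_only, self.n_dp)
        if any(v < 0 for v in parts) or self.n_excluded < 0:
            raise ValueError("negative droplet count")
        if sum(parts) != self.n_total:
            raise ValueError("quadrant counts do not sum to n_total")

    @property
    def n_ch1_positive(self) -> int:
        """Droplets positive on channel 1 (single or double positive)."""
        return self.n_ch1_only + self.n_dp

    @property
    def n_ch2_positive(self) -> int:
        return self.n_ch2_only + self.n_dp

    def n_negative(self, channel: str) -> int:
        """Negative-droplet count for the Poisson estimator on a channel."""
        if channel == "ch1":
            return self.n_total - self.n_ch1_positive
        if channel == "ch2":
            return self.n_total - self.n_ch2_positive
        raise ValueError("channel must be 'ch1' or 'ch2'")


def fit_thresholds(
    blank_wells: Sequence[WellData],
    k_sd: float = 7.0,
    fallback_margin: float = 500.0,
) -> ThresholdPair:
    """Fit per-channel thresholds as pooled-blank mean + ``k_sd`` · SD.

    Blank reactions (NTCs and/or CLCs) carry no target, so their pooled
    amplitude distribution is the negative cluster; the threshold is
    placed ``k_sd`` standard deviations above its mean.  The default
    ``k_sd = 7`` puts the per-droplet false-positive probability below
    1e-11 for Gaussian blanks, which keeps the limit of blank at zero
    over tens of wells while remaining far below the positive cluster.

    If the blanks are degenerate (zero SD), the threshold falls back to
    mean + ``fallback_margin`` and a warning is logged.
    """
    if not blank_wells:
        raise ValueError("at least one blank well is required")
    ch1 = np.concatenate([w.ch1 for w in blank_wells])
    ch2 = np.concatenate([w.ch2 for w in blank_wells])
    if ch1.size == 0:
        raise ValueError("blank wells contain zero droplets")

    def _one(amps: np.ndarray, name: str) -> float:
        mu = float(np.mean(amps))
        sd = float(np.std(amps, ddof=1)) if amps.size > 1 else 0.0
        if sd == 0.0:
            logger.warning(
                "constant blank amplitudes on %s; using fallback margin %g",
                name, fallback_margin,
            )
            return mu + fallback_margin
        return mu + k_sd * sd

    pair = ThresholdPair(
        ch1_threshold=_one(ch1, "ch1"),
        ch2_threshold=_one(ch2, "ch2"),
        k_sd=k_sd,
        n_blank_wells=len(blank_wells),
    )
    logger.info(
        "thresholds from %d blank wells (%d droplets): ch1=%.1f ch2=%.1f",
        len(blank_wells), ch1.size, pair.ch1_threshold, pair.ch2_threshold,
    )
    return pair


def classify_well(
    well: WellData,
    thresholds: ThresholdPair,
    exclusions: Sequence[ExclusionRegion] = (),
) -> QuadrantCounts:
    """Assign every droplet to a quadrant by strict threshold comparison.

    A droplet is positive on a channel iff amplitude ``>`` threshold
    (a droplet exactly at the threshold is negative — conservative for
    rare targets).  Droplets inside any exclusion rectangle are removed
    from ``n_total`` and reported in ``n_excluded``.
    """
    ch1, ch2 = well.ch1, well.ch2
    excluded = np.zeros(ch1.shape, dtype=bool)
    for region in exclusions:
        excluded |= region.contains(ch1, ch2)
    keep = ~excluded
    pos1 = ch1[keep] > thresholds.ch1_threshold
    pos2 = ch2[keep] > thresholds.ch2_threshold
    n_dp = int(np.sum(pos1 & pos2))
    n_ch1_only = int(np.sum(pos1 & ~pos2))
    n_ch2_only = int(np.sum(~pos1 & pos2))
    n_dn = int(np.sum(~pos1 & ~pos2))
    n_excluded = int(np.sum(excluded))
    if n_excluded:
        logger.info("well %s: excluded %d droplets", well.well_id, n_excluded)
    return QuadrantCounts(
        n_total=n_dn + n_ch1_only + n_ch2_only + n_dp,
        n_dn=n_dn,
        n_ch1_only=n_ch1_only,
        n_ch2_only=n_ch2_only,
        n_dp=n_dp,
        n_excluded=n_excluded,
        well_id=well.well_id,
        group_id=well.group_id,
    )


def qc_filter_wells(
    counts: Iterable[QuadrantCounts],
    min_droplets: int = DEFAULT_QC_MIN_DROPLETS,
) -> tuple[list[QuadrantCounts], list[tuple[QuadrantCounts, str]]]:
    """Keep wells with strictly more than ``min_droplets`` accepted droplets.

    Returns ``(kept, dropped)`` where each dropped entry carries a reason
    string; ``n_total`` is the post-exclusion count.
    """
    kept: list[QuadrantCounts] = []
    dropped: list[tuple[QuadrantCounts, str]] = []
    for c in counts:
        if c.n_total > min_droplets:
            kept.append(c)
        else:
            reason = (
                f"{c.n_total} accepted droplets <= QC minimum {min_droplets}"
            )
            logger.info("well %s dropped: %s", c.well_id, reason)
            dropped.append((c, reason))
    return kept, dropped


def merge_counts(counts_list: Sequence[QuadrantCounts]) -> QuadrantCounts:
    """Sum quadrant counts across replicate wells of one group.

    Summing partitions before the Poisson estimate is how rare targets
    gain sensitivity: four ~20,000-droplet replicates screen ~80,000
    partitions as a single sample.  All wells must share a group id.
    """
    if not counts_list:
        raise ValueError("cannot merge an empty list of counts")
    groups = {c.group_id for c in counts_list}
    if len(groups) > 1:
        raise ValueError(f"cannot merge counts from different groups: {sorted(groups)}")
    return QuadrantCounts(
        n_total=sum(c.n_total for c in counts_list),
        n_dn=sum(c.n_dn for c in counts_list),
        n_ch1_only=sum(c.n_ch1_only for c in counts_list),
        n_ch2_only=sum(c.n_ch2_only for c in counts_list),
        n_dp=sum(c.n_dp for c in counts_list),
        n_excluded=sum(c.n_excluded for c in counts_list),
        well_id="+".join(c.well_id for c in counts_list if c.well_id),
        group_id=counts_list[0].group_id,
    )
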
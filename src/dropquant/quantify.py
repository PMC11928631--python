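"""Poisson absolute quantification from droplet counts.

Each droplet is an independent partition; target copies load into a
droplet of volume V (µL) as Poisson(c·V) at concentration c copies/µL.
The fraction of negative droplets therefore estimates e^{-λ} with
λ = c·V copies per droplet, giving the standard digital-PCR estimator

    λ̂ = −ln(N_neg / N),      ĉ = λ̂ / V_droplet

with V_droplet the per-droplet volume in µL.  The default droplet volume
is 0.70 nL, measured by optical microscopy of droplet monolayers (the
instrument software assumes 0.85 nL, which overestimates the droplet
size and hence underestimates concentration).

The standard error of λ̂ comes from the delta method on the binomial
negative fraction p = N_neg/N:  SE(λ̂) = sqrt((1−p)/(N·p)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .classify import QuadrantCounts

#: Droplet volume (nL) measured by monolayer microscopy; used instead of
#: the 0.85 nL assumed by the vendor software.
DEFAULT_DROPLET_VOLUME_NL = 0.70
#: Volume loaded into the droplet generator from the 22 µL reaction mix.
DEFAULT_REACTION_VOLUME_UL = 20.0
#: Reference copies per genome for a diploid autosomal locus (RPP30).
DEFAULT_REF_COPIES_PER_CELL = 2

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class SaturationError(ValueError):
    """No negative droplets: λ is above the assay's dynamic range."""


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Poisson concentration estimate for one channel of a merged group."""

    lambda_: float
    se_lambda: float
    concentration_per_ul: float
    ci95: tuple[float, float]
    n_total: int
    n_neg: int
    droplet_volume_nl: float
    channel: str = "target"

    @property
    def copies_per_droplet(self) -> float:
        return self.lambda_


@dataclass(frozen=True)
class TargetPerCell:
    """Target copies per cell via the reference channel.

    Cells per reaction are estimated from the reference-gene
    concentration: cells = c_ref · V_reaction / copies-per-cell.
    """

    targets_per_cell: float
    ci95: tuple[float, float]
    cells_per_reaction: float
    copies_per_reaction: float
    ref_copies_per_cell: float
    reaction_volume_ul: float


def estimate_lambda(n_neg: int, n_total: int) -> tuple[float, float]:
    """Mean copies per droplet and its delta-method standard error.

    Parameters
    ----------
    n_neg : int
        Negative droplets on the channel of interest.
    n_total : int
        Accepted droplets.

    Returns
    -------
    (lambda, se) : tuple of float
        ``lambda = -ln(n_neg/n_total)``; ``se = sqrt((1-p)/(n_total*p))``
        with ``p = n_neg/n_total``.  ``n_neg == n_total`` gives λ = 0
        with SE 0 (one-sided CI downstream).

    Raises
    ------
    SaturationError
        If ``n_neg == 0``: every droplet is positive and λ is above the
        dynamic range (undefined, not infinite-precision).
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if n_neg < 0 or n_neg > n_total:
        raise ValueError("need 0 <= n_neg <= n_total")
    if n_neg == 0:
        raise SaturationError(
            f"no negative droplets among {n_total}: concentration above dynamic range"
        )
    p = n_neg / n_total
    lam = -math.log(p) + 0.0  # avoid -0.0 when p == 1
    se = math.sqrt((1.0 - p) / (n_total * p))
    return lam, se


def to_concentration(
    n_neg: int,
    n_total: int,
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
    channel: str = "target",
) -> ConcentrationEstimate:
    """Concentration in copies/µL from droplet counts.

    ``concentration = λ / (droplet volume in µL)``; the 95% CI is
    ``(λ ± 1.96·SE)/V`` floored at 0.  For ``n_neg == n_total`` the point
    estimate is 0 with a one-sided upper bound.
    """
    if droplet_volume_nl <= 0:
        raise ValueError("droplet volume must be positive")
    lam, se = estimate_lambda(n_neg, n_total)
    v_ul = droplet_volume_nl * 1e-3
    conc = lam / v_ul
    lo = max(0.0, (lam - Z_95 * se) / v_ul)
    hi = (lam + Z_95 * se) / v_ul
    if n_neg == n_total:
        # all-negative well: zero point estimate; one-sided 95% upper
        # bound from the rule of three (λ < 3/N when 0 of N positive)
        lo = 0.0
        hi = (3.0 / n_total) / v_ul
    return ConcentrationEstimate(
        lambda_=lam,
        se_lambda=se,
        concentration_per_ul=conc,
        ci95=(lo, hi),
        n_total=n_total,
        n_neg=n_neg,
        droplet_volume_nl=droplet_volume_nl,
        channel=channel,
    )


def concentration_from_counts(
    counts: QuadrantCounts,
    channel: str = "ch1",
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
) -> ConcentrationEstimate:
    """Convenience wrapper: quadrant counts → concentration for a channel."""
    return to_concentration(
        counts.n_negative(channel),
        counts.n_total,
        droplet_volume_nl,
        channel="target" if channel == "ch1" else "reference",
    )


def targets_per_cell(
    target_est: ConcentrationEstimate,
    ref_est: ConcentrationEstimate,
    ref_copies_per_cell: float = DEFAULT_REF_COPIES_PER_CELL,
    reaction_volume_ul: float = DEFAULT_REACTION_VOLUME_UL,
    propagate_ref_uncertainty: bool = False,
) -> TargetPerCell:
    """Target copies per cell from paired target/reference estimates.

    targets/cell = c_target / (c_ref / copies-per-cell).  By default the
    CI propagates only the target-channel uncertainty: the reference is
    typically 10³–10⁴-fold more abundant, so its relative SE is
    negligible.  ``propagate_ref_uncertainty=True`` switches to the full
    delta-method ratio variance.
    """
    if ref_est.concentration_per_ul <= 0:
        raise ValueError("reference concentration is zero: cell count undefined")
    cells = ref_est.concentration_per_ul * reaction_volume_ul / ref_copies_per_cell
    copies_rxn = target_est.concentration_per_ul * reaction_volume_ul
    ratio = target_est.concentration_per_ul / (
        ref_est.concentration_per_ul / ref_copies_per_cell
    )
    scale = ref_copies_per_cell / ref_est.concentration_per_ul
    if propagate_ref_uncertainty and ref_est.lambda_ > 0:
        rel_var = (
            (target_est.se_lambda / target_est.lambda_) ** 2
            if target_est.lambda_ > 0
            else 0.0
        ) + (ref_est.se_lambda / ref_est.lambda_) ** 2
        half = Z_95 * ratio * math.sqrt(rel_var)
        ci = (max(0.0, ratio - half), ratio + half)
    else:
        ci = (target_est.ci95[0] * scale, target_est.ci95[1] * scale)
    return TargetPerCell(
        targets_per_cell=ratio,
        ci95=ci,
        cells_per_reaction=cells,
        copies_per_reaction=copies_rxn,
        ref_copies_per_cell=ref_copies_per_cell,
        reaction_volume_ul=reaction_volume_ul,
    )


def copies_per_ul_to_per_cell(
    concentration_per_ul: float, cells_per_ul: float
) -> float:
    """Convert a copies/µL concentration to copies per cell.

    Used to place per-volume limits (e.g. a 2 copies/µL-of-blood limit of
    quantification) on the per-cell scale: at 10³ cells/µL, 2 copies/µL
    is 0.002 copies/cell.
    """
    if cells_per_ul <= 0:
        raise ValueError("cells_per_ul must be positive")
    return concentration_per_ul / cells_per_ul
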
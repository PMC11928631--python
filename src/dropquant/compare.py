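"""Method comparison: linearity, rank agreement and Bland-Altman analysis.

Used to compare the crude-lysate assay against a reference assay run on
the same samples: ordinary least squares for accuracy (with a t-based
95% CI on the slope and a flag for whether it contains 1), Spearman rank
correlation for monotone agreement, and Bland-Altman bias with limits of
agreement for absolute agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm


@dataclass
class PairedMeasurements:
    """Same-unit measurements of the same samples by two methods.

    ``x`` is the reference method, ``y`` the test method.
    """

    x: np.ndarray
    y: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if not self.labels:
            self.labels = tuple(str(i) for i in range(self.x.size))
        if len(self.labels) != self.x.size:
            raise ValueError("labels length must match measurements")

    def __len__(self) -> int:
        return int(self.x.size)


@dataclass(frozen=True)
class LinearFitResult:
    slope: float
    intercept: float
    r2: float
    slope_ci95: tuple[float, float]
    p_slope: float
    slope_ci_contains_one: bool


@dataclass(frozen=True)
class AgreementResult:
    """Bland-Altman agreement: bias and 95% limits of agreement.

    ``bias`` is the mean difference in the stated direction (default
    test − reference); ``loa`` = bias ± 1.96·SD of the differences.
    """

    bias: float
    sd_diff: float
    loa: tuple[float, float]
    direction: str = "test - reference"
    table: pd.DataFrame | None = None


def linear_fit(pairs: PairedMeasurements) -> LinearFitResult:
    """Ordinary least squares of test on reference with slope CI.

    Requires ≥ 3 pairs and non-constant x.  The 95% CI on the slope uses
    the t distribution with n−2 degrees of freedom; the fit also reports
    whether that CI contains 1 (no proportional bias).
    """
    if len(pairs) < 3:
        raise ValueError("need >= 3 pairs for regression")
    if np.ptp(pairs.x) == 0:
        raise ValueError("x is constant: slope undefined")
    exog = sm.add_constant(pairs.x)
    fit = sm.OLS(pairs.y, exog).fit()
    ci = fit.conf_int(alpha=0.05)
    slope_ci = (float(ci[1, 0]), float(ci[1, 1]))
    return LinearFitResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r2=float(fit.rsquared),
        slope_ci95=slope_ci,
        p_slope=float(fit.pvalues[1]),
        slope_ci_contains_one=slope_ci[0] <= 1.0 <= slope_ci[1],
    )


def spearman_rho(pairs: PairedMeasurements) -> float:
    """Spearman rank correlation with ties mid-ranked."""
    if len(pairs) < 3:
        raise ValueError("need >= 3 pairs")
    if np.ptp(pairs.x) == 0 or np.ptp(pairs.y) == 0:
        raise ValueError("constant series: rank correlation undefined")
    rho, _ = stats.spearmanr(pairs.x, pairs.y)
    return float(rho)


def bland_altman(
    pairs: PairedMeasurements, direction: str = "test - reference"
) -> AgreementResult:
    """Bland-Altman bias and limits of agreement.

    Differences are taken as y − x ("test - reference") by default; pass
    ``direction="reference - test"`` to flip the sign convention (the
    direction is recorded in the result so the sign of the bias is never
    ambiguous).  Limits of agreement are bias ± 1.96·sample SD.
    """
    if len(pairs) < 2:
        raise ValueError("need >= 2 pairs for Bland-Altman")
    if direction == "test - reference":
        diff = pairs.y - pairs.x
    elif direction == "reference - test":
        diff = pairs.x - pairs.y
    else:
        raise ValueError("direction must be 'test - reference' or 'reference - test'")
    avg = (pairs.x + pairs.y) / 2.0
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    table = pd.DataFrame(
        {"label": pairs.labels, "average": avg, "difference": diff}
    )
    return AgreementResult(
        bias=bias,
        sd_diff=sd,
        loa=(bias - 1.96 * sd, bias + 1.96 * sd),
        direction=direction,
        table=table,
    )


def plot_bland_altman(result: AgreementResult, ax=None):
    """Scatter of per-pair (average, difference) with bias and LoA lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = result.table
    ax.scatter(t["average"], t["difference"], s=20)
    ax.axhline(result.bias, color="k", label=f"bias {result.bias:.4g}")
    for lim in result.loa:
        ax.axhline(lim, color="k", linestyle="--")
    ax.set_xlabel("average of methods")
    ax.set_ylabel(f"difference ({result.direction})")
    ax.legend()
    return ax


def plot_method_scatter(pairs: PairedMeasurements, fit: LinearFitResult | None = None, ax=None):
    """Reference-vs-test scatter with identity and optional fitted line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(pairs.x, pairs.y, s=20)
    lims = [min(pairs.x.min(), pairs.y.min()), max(pairs.x.max(), pairs.y.max())]
    ax.plot(lims, lims, "k:", label="identity")
    if fit is not None:
        xs = np.linspace(lims[0], lims[1], 50)
        ax.plot(xs, fit.intercept + fit.slope * xs, "r-",
                label=f"y = {fit.slope:.3f}x + {fit.intercept:.3f}")
    ax.set_xlabel("reference method")
    ax.set_ylabel("test method")
    ax.legend()
    return ax
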
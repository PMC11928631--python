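"""Assay performance characterization: LOB, LOD, LOQ, CV, probit hit rate.

Follows the standard clinical-assay definitions:

* LOB = mean + 1.645·SD of blank-reaction concentrations (95th percentile
  of the blank distribution under normality).
* LOD = LOB + 1.645·SD of the lowest dilution level.
* LOQ = the lowest tested level quantifiable with CV ≤ 35%.
* Repeatability = per-sample coefficient of variation over replicates,
  with sample SD (n−1 denominator).
* Hit rate = fraction of replicates at a level in which the target was
  detected (≥ 1 positive droplet in the merged group); a probit
  regression of hit rate on log10 concentration is fitted by maximum
  likelihood when rates vary, and skipped as degenerate when every level
  is all-hit or all-miss (the slope is unidentifiable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

Z_ONE_SIDED_95 = 1.645  # one-sided 95% normal quantile used by LOB/LOD
DEFAULT_CV_MAX_PCT = 35.0


@dataclass(frozen=True)
class BlankPanel:
    """Copy-number concentrations measured in blank reactions."""

    blank_measurements: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.blank_measurements) < 2:
            raise ValueError("need >= 2 blank measurements for an SD")
        if any(v < 0 for v in self.blank_measurements):
            raise ValueError("blank concentrations must be >= 0")

    @property
    def n_blanks(self) -> int:
        return len(self.blank_measurements)


@dataclass
class ValidationReport:
    """Bundle of assay-performance quantities."""

    lob: float | None = None
    lod: float | None = None
    loq: float | None = None
    loq_level: str | None = None
    loq_cv_pct: float | None = None
    cv_table: pd.DataFrame | None = None
    mean_cv_pct: float | None = None
    hit_rates: pd.DataFrame | None = None
    probit_fit: tuple[float, float] | str | None = None
    notes: list[str] = field(default_factory=list)

    def to_text(self) -> str:
        lines = ["Assay validation report", "=" * 23]
        def fmt(v):
            return "unavailable" if v is None else f"{v:.6g}"
        lines.append(f"LOB: {fmt(self.lob)}")
        lines.append(f"LOD: {fmt(self.lod)}")
        if self.loq is None:
            lines.append("LOQ: not reached" if self.loq_level == "not reached"
                         else "LOQ: unavailable")
        else:
            lines.append(
                f"LOQ: {self.loq:.6g} (level {self.loq_level}, "
                f"CV {self.loq_cv_pct:.2f}%)"
            )
        if self.mean_cv_pct is not None:
            lines.append(f"Mean intra-assay CV: {self.mean_cv_pct:.2f}%")
        if self.cv_table is not None:
            lines.append("")
            lines.append(self.cv_table.to_string(index=False))
        if self.hit_rates is not None:
            lines.append("")
            lines.append(self.hit_rates.to_string(index=False))
            lines.append(f"Probit fit: {self.probit_fit}")
        for n in self.notes:
            lines.append(f"note: {n}")
        return "\n".join(lines)


def cv_percent(replicates: Sequence[float]) -> tuple[float, float, float]:
    """Mean, sample SD and coefficient of variation (%) of replicates.

    Uses the n−1 (sample) standard deviation.  Raises on fewer than two
    replicates or a zero mean.
    """
    x = np.asarray(list(replicates), dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 replicates for a CV")
    mean = float(np.mean(x))
    if mean == 0.0:
        raise ValueError("CV undefined for zero mean")
    sd = float(np.std(x, ddof=1))
    return mean, sd, 100.0 * sd / mean


def repeatability_summary(
    samples: Mapping[str, Sequence[float]],
) -> tuple[pd.DataFrame, float]:
    """Per-sample CV table plus the unweighted mean of the CVs."""
    rows = []
    for sample_id, reps in samples.items():
        try:
            mean, sd, cv = cv_percent(reps)
        except ValueError as err:
            raise ValueError(f"sample {sample_id!r}: {err}") from err
        rows.append(
            dict(sample=sample_id, n=len(list(reps)), mean=mean, sd=sd,
                 cv_pct=cv)
        )
    table = pd.DataFrame(rows)
    return table, float(table["cv_pct"].mean())


def limit_of_blank(panel: BlankPanel) -> float:
    """LOB = mean + 1.645·SD over blank concentrations (sample SD)."""
    x = np.asarray(panel.blank_measurements, dtype=float)
    return float(np.mean(x) + Z_ONE_SIDED_95 * np.std(x, ddof=1))


def limit_of_detection(
    lob: float,
    lowest_level_replicates: Sequence[float] | None = None,
    sd: float | None = None,
) -> float:
    """LOD = LOB + 1.645·SD of the lowest dilution level.

    Either the replicate values at the lowest level or a precomputed SD
    must be supplied.
    """
    if sd is None:
        if lowest_level_replicates is None or len(list(lowest_level_replicates)) < 2:
            raise ValueError("need >= 2 lowest-level replicates or a precomputed SD")
        sd = float(np.std(np.asarray(list(lowest_level_replicates), dtype=float),
                          ddof=1))
    if sd < 0:
        raise ValueError("SD must be >= 0")
    return lob + Z_ONE_SIDED_95 * sd


def limit_of_quantification(
    levels: Sequence[tuple[str, float, Sequence[float]]],
    cv_max_pct: float = DEFAULT_CV_MAX_PCT,
) -> tuple[str | None, float | None, float | None]:
    """Lowest tested level with CV ≤ ``cv_max_pct`` (inclusive).

    ``levels`` is a sequence of ``(label, mean_concentration,
    replicates)`` sorted descending by concentration.  Returns
    ``(label, mean, cv)`` of the qualifying level, or
    ``("not reached", None, None)`` if none qualifies.
    """
    if not levels:
        raise ValueError("no dilution levels supplied")
    concs = [lvl[1] for lvl in levels]
    if any(b > a for a, b in zip(concs, concs[1:])):
        raise ValueError("levels must be sorted descending by concentration")
    chosen: tuple[str, float, float] | None = None
    for label, mean_conc, reps in levels:
        _, _, cv = cv_percent(reps)
        if cv <= cv_max_pct:
            chosen = (label, mean_conc, cv)  # keep last (lowest) qualifier
    if chosen is None:
        return "not reached", None, None
    return chosen


def probit_hit_rate(
    detections: Sequence[tuple[int, int, float]],
) -> tuple[pd.DataFrame, tuple[float, float] | str]:
    """Per-level hit rates and a probit dose-response fit.

    ``detections`` holds ``(n_detected, n_replicates, concentration)``
    per level.  The probit model Φ(a + b·log10 c) is fitted by maximum
    likelihood (binomial GLM) when hit rates vary between 0 and 1;
    with complete separation or all-identical rates the fit is flagged
    ``"degenerate"`` and only the rates are reported.
    """
    if not detections:
        raise ValueError("no dilution levels supplied")
    rows = []
    for n_det, n_rep, conc in detections:
        if n_rep <= 0:
            raise ValueError("zero replicates at a level")
        if not (0 <= n_det <= n_rep):
            raise ValueError("need 0 <= n_detected <= n_replicates")
        rows.append(dict(concentration=conc, n_detected=n_det,
                         n_replicates=n_rep, hit_rate=n_det / n_rep))
    table = pd.DataFrame(rows)

    rates = table["hit_rate"].to_numpy()
    if np.all(rates == 1.0) or np.all(rates == 0.0) or len(table) < 2:
        return table, "degenerate"
    endog = table[["n_detected"]].copy()
    endog["n_missed"] = table["n_replicates"] - table["n_detected"]
    exog = sm.add_constant(np.log10(table["concentration"].to_numpy()))
    try:
        import warnings

        with warnings.catch_warnings():
            # quasi-separation is expected near 0/100% plateaus; the
            # finite params statsmodels returns are still the MLE
            # restricted to its stopping tolerance
            warnings.simplefilter("ignore")
            fit = sm.GLM(
                endog.to_numpy(), exog,
                family=sm.families.Binomial(link=sm.families.links.Probit()),
            ).fit()
    except Exception:
        return table, "degenerate"
    intercept, slope = float(fit.params[0]), float(fit.params[1])
    if not (math.isfinite(intercept) and math.isfinite(slope)):
        return table, "degenerate"
    return table, (intercept, slope)


def probit_c50(probit_fit: tuple[float, float]) -> float:
    """Concentration with 50% detection from a probit fit (Φ⁻¹(0.5)=0)."""
    intercept, slope = probit_fit
    if slope == 0:
        raise ValueError("zero slope: c50 undefined")
    return 10.0 ** (-intercept / slope)
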
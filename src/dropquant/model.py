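"""Plate-level model: thresholds → classification → QC → merge → Poisson.

`DropletPlateModel` is constructed from a `PlateData` (droplet
amplitudes plus manifest) and a `RunConfig`; `fit()` runs the full
analysis and returns a `DropletPlateResults` carrying per-well
classifications, per-group concentration estimates with 95% CIs, and —
when the manifest describes blank wells and/or a dilution series — an
assay validation report (LOB/LOD/LOQ, repeatability CVs, probit hit
rates).  `summary()` renders the estimates as a text table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classify as _classify
from . import quantify as _quantify
from . import validate as _validate
from .classify import QuadrantCounts, ThresholdPair
from .io import PlateData, RunConfig

logger = logging.getLogger(__name__)


@dataclass
class DropletPlateResults:
    """Fitted plate analysis.

    Attributes
    ----------
    thresholds : ThresholdPair
        Blank-derived positivity thresholds.
    classifications : DataFrame
        One row per well: quadrant counts, exclusions, QC status.
    concentrations : DataFrame
        One row per merged group and channel: counts, λ, copies/µL with
        CI, plus cells/reaction, copies/reaction and targets/cell where
        the reference channel allows it.
    validation : ValidationReport or None
        LOB/LOD/LOQ, CV table and hit rates when computable.
    """

    model: "DropletPlateModel"
    thresholds: ThresholdPair
    classifications: pd.DataFrame
    concentrations: pd.DataFrame
    validation: _validate.ValidationReport | None = None
    dropped_wells: list[tuple[QuadrantCounts, str]] = field(default_factory=list)
    merged_counts: dict[str, QuadrantCounts] = field(default_factory=dict)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Droplet plate analysis",
            "=" * 60,
            f"wells analysed: {len(self.classifications)}"
            f" (dropped by QC: {len(self.dropped_wells)})",
            f"thresholds: ch1 {self.thresholds.ch1_threshold:.1f}, "
            f"ch2 {self.thresholds.ch2_threshold:.1f} "
            f"(mean + {self.thresholds.k_sd:g} SD over "
            f"{self.thresholds.n_blank_wells} blank wells)",
            f"droplet volume: {cfg.droplet_volume_nl:g} nL; "
            f"reaction volume: {cfg.reaction_volume_ul:g} uL; "
            f"reference copies/cell: {cfg.ref_copies_per_cell:g}",
            "",
            "Concentration estimates (per merged group)",
            "-" * 60,
        ]
        cols = ["group", "channel", "n_total", "n_neg", "lambda",
                "conc_per_ul", "ci_low", "ci_high", "targets_per_cell"]
        view = self.concentrations[
            [c for c in cols if c in self.concentrations.columns]
        ]
        lines.append(view.to_string(index=False, float_format=lambda v: f"{v:.6g}"))
        if self.validation is not None:
            lines += ["", self.validation.to_text()]
        return "\n".join(lines)

    def to_csv(self, directory) -> None:
        """Write classification and concentration tables (audit trail)."""
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.classifications.to_csv(directory / "classification.csv", index=False)
        self.concentrations.to_csv(directory / "concentrations.csv", index=False)
        if self.validation is not None:
            (directory / "validation.txt").write_text(self.validation.to_text())
            if self.validation.cv_table is not None:
                self.validation.cv_table.to_csv(
                    directory / "cv_table.csv", index=False
                )

    def plot_amplitudes(self, well_id: str, ax=None):
        """2-D amplitude plot of one well with the fitted thresholds."""
        import matplotlib.pyplot as plt

        well = next(w for w in self.model.plate.wells if w.well_id == well_id)
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(well.ch2, well.ch1, s=2, alpha=0.4)
        ax.axhline(self.thresholds.ch1_threshold, color="magenta", lw=1)
        ax.axvline(self.thresholds.ch2_threshold, color="magenta", lw=1)
        ax.set_xlabel("Ch2 amplitude (reference)")
        ax.set_ylabel("Ch1 amplitude (target)")
        ax.set_title(well_id)
        return ax


class DropletPlateModel:
    """Two-channel droplet PCR plate analysis model.

    Parameters
    ----------
    plate : PlateData
        Droplet amplitudes plus manifest (roles, groups, dilutions).
    config : RunConfig, optional
        Analysis constants (droplet volume, threshold k, QC minimum,
        exclusion regions, ...).
    """

    def __init__(self, plate: PlateData, config: RunConfig | None = None):
        self.plate = plate
        self.config = config or RunConfig()

    @classmethod
    def from_directory(cls, directory, config: RunConfig | None = None):
        from .io import load_plate

        return cls(load_plate(directory), config=config)

    # -- fitting ---------------------------------------------------------

    def fit(self) -> DropletPlateResults:
        cfg = self.config
        blanks = self.plate.wells_by_role("ntc", "clc")
        if not blanks:
            raise ValueError("no blank (ntc/clc) wells: cannot fit thresholds")
        thresholds = _classify.fit_thresholds(blanks, k_sd=cfg.threshold_k_sd)

        counts_by_well: dict[str, QuadrantCounts] = {}
        for well in self.plate.wells:
            counts_by_well[well.well_id] = _classify.classify_well(
                well, thresholds, cfg.exclusions
            )

        sample_counts = [
            counts_by_well[w.well_id]
            for w in self.plate.wells_by_role("sample", "dna_control")
        ]
        kept, dropped = _classify.qc_filter_wells(
            sample_counts, min_droplets=cfg.qc_min_droplets
        )
        if sample_counts and not kept:
            reasons = "; ".join(r for _, r in dropped)
            raise ValueError(f"all sample wells failed droplet QC: {reasons}")
        kept_ids = {c.well_id for c in kept}

        classifications = self._classification_table(counts_by_well, kept_ids,
                                                     thresholds)
        merged = self._merge_groups(kept)
        concentrations = self._concentration_table(merged)
        validation = self._validation_report(counts_by_well, merged,
                                             concentrations)
        return DropletPlateResults(
            model=self,
            thresholds=thresholds,
            classifications=classifications,
            concentrations=concentrations,
            validation=validation,
            dropped_wells=dropped,
            merged_counts=merged,
        )

    # -- pieces ----------------------------------------------------------

    def _classification_table(self, counts_by_well, kept_ids, thresholds):
        rows = []
        roles = dict(zip(self.plate.manifest["well"], self.plate.manifest["role"]))
        for wid, c in counts_by_well.items():
            rows.append(
                dict(
                    well=wid, role=roles.get(wid, ""), group=c.group_id,
                    n_total=c.n_total, n_dn=c.n_dn, n_ch1_only=c.n_ch1_only,
                    n_ch2_only=c.n_ch2_only, n_dp=c.n_dp,
                    n_excluded=c.n_excluded,
                    ch1_threshold=thresholds.ch1_threshold,
                    ch2_threshold=thresholds.ch2_threshold,
                    qc_pass=(wid in kept_ids) or roles.get(wid) in ("ntc", "clc"),
                )
            )
        return pd.DataFrame(rows)

    def _merge_groups(self, kept: list[QuadrantCounts]) -> dict[str, QuadrantCounts]:
        by_group: dict[str, list[QuadrantCounts]] = {}
        for c in kept:
            by_group.setdefault(c.group_id, []).append(c)
        return {g: _classify.merge_counts(cs) for g, cs in by_group.items()}

    def _concentration_table(self, merged) -> pd.DataFrame:
        cfg = self.config
        rows = []
        for group, counts in merged.items():
            ests: dict[str, _quantify.ConcentrationEstimate | None] = {}
            for channel in ("ch1", "ch2"):
                try:
                    ests[channel] = _quantify.concentration_from_counts(
                        counts, channel, cfg.droplet_volume_nl
                    )
                except _quantify.SaturationError:
                    logger.warning("group %s %s saturated", group, channel)
                    ests[channel] = None
            tpc = None
            if (
                ests["ch1"] is not None and ests["ch2"] is not None
                and ests["ch2"].concentration_per_ul > 0
            ):
                tpc = _quantify.targets_per_cell(
                    ests["ch1"], ests["ch2"],
                    ref_copies_per_cell=cfg.ref_copies_per_cell,
                    reaction_volume_ul=cfg.reaction_volume_ul,
                )
            for channel, est in ests.items():
                row = dict(group=group, channel="target" if channel == "ch1"
                           else "reference",
                           n_total=counts.n_total,
                           n_neg=counts.n_negative(channel))
                if est is None:
                    row.update(saturated=True, **{
                        "lambda": np.nan, "conc_per_ul": np.nan,
                        "ci_low": np.nan, "ci_high": np.nan,
                    })
                else:
                    row.update(
                        saturated=False,
                        **{
                            "lambda": est.lambda_,
                            "conc_per_ul": est.concentration_per_ul,
                            "ci_low": est.ci95[0], "ci_high": est.ci95[1],
                        },
                    )
                row["droplet_volume_nl"] = cfg.droplet_volume_nl
                if channel == "ch1" and tpc is not None:
                    row.update(
                        cells_per_reaction=tpc.cells_per_reaction,
                        copies_per_reaction=tpc.copies_per_reaction,
                        targets_per_cell=tpc.targets_per_cell,
                        tpc_ci_low=tpc.ci95[0], tpc_ci_high=tpc.ci95[1],
                    )
                rows.append(row)
        return pd.DataFrame(rows)

    def _validation_report(self, counts_by_well, merged, concentrations):
        cfg = self.config
        manifest = self.plate.manifest
        report = _validate.ValidationReport()
        have_anything = False

        # LOB from per-well blank target-channel concentrations
        blank_ids = manifest.loc[
            manifest["role"].isin(["ntc", "clc"]), "well"
        ].tolist()
        blank_concs = []
        for wid in blank_ids:
            c = counts_by_well.get(wid)
            if c is None or c.n_total == 0:
                continue
            n_neg = c.n_negative("ch1")
            if n_neg == 0:
                continue  # saturated blank: contamination, not a blank
            est = _quantify.to_concentration(
                n_neg, c.n_total, cfg.droplet_volume_nl
            )
            blank_concs.append(est.concentration_per_ul)
        if len(blank_concs) >= 2:
            report.lob = _validate.limit_of_blank(
                _validate.BlankPanel(tuple(blank_concs))
            )
            have_anything = True

        # dilution-series validation from sample groups
        samples = manifest[
            (manifest["role"] == "sample") & manifest["dilution"].notna()
        ]
        if not samples.empty and merged:
            level_values: dict[float, list[float]] = {}
            level_detect: dict[float, list[bool]] = {}
            for (dilution, group), _sub in samples.groupby(["dilution", "group"]):
                counts = merged.get(str(group))
                if counts is None:
                    continue
                detected = counts.n_ch1_positive >= 1
                level_detect.setdefault(float(dilution), []).append(detected)
                value = self._replicate_value(counts)
                if value is not None:
                    level_values.setdefault(float(dilution), []).append(value)

            usable = {
                lvl: vals
                for lvl, vals in level_values.items()
                if len(vals) >= 2 and float(np.mean(vals)) != 0.0
            }
            if usable:
                cv_table, mean_cv = _validate.repeatability_summary(
                    {f"level_{lvl:g}": vals
                     for lvl, vals in sorted(usable.items(), reverse=True)}
                )
                cv_table.insert(1, "dilution",
                                sorted(usable.keys(), reverse=True))
                report.cv_table = cv_table
                report.mean_cv_pct = mean_cv
                lowest = min(usable)
                report.lod = _validate.limit_of_detection(
                    report.lob if report.lob is not None else 0.0,
                    usable[lowest],
                )
                levels = [
                    (f"level_{lvl:g}", float(np.mean(vals)), vals)
                    for lvl, vals in sorted(usable.items(), reverse=True)
                ]
                label, mean_conc, cv = _validate.limit_of_quantification(
                    levels, cv_max_pct=cfg.cv_max_pct
                )
                report.loq_level = label
                if mean_conc is not None:
                    report.loq = mean_conc
                    report.loq_cv_pct = cv
                have_anything = True

            if level_detect:
                det = [
                    (int(sum(flags)), len(flags), lvl)
                    for lvl, flags in sorted(level_detect.items(), reverse=True)
                ]
                report.hit_rates, report.probit_fit = _validate.probit_hit_rate(det)
                have_anything = True

        if report.lob is not None and report.lod is None:
            report.notes.append("LOD/LOQ unavailable: no dilution-series wells")
        return report if have_anything else None

    def _replicate_value(self, counts: QuadrantCounts) -> float | None:
        """One replicate's value on the configured LOQ scale."""
        cfg = self.config
        try:
            target = _quantify.concentration_from_counts(
                counts, "ch1", cfg.droplet_volume_nl
            )
        except _quantify.SaturationError:
            return None
        if cfg.loq_scale == "copies_per_reaction":
            return target.concentration_per_ul * cfg.reaction_volume_ul
        try:
            ref = _quantify.concentration_from_counts(
                counts, "ch2", cfg.droplet_volume_nl
            )
        except _quantify.SaturationError:
            return None
        if ref.concentration_per_ul <= 0:
            return None
        return _quantify.targets_per_cell(
            target, ref,
            ref_copies_per_cell=cfg.ref_copies_per_cell,
            reaction_volume_ul=cfg.reaction_volume_ul,
        ).targets_per_cell


def run_pipeline(config: RunConfig, plate: PlateData) -> DropletPlateResults:
    """Functional entry point: fit the plate model under a run config."""
    return DropletPlateModel(plate, config).fit()
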
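"""File formats and run configuration.

The droplet-level interchange format is the amplitude CSV exported by
the instrument software: one row per droplet with ``Ch1 Amplitude`` and
``Ch2 Amplitude`` columns (extra columns, e.g. a ground-truth
``Cluster`` column from the simulator, are preserved as metadata).  A
plate manifest CSV maps well ids to roles, replicate groups and
dilution metadata.  Run parameters live in a flat TOML file.
"""

from __future__ import annotations

import hashlib
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import ExclusionRegion, VALID_ROLES, WellData
from .quantify import (
    DEFAULT_DROPLET_VOLUME_NL,
    DEFAULT_REACTION_VOLUME_UL,
    DEFAULT_REF_COPIES_PER_CELL,
)
from .validate import DEFAULT_CV_MAX_PCT

AMPLITUDE_COLUMNS = ("Ch1 Amplitude", "Ch2 Amplitude")
MANIFEST_COLUMNS = (
    "well", "sample_id", "role", "group", "dilution", "replicate",
    "cells_per_well",
)


@dataclass
class RunConfig:
    """All analysis constants in one auditable place."""

    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL
    threshold_k_sd: float = 7.0
    ref_copies_per_cell: float = DEFAULT_REF_COPIES_PER_CELL
    reaction_volume_ul: float = DEFAULT_REACTION_VOLUME_UL
    cv_max_pct: float = DEFAULT_CV_MAX_PCT
    qc_min_droplets: int = 10_000
    loq_scale: str = "targets_per_cell"  # or "copies_per_reaction"
    exclusions: list[ExclusionRegion] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("droplet_volume_nl", "threshold_k_sd",
                     "ref_copies_per_cell", "reaction_volume_ul",
                     "cv_max_pct"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.qc_min_droplets < 0:
            raise ValueError("qc_min_droplets must be >= 0")
        if self.loq_scale not in ("targets_per_cell", "copies_per_reaction"):
            raise ValueError("loq_scale must be 'targets_per_cell' or 'copies_per_reaction'")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        exclusions = [
            ExclusionRegion(
                ch1_range=tuple(e["ch1_range"]),
                ch2_range=tuple(e["ch2_range"]),
                reason=e.get("reason", ""),
            )
            for e in raw.pop("exclusions", [])
        ]
        return cls(exclusions=exclusions, **raw)

    def digest(self) -> str:
        """Short provenance hash of every config value."""
        payload = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class PlateData:
    """Wells plus manifest: the unit the pipeline operates on."""

    wells: list[WellData]
    manifest: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = set(self.manifest["well"])
        for w in self.wells:
            if w.well_id not in known:
                raise ValueError(f"well {w.well_id} has no manifest row")

    def wells_by_role(self, *roles: str) -> list[WellData]:
        return [w for w in self.wells if w.role in roles]


def read_amplitude_csv(
    path: str | Path,
    well_id: str | None = None,
    role: str = "sample",
    group_id: str = "",
) -> WellData:
    """Read a droplet amplitude CSV into a WellData.

    The header must contain ``Ch1 Amplitude`` and ``Ch2 Amplitude``;
    extra columns are kept in ``metadata['extra_columns']``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in AMPLITUDE_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    for col in AMPLITUDE_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(vals.isna().to_numpy() & df[col].notna().to_numpy())[0]
        if bad.size:
            raise ValueError(
                f"{path}: non-numeric amplitude in column {col!r} "
                f"at data row {bad[0] + 1}"
            )
        if vals.isna().any():
            row = int(np.nonzero(vals.isna().to_numpy())[0][0]) + 1
            raise ValueError(f"{path}: missing amplitude in {col!r} at data row {row}")
        df[col] = vals
    extra = {
        c: df[c].to_numpy() for c in df.columns if c not in AMPLITUDE_COLUMNS
    }
    return WellData(
        well_id=well_id if well_id is not None else path.stem,
        role=role,
        ch1=df["Ch1 Amplitude"].to_numpy(dtype=float),
        ch2=df["Ch2 Amplitude"].to_numpy(dtype=float),
        group_id=group_id,
        metadata={"source": str(path), "extra_columns": extra} if extra
        else {"source": str(path)},
    )


def write_amplitude_csv(
    well: WellData, path: str | Path, cluster: np.ndarray | None = None
) -> None:
    """Write a WellData as an amplitude CSV (optional ground-truth cluster).

    ``cluster`` codes the true quadrant 1–4 (double-negative, ch1-only,
    ch2-only, double-positive) when written by the simulator.
    """
    df = pd.DataFrame({
        "Ch1 Amplitude": well.ch1,
        "Ch2 Amplitude": well.ch2,
    })
    if cluster is not None:
        df["Cluster"] = np.asarray(cluster, dtype=int)
    df.to_csv(path, index=False)


def read_plate_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate the plate manifest CSV.

    Requires the columns ``well, sample_id, role, group, dilution,
    replicate, cells_per_well``; rejects duplicate well ids and unknown
    role tokens.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing manifest columns {missing}")
    dupes = df["well"][df["well"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate well ids {sorted(set(dupes))}")
    bad_roles = sorted(set(df["role"]) - set(VALID_ROLES))
    if bad_roles:
        raise ValueError(
            f"{path}: unknown role tokens {bad_roles}; allowed: {list(VALID_ROLES)}"
        )
    return df


def write_plate_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, index=False, columns=list(MANIFEST_COLUMNS))


def load_plate(directory: str | Path) -> PlateData:
    """Load a plate directory: ``manifest.csv`` plus ``<well>.csv`` files."""
    directory = Path(directory)
    manifest = read_plate_manifest(directory / "manifest.csv")
    wells = []
    for _, row in manifest.iterrows():
        well_path = directory / f"{row['well']}.csv"
        if not well_path.exists():
            raise FileNotFoundError(
                f"manifest references {row['well']} but {well_path} is missing"
            )
        wells.append(
            read_amplitude_csv(
                well_path, well_id=row["well"], role=row["role"],
                group_id=str(row["group"]),
            )
        )
    return PlateData(wells=wells, manifest=manifest,
                     provenance={"directory": str(directory)})


def save_plate(
    plate: PlateData, directory: str | Path,
    clusters: dict[str, np.ndarray] | None = None,
) -> None:
    """Write a plate as manifest.csv plus one amplitude CSV per well."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_plate_manifest(plate.manifest, directory / "manifest.csv")
    for well in plate.wells:
        cluster = clusters.get(well.well_id) if clusters else None
        write_amplitude_csv(well, directory / f"{well.well_id}.csv", cluster)
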
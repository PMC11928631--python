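import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from dropquant.io import PlateData
from dropquant.simulate import (
    SimConfig,
    simulate_blank_well,
    simulate_dilution_series,
)

# Printed intra-assay repeatability table: replicate TREC copies/reaction,
# their mean and CV% for eight samples run in triplicate.
TABLE1 = {
    "LD8": ([20.6694, 18.8806, 8.8278], 16.1259, 39.5843),
    "TD1": ([14.9900, 11.7225, 13.7664], 13.4930, 12.2348),
    "TD2": ([33.1795, 46.4623, 33.7355], 37.7924, 19.8809),
    "DPG4": ([109.7046, 78.9029, 114.8296], 101.1457, 19.2124),
    "Dil1": ([2.14933, 3.51072, 3.70429], 3.1214, 27.1485),
    "Dil2": ([3.687285, 2.287295, 1.714177], 2.5629, 39.6041),
    "Dil3": ([3.718888, 6.004963, 6.049773], 5.2579, 25.3523),
    "Dil4": ([4.626611, 3.227553, 3.434326], 3.7628, 20.0691),
}
TABLE1_GRAND_MEAN_CV = 25.38


@pytest.fixture(scope="session")
def base_config():
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def blank_wells(base_config):
    """Eight blank control wells (alternating NTC/CLC)."""
    wells = []
    for i in range(8):
        cfg = replace(base_config, seed=500 + i)
        wells.append(
            simulate_blank_well(
                cfg, well_id=f"B{i:02d}", role="ntc" if i % 2 == 0 else "clc"
            )
        )
    return wells


def make_dilution_plate(seed=21, n_droplets=12_000, replicates=3,
                        merge_wells=1, n_blanks=6,
                        levels=(0.016, 0.0016, 0.0006, 0.0003),
                        cells_per_well=2500.0):
    """Small synthetic plate: dilution series plus blank wells."""
    base = SimConfig(seed=seed, n_droplets_mean=n_droplets, n_droplets_sd=0.0)
    wells, manifest = simulate_dilution_series(
        base, list(levels), cells_per_well, replicates=replicates,
        merge_wells_per_replicate=merge_wells,
    )
    all_wells = [w for w, _ in wells]
    truths = {w.well_id: t for w, t in wells}
    rows = [manifest]
    for i in range(n_blanks):
        blank = simulate_blank_well(
            replace(base, seed=seed + 900 + i),
            well_id=f"B{i:02d}", role="ntc" if i % 2 == 0 else "clc",
        )
        blank.group_id = f"blank{i}"
        all_wells.append(blank)
        rows.append(pd.DataFrame([dict(
            well=blank.well_id, sample_id=f"blank{i}", role=blank.role,
            group=f"blank{i}", dilution=np.nan, replicate=1, cells_per_well=0,
        )]))
    plate = PlateData(wells=all_wells,
                      manifest=pd.concat(rows, ignore_index=True))
    return plate, truths


@pytest.fixture(scope="session")
def dilution_plate():
    return make_dilution_plate()
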
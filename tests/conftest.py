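import numpy as np
import pandas as pd
import pytest

import aridclines as ac


@pytest.fixture(scope="session")
def field_study():
    """Default-condition synthetic field study (table, truth)."""
    return ac.generate_field_study(ac.SyntheticConfig(), seed=101)


@pytest.fixture(scope="session")
def field_std(field_study):
    table, truth = field_study
    table = ac.relative_fitness(table)
    std = ac.transform_and_standardize(table, transform="none")
    return table, std, truth


@pytest.fixture()
def raw_plants():
    """Five plants with hand-computable raw measurements (the spreadsheet
    fixture used to pin down every derivation formula)."""
    return pd.DataFrame({
        "plant_id": ["a", "b", "c", "d", "e"],
        "experiment": ["field2019"] * 5,
        "population": ["P1", "P1", "P2", "P2", "P3"],
        "patch": ["p1", "p2", "p3", "p4", "p5"],
        "block": ["none"] * 5,
        "treatment": ["wet", "dry", "wet", "dry", "wet"],
        "leaf_count_wk0": [4, 6, 10, 2, 5],
        "leaf_count_wk8": [20, 14, 26, 10, 29],
        "fv_fm": [0.8, 0.7, 0.75, 0.72, 0.78],
        "photosynthesis": [12.0, 9.0, 11.0, 8.0, 10.0],
        "stomatal_conductance": [0.3, 0.2, 0.25, 0.15, 0.28],
        "leaf_area_cm2": [10.0, 8.0, 12.0, 6.0, 9.0],
        "leaf_fw_g": [2.0, 1.5, 3.0, 1.2, 2.5],
        "leaf_dw_g": [1.0, 0.5, 2.0, 0.4, 1.0],
        "shoot_dw_g": [5.0, 4.0, 8.0, 2.0, 6.0],
        "root_dw_g": [1.0, 2.0, 2.0, 1.0, 3.0],
        "days_to_flowering": [60, 55, 70, 50, 65],
        "chlorogenic_acid": [1.1, 2.0, 1.5, 2.5, 1.2],
        "phenolic_acid": [0.5, 0.9, 0.6, 1.1, 0.7],
        "flavonoid": [0.2, 0.4, 0.3, 0.5, 0.25],
        "seeds_per_gram": [50.0, 40.0, 60.0, 0.0, 33.3],
        "capitula_dw_g": [2.0, 1.0, 0.5, 0.0, 3.0],
    })
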
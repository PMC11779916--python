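import numpy as np
import pandas as pd
import pytest

import adaptkin as ak


@pytest.fixture(scope="session")
def age_params():
    return ak.default_age_params()


@pytest.fixture(scope="session")
def design():
    return ak.BlockDesign()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_features_df(values_by_subject, variable="movement_time_ms", age_group="adult"):
    """Hand-built tidy feature table: one variable carries the given
    per-trial values (trial 1..n), the others a constant."""
    rows = []
    design = ak.BlockDesign()
    for sid, values in values_by_subject.items():
        for trial, v in enumerate(values, start=1):
            row = {
                "subject_id": sid,
                "age_group": age_group if isinstance(age_group, str) else age_group[sid],
                "trial": trial,
                "block": design.block_of(trial),
                "peak_speed_mm_s": 300.0,
                "movement_time_ms": 1000.0,
                "movement_units": 1.0,
                "valid_peak_speed": True,
                "valid_movement_time": True,
                "valid_movement_units": True,
            }
            row[variable] = v
            rows.append(row)
    columns = [
        "subject_id", "age_group", "trial", "block",
        "peak_speed_mm_s", "movement_time_ms", "movement_units",
        "valid_peak_speed", "valid_movement_time", "valid_movement_units",
    ]
    return pd.DataFrame(rows, columns=columns)


@pytest.fixture(scope="session")
def noisefree_subject(age_params):
    """One noise-free adult subject (deterministic trial targets are still
    drawn from the subject's stream, but positions carry no sensor noise)."""
    return ak.generate_subject(age_params["adult"], seed=11, subject_id="nf_adult", noise_sd=0.0)


@pytest.fixture(scope="session")
def small_cohort(age_params):
    """3 x 4 subjects with default noise; shared across tests."""
    return ak.generate_cohort(seed=77, group_sizes={"1.5yo": 4, "3yo": 4, "adult": 4})


@pytest.fixture(scope="session")
def small_cohort_features(small_cohort):
    return ak.compute_features(small_cohort)
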
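import numpy as np
import pandas as pd
import pytest

from neoscreen import TrialDataset


def make_records(groups: dict[tuple[str, str, str], list[float]]) -> pd.DataFrame:
    """Build a records frame from {(experiment, litter, treatment): values}."""
    rows = []
    counter = 0
    for (exp, lit, trt), values in groups.items():
        for v in values:
            counter += 1
            rows.append(
                {
                    "animal_id": f"a{counter:03d}",
                    "experiment_id": exp,
                    "litter_id": lit,
                    "treatment": trt,
                    "sex": "male" if counter % 2 else "female",
                    "area_loss_pct": float(v),
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def small_dataset() -> TrialDataset:
    """Two experiments, two litters each, control + one treated arm."""
    df = make_records(
        {
            ("E1", "L1", "control"): [40, 42, 38, 45],
            ("E1", "L2", "control"): [41, 39, 43],
            ("E1", "L1", "drugA"): [30, 28, 33],
            ("E1", "L2", "drugA"): [25, 35, 31],
            ("E2", "L1", "control"): [44, 40, 37, 42],
            ("E2", "L2", "control"): [39, 46, 41],
            ("E2", "L1", "drugB"): [43, 39, 41],
            ("E2", "L2", "drugB"): [38, 44, 40],
        }
    )
    return TrialDataset(df)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
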
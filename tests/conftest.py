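import numpy as np
import pandas as pd
import pytest

from gmci.io import CountTable, SampleMetadata
from gmci.simulate import generate_cohort, scenario_presets


def make_count_table(matrix, sample_ids=None, species=None) -> CountTable:
    matrix = np.asarray(matrix)
    sample_ids = sample_ids or [f"s{i}" for i in range(matrix.shape[0])]
    species = species or [f"sp{j}" for j in range(matrix.shape[1])]
    return CountTable(pd.DataFrame(matrix, index=sample_ids, columns=species))


def make_metadata(records) -> SampleMetadata:
    """records: list of (sample_id, group, cohort, sex, age)."""
    df = pd.DataFrame(
        [{"sample_id": sid, "group": g, "cohort": c, "sex": s, "age": a,
          "timepoint": "pre"} for sid, g, c, s, a in records]
    ).set_index("sample_id")
    return SampleMetadata(df)


@pytest.fixture(scope="session")
def strong_cohort():
    """Strong planted dysbiosis, 40/40 samples: high-signal regime."""
    cfg = scenario_presets("strong_dysbiosis", seed=3)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """No planted effects, 20/20 samples: exchangeable groups."""
    cfg = scenario_presets("null", seed=0)
    return generate_cohort(cfg)
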
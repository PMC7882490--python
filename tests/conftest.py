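import numpy as np
import pandas as pd
import pytest

from riskbeliefs.survey_io import SurveyTable, default_codebook
from riskbeliefs.synthetic_data import GeneratorConfig, generate_survey


@pytest.fixture(scope="session")
def default_table() -> SurveyTable:
    """One two-wave synthetic survey at the default study conditions."""
    table, _ = generate_survey(GeneratorConfig(seed=7))
    return table


@pytest.fixture(scope="session")
def codebook():
    return default_codebook()


def minimal_rows(n: int, wave: int = 1) -> pd.DataFrame:
    """A small valid survey frame to mutate in I/O tests."""
    rng = np.random.default_rng(42)
    cb = default_codebook()
    df = pd.DataFrame(
        {
            "respondent_id": [f"r{i}" for i in range(n)],
            "wave": wave,
            "gender": rng.choice(["female", "male"], n),
            "age_category": rng.choice(["20-29", "50-59"], n),
            "region_tier": rng.choice(["lowest", "medium", "highest"], n),
            "weight": 1.0,
        }
    )
    for name, item in cb.items.items():
        if name not in df.columns:
            df[name] = np.nan
    return df[cb.columns]
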
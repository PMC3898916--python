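import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from amsnet.records import CSV_COLUMNS, LLS_COLUMNS, VAS_COLUMNS
from amsnet.synthetic import ArchetypeSpec, SimConfig, simulate_dataset


def make_record_frame(rows: list[dict]) -> pd.DataFrame:
    """Build a dialect-complete records table from partial row dicts."""
    defaults = {
        "subject_id": "S0001",
        "expedition": "longitudinal",
        "day": 1,
        "altitude_m": 5200.0,
        "treatment": "placebo",
        "sex": "male",
        "age_band": "22-25",
        **{c: 0.0 for c in VAS_COLUMNS},
        **{c: 0 for c in LLS_COLUMNS},
    }
    df = pd.DataFrame([{**defaults, **row} for row in rows])
    df["day"] = df["day"].astype("Int64")
    return df[list(CSV_COLUMNS)]


def small_sim_config(seed: int = 0, **overrides) -> SimConfig:
    """A scaled-down simulation (~320 records) for fast property tests."""
    kwargs = dict(n_subjects=80, days_per_subject=5, seed=seed,
                  expedition_split=0.5)
    kwargs.update(overrides)
    return SimConfig(**kwargs)


def low_severity_config(seed: int = 0) -> SimConfig:
    """Archetype weights favouring low-symptom profiles.

    With 80% diffuse low-severity background the total-score distribution is
    strongly right-skewed, the regime in which the square-root transform acts
    as a normalising map.
    """
    from amsnet.synthetic import default_archetypes

    arch = tuple(
        ArchetypeSpec(a.name, a.item_means, a.item_sd,
                      round(a.weight * 0.20 / 0.55, 3))
        for a in default_archetypes()
    )
    return SimConfig(seed=seed, archetypes=arch, background_fraction=0.8)


@pytest.fixture(scope="session")
def default_dataset() -> pd.DataFrame:
    """One full-size generated dataset, shared across tests."""
    return simulate_dataset(SimConfig(seed=0))


@pytest.fixture(scope="session")
def small_dataset() -> pd.DataFrame:
    return simulate_dataset(small_sim_config(seed=0))
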
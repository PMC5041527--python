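import numpy as np
import pandas as pd
import pytest

from ewas_screen import (
    QuestionDef,
    QuestionnaireSpec,
    SimConfig,
    StudyDataset,
    simulate_study,
)


@pytest.fixture(scope="session")
def small_spec() -> QuestionnaireSpec:
    return QuestionnaireSpec(
        (
            QuestionDef("bin_a", "binary", ("no", "yes")),
            QuestionDef("bin_rev", "binary", ("no", "yes"), orientation="reversed"),
            QuestionDef("ord3", "ordinal", ("never", "sometimes", "often")),
            QuestionDef(
                "ord5",
                "ordinal",
                ("never", "rarely", "sometimes", "often", "daily"),
            ),
        )
    )


@pytest.fixture()
def tiny_dataset(small_spec) -> StudyDataset:
    """Six participants: two full matched strata, one unmatched case, one
    orphan control."""
    participants = pd.DataFrame(
        {
            "participant_id": ["c1", "k1", "c2", "k2a", "k2b", "c3", "k9"],
            "status": ["case", "control", "case", "control", "control", "case",
                       "control"],
            "matched_set_id": ["s1", "s1", "s2", "s2", "s2", None, "s9"],
            "reference_age": [7.0, 7.0, 10.0, 10.0, 10.0, 4.0, 8.0],
            "delay": [2.0, np.nan, 3.0, np.nan, np.nan, 1.0, np.nan],
            "ses": [1, 1, 0, 0, 2, 1, 1],
            "urban_unit_index": [3, 3, 5, 5, 1, 2, 4],
            "pct_farmers": [0.05, 0.05, 0.0, 0.0, 0.3, 0.1, 0.02],
            "center_id": ["c1", "c1", "c2", "c2", "c2", "c1", "c1"],
            "attended_primary_school": [True, True, True, True, True, False,
                                        True],
        }
    )
    raw = pd.DataFrame(
        {
            "bin_a": ["yes", "no", "no", "no", "yes", "yes", None],
            "bin_rev": ["no", "yes", "yes", "no", "no", None, "yes"],
            "ord3": ["never", "often", "sometimes", "never", "often",
                     "sometimes", "never"],
            "ord5": ["daily", "never", "rarely", "often", "sometimes",
                     "never", "daily"],
        },
        index=participants["participant_id"].tolist(),
    )
    return StudyDataset(participants=participants, raw_responses=raw,
                        spec=small_spec)


@pytest.fixture(scope="session")
def null_study():
    """A medium null study shared across read-only tests."""
    config = SimConfig(
        n_cases=200,
        control_pattern=(0.0, 451.0, 241.0),
        n_variables=60,
        missing_rate=0.02,
        seed=42,
    )
    return simulate_study(config)
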
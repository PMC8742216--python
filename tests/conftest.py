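import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from akipredict.pipeline import frames_to_records, label_admissions  # noqa: E402
from akipredict.synthetic import SimConfig, generate_cohort  # noqa: E402


@pytest.fixture(scope="session")
def small_cohort():
    """A deterministic n=1000 synthetic cohort shared across tests."""
    config = SimConfig(n_admissions=1000, seed=11)
    admissions_df, labs_df, truth = generate_cohort(config)
    admissions, events = frames_to_records(admissions_df, labs_df)
    return {"config": config, "admissions_df": admissions_df,
            "labs_df": labs_df, "truth": truth,
            "admissions": admissions, "events": events}


@pytest.fixture(scope="session")
def small_cohort_labeled(small_cohort):
    episodes, first = label_admissions(small_cohort["admissions"],
                                       small_cohort["events"])
    return {**small_cohort, "episodes": episodes, "first": first}
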
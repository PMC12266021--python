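import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from inavarmeta import dataset

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_row(study="S1", exp="E1", **kwargs):
    """One valid experiment row with sensible defaults, as a dict."""
    row = {c: np.nan for c in dataset.COLUMNS}
    row.update(
        study_id=study, experiment_id=exp,
        mu_a=-40.0, sd_a=4.0, n_a=10,
        mu_i=-85.0, sd_i=3.6, n_i=12,
        cell_type="HEK", alpha_subunit="a", beta1="no",
        ljp_status="unreported",
    )
    row.update(kwargs)
    return row


def frame(rows):
    return pd.DataFrame(rows).reindex(columns=dataset.COLUMNS)


@pytest.fixture
def toy_frame():
    """Three valid experiments, two of which report both midpoints."""
    return frame([
        make_row("S1", "E1", mu_a=-42.0, mu_i=-86.0),
        make_row("S1", "E2", mu_a=-38.0, mu_i=-80.0, sd_a=np.nan, sem_a=1.2,
                 n_a=9),
        make_row("S2", "E1", mu_a=np.nan, sd_a=np.nan, n_a=np.nan,
                 mu_i=-90.0),
    ])


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (the study conditions), SDs resolved."""
    from inavarmeta import CohortConfig, generate_cohort, resolve_sd

    records, truth = generate_cohort(CohortConfig(seed=7))
    return resolve_sd(dataset.validate(records, strict=False)), truth
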
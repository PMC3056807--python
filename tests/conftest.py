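import numpy as np
import pandas as pd
import pytest

from mdicp.cohort import CohortConfig, simulate_cohort
from mdicp.preprocess import preprocess_cohort


@pytest.fixture(scope="session")
def small_records():
    """A small default-structure cohort shared across read-only tests."""
    cfg = CohortConfig(n_patients=12, hours_mean=40, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def aligned_small(small_records):
    return preprocess_cohort(small_records)


@pytest.fixture(scope="session")
def null_frame():
    """Coupling-free cohort: markers carry no pressure signal at any lag."""
    cfg = CohortConfig(n_patients=15, hours_mean=50, seed=21,
                       coupling_icp=0.0, coupling_cpp=0.0, missing_rate=0.0)
    return preprocess_cohort(simulate_cohort(cfg))


def make_panel(series_by_patient, extra_cols=None):
    """Build an aligned-frame-shaped DataFrame from {pid: {col: values}}."""
    frames = []
    for pid, cols in series_by_patient.items():
        n = len(next(iter(cols.values())))
        df = pd.DataFrame({c: np.asarray(v, dtype=float) for c, v in cols.items()})
        df["patient_id"] = pid
        df["location"] = "pericontusional"
        if "hour" not in df.columns:
            df["hour"] = np.arange(n)
        else:
            df["hour"] = df["hour"].astype(int)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    for c, v in (extra_cols or {}).items():
        out[c] = v
    return out
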
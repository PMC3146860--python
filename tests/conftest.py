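import datetime as dt

import numpy as np
import pytest

from accelpool import EpochSeries, SimConfig, generate_cohort


def mk_series(counts, start=dt.datetime(2004, 4, 5), epoch=60, **kw):
    kw.setdefault("serial_number", "TEST001")
    kw.setdefault("source_name", "testfile")
    return EpochSeries(
        epoch_length=epoch, start_datetime=start,
        counts=np.asarray(counts, dtype=np.int64), **kw)


@pytest.fixture(scope="session")
def clean_cohort():
    """Small artifact-free cohort shared across read-only tests."""
    return generate_cohort(SimConfig(seed=1234, n_participants=8))


@pytest.fixture(scope="session")
def mixed_cohort():
    """Cohort with every artifact kind injected at detectable presets."""
    return generate_cohort(SimConfig(
        seed=99, n_participants=25,
        artifact_rates={"temporal_shift": 0.12, "saturation_plateau": 0.08,
                        "no_baseline_return": 0.08},
    ))
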
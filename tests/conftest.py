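import numpy as np
import pandas as pd
import pytest

from lagddm.ddm import DDMParams, OptionPair, VARIANTS
from lagddm import design


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def option_pair():
    return OptionPair(ms1=15, mo1=5, ms2=8, mo2=12)


@pytest.fixture(scope="session")
def v2_params():
    return DDMParams(
        omega_s=0.08,
        omega_o=0.05,
        rst={"better": 0.5, "equal": 0.0, "worse": -0.5},
        threshold=1.0,
        ndt=0.3,
        bias=0.0,
    )


@pytest.fixture(scope="session")
def small_subject(v2_params):
    """One synthetic subject, 60 trials, generated once per session."""
    root = np.random.SeedSequence(777)
    d_rng, s_rng = (np.random.default_rng(s) for s in root.spawn(2))
    options = design.generate_option_set(60, d_rng)
    schedule = design._schedule_for_length(60, d_rng)
    recs = design.generate_synthetic_subject(
        v2_params, schedule, options, s_rng, subject_id="s0", variant=VARIANTS[2]
    )
    df = design.records_to_frame(recs)
    return df[~df["censored"]].reset_index(drop=True)
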
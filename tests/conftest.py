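import numpy as np
import pytest

from lfpgate import (
    SynthConfig, generate_session, build_streams, PreprocessConfig,
    make_windows, window_strengths, label_states, calibrate_threshold,
    DetectorConfig,
)


@pytest.fixture(scope="session")
def small_session():
    """A 60 s default-configuration synthetic session, shared read-only."""
    cfg = SynthConfig(duration_s=60.0, seed=1234)
    rec, events, truth = generate_session(cfg)
    return cfg, rec, events, truth


@pytest.fixture(scope="session")
def windowed_session(small_session):
    """Streams, windows, calibrated detector and labels for the session."""
    _, rec, events, truth = small_session
    hi, lo = build_streams(rec, PreprocessConfig())
    ds = make_windows(hi.codes, hi.fs, x_low=lo.codes, fs_low=lo.fs)
    det = DetectorConfig()
    strengths = window_strengths(ds, det)
    pre = label_states(ds, events, np.zeros(ds.n_windows, bool))
    vth = calibrate_threshold(strengths[pre == "S3"], det.q)
    labels = label_states(ds, events, strengths >= vth)
    return ds, events, det, strengths, vth, labels
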
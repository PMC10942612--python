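import warnings

import numpy as np
import pandas as pd
import pytest

import swimlab as sl


@pytest.fixture(scope="session")
def noiseless_spec() -> sl.SimSpec:
    return sl.SimSpec(noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def noiseless_trial(noiseless_spec):
    """One full noiseless ~40 h trial: (trace, truth record)."""
    return sl.simulate_trial(noiseless_spec)


@pytest.fixture(scope="session")
def noiseless_analysis(noiseless_spec, noiseless_trial):
    trace, _ = noiseless_trial
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sl.analyze_trial(
            trace,
            noiseless_spec.respirometer,
            noiseless_spec.subject,
            noiseless_spec.protocol.speed_plan,
        )


@pytest.fixture(scope="session")
def clean_track():
    """Single fish, no turns, no heading jitter: exact geometric baseline."""
    return sl.simulate_school_tracks(
        n_fish=1, speed_bls=1.0, ftb_hz=5.0, amplitude_m=0.012,
        heading_sd_deg=0.0, n_turns=0, duration_s=10.0, fps=125.0, seed=0,
    )


def make_linear_window(do_start=100.0, do_end=95.0, duration_s=660.0):
    """A sealed-phase window with a perfectly linear DO decline."""
    t = np.arange(0.0, duration_s + 1.0)
    do = do_start + (do_end - do_start) * t / duration_s
    return pd.DataFrame(
        {
            "time_s": t,
            "do_percent_sat": do,
            "temp_c": 28.0,
            "velocity_bls": 0.0,
            "phase": "rest",
        }
    )


def make_mo2_series(t_h, mo2, phase="recovery", speed=0.0):
    """Build an MO2Series DataFrame from explicit times (h) and rates."""
    t_h = np.asarray(t_h, float)
    mo2 = np.asarray(mo2, float)
    return pd.DataFrame(
        {
            "window_start_s": t_h * 3600.0,
            "window_end_s": t_h * 3600.0,
            "t_mid_s": t_h * 3600.0,
            "phase": phase,
            "speed_bls": speed,
            "mo2_mgO2_kg_h": mo2,
            "r2": 1.0,
            "flagged": False,
        }
    )
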
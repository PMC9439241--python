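import numpy as np
import pytest

import hrvdecay as hd


@pytest.fixture(scope="session")
def truths():
    """Three reproducible subject ground truths."""
    return hd.draw_cohort_truths(3, seed=11)


@pytest.fixture(scope="session")
def subject(truths):
    """One simulated graded exercise test at default noise."""
    tr = truths[0]
    proto = hd.make_protocol(exhaustion_power_w=tr.exhaustion_power)
    return hd.simulate_subject(proto, tr, seed=101)


@pytest.fixture(scope="session")
def noiseless_subject(truths):
    """Same subject with the HRV noise switched off (pure ODE trend)."""
    from dataclasses import replace

    tr = replace(truths[0], b_true=0.0)
    proto = hd.make_protocol(exhaustion_power_w=tr.exhaustion_power)
    return hd.simulate_subject(proto, tr, seed=101)


@pytest.fixture(scope="session")
def small_cohort():
    """Six-subject cohort without artifacts (fast shared fixture)."""
    return hd.simulate_cohort(6, seed=42, artifacts=None)


def decay_windows(b=1325.0, tau=19.6, hr=None, sigma=0.0, seed=0, phase="effort"):
    """Synthetic window table drawn directly from the decay law."""
    import pandas as pd

    if hr is None:
        hr = np.arange(60.0, 191.0, 5.0)
    hr = np.asarray(hr, dtype=float)
    rng = np.random.default_rng(seed)
    sdrr = b * 2.0 ** (-hr / tau) + rng.normal(0.0, sigma, hr.size)
    return pd.DataFrame({
        "j": np.arange(hr.size), "phase": phase,
        "t_start": 60.0 * np.arange(hr.size), "t_end": 60.0 * (np.arange(hr.size) + 1),
        "n_beats": 60, "sdrr_ms": sdrr, "hr_bpm": hr, "p_w": hr * 2.0 - 100.0,
        "i_pct": hr / 2.0,
    })
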
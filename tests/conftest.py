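import numpy as np
import pandas as pd
import pytest

from phaselink import synthetic as syn


@pytest.fixture(scope="session")
def small_schedule():
    sched = syn.generate_schedule(50, seed=11)
    sched.validate()
    return sched


@pytest.fixture(scope="session")
def clean_taps(small_schedule):
    """Noise-free tap stream: fixed 500 ms latency, no errors, no jitter."""
    params = syn.TapParams(fixed_latency_ms=500.0, tap_jitter_ms=0.0)
    return syn.generate_tap_stream(small_schedule, params, seed=7)


@pytest.fixture(scope="session")
def bank():
    from phaselink import spectral as spc
    return spc.design_bank()


def make_mediation_data(n=400, a1=0.5, b1=-0.4, a3=0.0, b2=0.0,
                        sigma=0.5, beta=0.0, seed=0, centered=True,
                        sigma1=None, sigma2=None):
    truth = syn.GroundTruth(
        coefficients=syn.MediationCoefficients(a1=a1, b1=b1, a3=a3, b2=b2,
                                               c1=0.2),
        n_young=n // 2, n_older=n - n // 2,
        sigma1=sigma if sigma1 is None else sigma1, beta1=beta,
        sigma2=sigma if sigma2 is None else sigma2, beta2=beta, seed=seed)
    df, truth = syn.generate_cohort(n // 2, n - n // 2, truth, seed=seed)
    if centered:
        for c in ("X", "W", "M"):
            df[c] = df[c] - df[c].mean()
    return df, truth
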
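import numpy as np
import pytest
from hypothesis import settings

from flimredox import BiExpParams, IRFModel, TimeAxis

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def axis() -> TimeAxis:
    return TimeAxis(n_bins=256, period=12.5)


@pytest.fixture(scope="session")
def irf() -> IRFModel:
    return IRFModel(shape="gaussian", center=1.0, fwhm=0.2)


@pytest.fixture(scope="session")
def delta_irf(axis) -> IRFModel:
    curve = np.zeros(axis.n_bins)
    curve[0] = 1.0
    return IRFModel(shape="measured", curve=curve)


@pytest.fixture(scope="session")
def truth_params() -> BiExpParams:
    # a1% = 0.7: 70% free NAD(P)H, 30% enzyme-bound
    return BiExpParams(a1=7000.0, a2=3000.0, tau1=0.4, tau2=2.5)


def brute_force_model(params, irf_curve, axis, n_periods=200):
    """Independent oracle: explicit multi-period sum + direct circular convolution."""
    t = axis.times
    decay = np.zeros(axis.n_bins)
    for p in range(n_periods):
        decay += params.a1 * np.exp(-(t + p * axis.period) / params.tau1)
        decay += params.a2 * np.exp(-(t + p * axis.period) / params.tau2)
    irf_curve = irf_curve / irf_curve.sum()
    out = np.zeros(axis.n_bins)
    for k in range(axis.n_bins):
        acc = 0.0
        for j in range(axis.n_bins):
            acc += irf_curve[j] * decay[(k - j) % axis.n_bins]
        out[k] = acc
    return out + params.background
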
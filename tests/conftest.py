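import numpy as np
import pytest

from magnetherm import calcium, thermometry


@pytest.fixture(scope="session")
def template():
    return calcium.default_template()


@pytest.fixture()
def flat_trace():
    t = np.arange(301) / 10.0
    return thermometry.FluorescenceTrace(time=t, intensity=np.full(301, 100.0))


def make_norm_trace(dff, fs=10.0, f0=1000.0):
    """Wrap a ΔF/F array (percent) in a NormalizedTrace on a uniform grid."""
    t = np.arange(len(dff)) / fs
    return thermometry.NormalizedTrace(time=t, dff=np.asarray(dff, float),
                                       baseline_F0=f0)
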
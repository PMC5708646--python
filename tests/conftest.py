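import numpy as np
import pytest

from blmchan import io, sim


@pytest.fixture(scope="session")
def toy_fixture():
    return sim.make_fixture("two_state_toy")


@pytest.fixture(scope="session")
def nachbac_fixture():
    return sim.make_fixture("nachbac_default")


@pytest.fixture()
def simple_trace():
    """1 s of zeros at 12.5 kHz, +35 mV command."""
    rate = 12500.0
    n = int(rate)
    return io.Trace(
        time=np.arange(n) / rate,
        current=np.zeros(n),
        voltage=np.full(n, 35.0),
        sample_rate=rate,
    )


def rect_pulse_trace(amplitude_pA=3.0, pulse_s=0.2, total_s=1.0, rate=12500.0,
                     voltage_mV=35.0):
    """Noiseless trace with one rectangular current pulse in the middle."""
    n = int(total_s * rate)
    cur = np.zeros(n)
    s = n // 2
    e = s + int(pulse_s * rate)
    cur[s:e] = amplitude_pA
    return io.Trace(
        time=np.arange(n) / rate,
        current=cur,
        voltage=np.full(n, voltage_mV),
        sample_rate=rate,
    )
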
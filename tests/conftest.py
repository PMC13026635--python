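import numpy as np
import pytest

from physio.synth import ParametricAPParams, PassiveCircuitParams, gen_parametric_ap
from physio.traceio import Sweep, SweepSet, VOLTAGE


@pytest.fixture
def canonical_ap():
    """The reference parametric AP: threshold -45, peak +15, rise 0.2 ms,
    fall 0.3 ms -> true halfwidth 0.25 ms."""
    return ParametricAPParams()


@pytest.fixture
def canonical_ap_sweep(canonical_ap):
    sweep, truth = gen_parametric_ap(canonical_ap, sample_rate=100.0)
    return sweep, truth


@pytest.fixture
def passive_params():
    """Noiseless biexponential transient parameters (A1=150 pA tau1=0.2 ms,
    A2=50 pA tau2=1.0 ms): closed-form C = 14.646 pF at -5 mV."""
    return PassiveCircuitParams(noise_sd=0.0, n_repetitions=3)


def flat_voltage_sweep(value=-76.0, n=2000, si=0.02, corrected=True):
    return Sweep(np.full(n, float(value)), si, kind=VOLTAGE,
                 stimulus={"onset_ms": n * si}, ljp_corrected=corrected)
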
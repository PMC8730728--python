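import numpy as np
import pytest

from confkin import KineticTrace, eval_1v1


@pytest.fixture
def make_trace():
    """Factory for noiseless 1:1 traces from the analytic curve."""

    def _make(
        kon=2e5,
        koff=5e-3,
        rmax=1.0,
        conc=1e-8,
        t_dis=600.0,
        t_end=1200.0,
        n=200,
        noise_sd=0.0,
        seed=None,
        **kwargs,
    ):
        times = np.linspace(0.0, t_end, n)
        signal = eval_1v1(kon, koff, rmax, conc, t_dis, times)
        if noise_sd > 0:
            rng = np.random.default_rng(seed)
            signal = signal + rng.normal(0.0, noise_sd, size=n)
        return KineticTrace(
            times=times, signal=signal, analyte_conc=conc, t_dis=t_dis, **kwargs
        )

    return _make
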
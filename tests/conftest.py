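import numpy as np
import pytest

from strokephys import PassiveModel, RunConfig, SpikingModel, StepDescriptor


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture
def passive_model():
    return PassiveModel(E_L=-70.0, R_in=150.0, tau_m=20.0, noise_sd=0.0)


@pytest.fixture
def spiking_model():
    return SpikingModel(
        E_L=-70.0,
        R_in=100.0,
        tau_m=20.0,
        noise_sd=0.0,
        V_T=-45.0,
        V_reset=-65.0,
        t_ref=3.0,
        ap_peak_amp=100.0,
        ap_rise_ms=0.4,
        ap_fall_ms=0.8,
    )


@pytest.fixture
def hyper_family():
    """The standard -25..-100 pA 1-s hyperpolarising step family."""
    return [StepDescriptor(0.0, a, 0.1, 1.0) for a in (-25.0, -50.0, -75.0, -100.0)]


def closed_form_passive(model, step, sweep):
    """Independent oracle: piecewise closed-form RC response on the sample grid.

    Sample n of the simulator holds V after n+1 exact exponential updates,
    i.e. the continuous-time solution at t = (n+1) dt with the current of
    each sample applied over its own interval.
    """
    n = sweep.n_samples
    dt = 1.0 / sweep.sampling_rate
    i = step.waveform(n, sweep.sampling_rate)
    tau_s = model.tau_m / 1000.0
    v = np.empty(n)
    v_prev = model.E_L
    for k in range(n):
        v_ss = model.E_L + i[k] * model.R_in / 1000.0
        v_prev = v_ss + (v_prev - v_ss) * np.exp(-dt / tau_s)
        v[k] = v_prev
    return v
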
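import numpy as np
import pytest

from denatkin.simulate import (DscSimSpec, KineticPeakSpec, RheoSimSpec,
                               default_dsc_spec, preexponential_for_peak,
                               synthesize_dsc, synthesize_rheo)

BETA = 5.0


def make_peak_spec(model="F1", E=2.0e5, T_peak_K=330.0, delta_H=10.0,
                   beta=BETA) -> KineticPeakSpec:
    """Stage spec with A placed so the rate maximum lands at T_peak_K."""
    A = preexponential_for_peak(model, E, T_peak_K, beta)
    return KineticPeakSpec(model=model, E=E, A=A, delta_H=delta_H)


def single_peak_sim(model="F1", E=2.0e5, T_peak_K=330.0, noise_sd=0.0,
                    seed=0, baseline=(0.0, 0.0), delta_H=10.0):
    """Noise-controlled single-stage thermogram around its rate maximum."""
    pk = make_peak_spec(model, E, T_peak_K, delta_H)
    Tc = T_peak_K - 273.15
    spec = DscSimSpec(peaks=(pk,), beta=BETA, T_start=Tc - 70, T_end=Tc + 70,
                      step=0.1, mass=15.0, baseline=baseline,
                      noise_sd=noise_sd, seed=seed)
    tg, truth = synthesize_dsc(spec)
    return spec, tg, truth


@pytest.fixture(scope="session")
def f1_peak_sim():
    return single_peak_sim("F1")


@pytest.fixture(scope="session")
def f2_peak_sim():
    return single_peak_sim("F2")


@pytest.fixture(scope="session")
def four_peak_noisy():
    """Default four-stage recipe with 1%-of-height Gaussian noise and a
    drifting baseline."""
    quiet = default_dsc_spec()
    _, truth0 = synthesize_dsc(quiet)
    noise_sd = 0.01 * float(np.max(truth0.noiseless))
    spec = default_dsc_spec(noise_sd=noise_sd, seed=7, baseline=(0.1, 0.002))
    tg, truth = synthesize_dsc(spec)
    return spec, tg, truth


@pytest.fixture(scope="session")
def default_rheo():
    spec = RheoSimSpec()
    sweep, truth = synthesize_rheo(spec)
    return spec, sweep, truth
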
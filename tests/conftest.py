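import numpy as np
import pytest

from physioecon import edasynth as es
from physioecon.pipeline import EpochSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_condition_epochs(
    mean_amp: float,
    n: int,
    rng: np.random.Generator,
    condition: str = "c",
    noise_sd: float = 0.05,
    sampling_rate: float = 125.0,
    epoch_length_s: float = 15.0,
    cv: float = 0.5,
    kernel: es.SCRKernelParams = es.SCRKernelParams(),
) -> EpochSet:
    """Event-locked epochs with a latency-shifted SCR of lognormal
    amplitude plus white noise — the shape the pipeline would extract
    from a synthetic trace."""
    n_samples = int(round(epoch_length_s * sampling_rate))
    h = es.phasic_signal(
        np.array([kernel.latency]),
        np.array([1.0]),
        kernel,
        n_samples,
        sampling_rate,
    )
    if cv > 0:
        sigma2 = np.log(1 + cv**2)
        amps = rng.lognormal(
            np.log(mean_amp) - sigma2 / 2, np.sqrt(sigma2), n
        )
    else:
        amps = np.full(n, mean_amp)
    data = amps[:, None] * h[None, :]
    if noise_sd > 0:
        data = data + rng.normal(0, noise_sd, data.shape)
    return EpochSet(condition, data, sampling_rate)
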
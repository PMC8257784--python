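import numpy as np
import pytest

from axonfid.synthetic_data import FrequencyFailureProfile, GeneratorConfig, gen_paired_recording, gen_soma_train


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def paired_recording():
    """A 60-s paired recording at control failure rate, fixed seed."""
    cfg = GeneratorConfig(seed=7)
    soma = gen_soma_train(cfg)
    return gen_paired_recording(soma, cfg)


def make_pair(times_s, axon_times_s, duration_s):
    """Hand-built paired recording from explicit spike times."""
    from axonfid.spike_metrics import PairedRecording, SpikeTrain

    return PairedRecording(
        soma=SpikeTrain("toy", "soma", np.asarray(times_s, float), duration_s),
        axon=SpikeTrain("toy", "axon", np.asarray(axon_times_s, float), duration_s),
    )
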
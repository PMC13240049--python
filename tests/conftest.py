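import numpy as np
import pytest

from asmconn.preprocess import ChannelInfo
from asmconn.synthetic import (
    CcepKernelSpec,
    RestSessionConfig,
    StimSessionConfig,
    gen_rest_session,
    gen_stim_session,
)


@pytest.fixture
def channels8():
    return [
        ChannelInfo(name=f"C{i + 1}", shaft="S", contact_index=i + 1, zone=z)
        for i, z in enumerate(["SOZ", "SOZ", "EPZ", "EPZ", "IZ", "IZ", "NIZ", "NIZ"])
    ]


@pytest.fixture
def small_stim(channels8):
    """One small stimulation session: 40 pulses, kernels on C3..C6."""
    kernels = {
        ("C1-C2", f"C{i}"): CcepKernelSpec(n1_amplitude_uv=100.0, n2_amplitude_uv=40.0)
        for i in (3, 4, 5, 6)
    }
    cfg = StimSessionConfig(
        channels=channels8,
        stim_pairs=["C1-C2"],
        kernels=kernels,
        pulses_per_train=40,
        fs_hz=1024.0,
        noise_sd_uv=5.0,
        seed=42,
    )
    rec, onsets, truth = gen_stim_session(cfg, "ASM-ON")
    return cfg, rec, onsets, truth


@pytest.fixture(scope="session")
def rest_pair_600s():
    """ON session with r=0.8 on channels (0,1); OFF session uncorrelated."""
    n_ch = 8
    target = np.eye(n_ch)
    target[0, 1] = target[1, 0] = 0.8
    on = gen_rest_session(
        RestSessionConfig(n_channels=n_ch, duration_s=600.0, fs_hz=500.0,
                          target_fc=target, modulation_depth=0.5, seed=101),
        "ASM-ON",
    )
    off = gen_rest_session(
        RestSessionConfig(n_channels=n_ch, duration_s=600.0, fs_hz=500.0,
                          modulation_depth=0.5, seed=202),
        "ASM-OFF",
    )
    return on, off
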
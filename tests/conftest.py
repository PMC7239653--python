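import numpy as np
import pytest

from odmap import imaging, synthetic


@pytest.fixture(scope="session")
def tiny_truth():
    """Noise-free 16x16 truth with ODI (2.5-1.3)/(2.5+1.3) ~ 0.3158."""
    return synthetic.ImagingTruth.uniform_disk(
        shape=(16, 16), radius=6, amp_contra=2.5e-4, amp_ipsi=1.3e-4,
        noise_sd=0.0, seed=7,
    )


@pytest.fixture(scope="session")
def tiny_session(tiny_truth):
    """Four noise-free stacks (25 s at 6 Hz, 0.12 Hz stimulus = 3 cycles)."""
    return synthetic.gen_session(
        tiny_truth, duration=25.0, frame_rate=6.0, stim_freq=0.12
    )


def cosine_stack(
    amp, freq=0.12, phase=0.0, duration=300.0, frame_rate=30.0,
    shape=(4, 4), eye="contra", direction=90.0,
):
    """Noise-free uniform cosine stack built independently of the generator."""
    t = np.arange(int(round(duration * frame_rate))) / frame_rate
    trace = 1.0 + amp * np.cos(2 * np.pi * freq * t + phase)
    frames = np.broadcast_to(
        trace[:, None, None], (len(t),) + tuple(shape)
    ).copy()
    return imaging.IntrinsicStack(
        frames=frames, frame_rate=frame_rate, stim_freq=freq,
        eye=eye, direction=direction,
    )
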
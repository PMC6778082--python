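import numpy as np
import pytest

from wormpheno import WormSimParams, render_clip


@pytest.fixture(scope="session")
def std_params() -> WormSimParams:
    """A mid-size moving worm in a compact chamber; shared across tests."""
    return WormSimParams(
        length_um=400.0,
        width_um=9.2,
        wave_amplitude=0.55,
        wave_freq_hz=1.0,
        speed_um_s=25.0,
        seed=7,
        chamber_px=512,
    )


@pytest.fixture(scope="session")
def std_clip(std_params):
    """Rendered clip + ground truth for std_params (session-cached)."""
    return render_clip(std_params)


@pytest.fixture(scope="session")
def std_record(std_clip):
    from wormpheno import analyze_clip

    clip, _truth = std_clip
    return analyze_clip(clip)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
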
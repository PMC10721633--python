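import numpy as np
import pytest

from spotdrop import IntensityTrace, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A fast, small-field simulation for structural tests."""
    return SimulationConfig(
        field_shape=(96, 96),
        n_spots=6,
        min_spacing=10 * 0.16,   # 10 px
        n_frames=30,
        drop_probability=0.5,
        seed=42,
    )


def make_trace(normalized, spot_id=0, frame_valid=None, usable=True):
    """Wrap a normalized array into an IntensityTrace with unit initial intensity."""
    normalized = np.asarray(normalized, dtype=float)
    return IntensityTrace(
        spot_id=spot_id,
        raw=normalized.copy(),
        normalized=normalized if usable else None,
        initial_intensity=1.0,
        n_initial_frames=5,
        frame_valid=(
            np.ones(len(normalized), dtype=bool) if frame_valid is None
            else np.asarray(frame_valid, dtype=bool)
        ),
        usable=usable,
    )
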
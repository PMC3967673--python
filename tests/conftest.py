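import numpy as np
import pytest

from gimotion.core import SeedContour
from gimotion.phantom import DuodenumSpec, FundusSpec, RespirationSpec


def circle_seed(n=20, radius=50.0, center=(80.0, 80.0), frame_index=0,
                label="fundus", clockwise=False, phase=0.0):
    """Seed polygon on a circle; counterclockwise unless requested."""
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False) + phase
    if clockwise:
        theta = theta[::-1]
    pts = np.column_stack([center[0] + radius * np.cos(theta),
                           center[1] + radius * np.sin(theta)])
    return SeedContour(points=pts, frame_index=frame_index, structure_label=label)


@pytest.fixture
def quiet_fundus_spec():
    """Fundus phantom with no respiration and no noise; oscillation spans
    exactly two periods of the 40-frame acquisition."""
    return FundusSpec(
        oscillation_amplitude=0.05,
        oscillation_period_s=40 * 0.656 / 2.0,
        respiration=RespirationSpec(amplitude_px=0.0),
        noise_sigma=0.0,
        seed=11,
    )


@pytest.fixture
def quiet_duodenum_spec():
    return DuodenumSpec(
        respiration=RespirationSpec(amplitude_px=0.0),
        noise_sigma=0.0,
        seed=13,
    )
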
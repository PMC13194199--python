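import numpy as np
import pytest

from platequant.plate import PlateLayout, PrepChain, Role, WellSpec
from platequant.simulate import (
    NOISELESS,
    ColourModel,
    NoiseModel,
    calibration_design_layout,
    demo_plate_layout,
    render_plate,
)


@pytest.fixture(scope="session")
def colour():
    return ColourModel()


@pytest.fixture(scope="session")
def calibration_layout():
    return calibration_design_layout()


@pytest.fixture(scope="session")
def demo_layout():
    return demo_plate_layout()


@pytest.fixture(scope="session")
def noiseless_plate(calibration_layout, colour):
    """Noise-free equilibrium render of the blank + 8x3 standards design."""
    return render_plate(calibration_layout, colour, NOISELESS)


@pytest.fixture
def tiny_layout():
    """1x3 plate: blank, one standard, one sample."""
    return PlateLayout(
        n_rows=1,
        n_cols=3,
        roi_radius=5,
        wells=[
            WellSpec(0, 0, Role.BLANK, 0.0, "blk"),
            WellSpec(0, 1, Role.STANDARD, 0.04, "s1"),
            WellSpec(
                0, 2, Role.SAMPLE, 0.08, "smp",
                prep=PrepChain(dilution=100, aliquot_ul=320, total_ul=400),
            ),
        ],
        grid={"origin_x": 15.0, "origin_y": 15.0, "pitch_x": 25.0, "pitch_y": 25.0},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
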
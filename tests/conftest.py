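import numpy as np
import pytest

from bladeopt.curves import OperatingPoint
from bladeopt.geometry import BladeDesign, PumpConstants
from bladeopt.pipeline import PipelineConfig, run_baseline
from bladeopt.virtual_pump import LossCoefficients


@pytest.fixture(scope="session")
def constants():
    return PumpConstants()


@pytest.fixture(scope="session")
def losses():
    return LossCoefficients()


@pytest.fixture(scope="session")
def target_op():
    return OperatingPoint(2.0, 70.0, label="OP_2L/min")


@pytest.fixture(scope="session")
def mid_design():
    """Centre of the iteration-0 box."""
    return BladeDesign(32.5, 82.5, 32.5, 11.5, 11.5, design_id="mid")


@pytest.fixture(scope="session")
def pipeline_config():
    return PipelineConfig(master_seed=1)


@pytest.fixture(scope="session")
def baseline(pipeline_config):
    """The 32-design factorial survey, simulated and scaled once per session."""
    return run_baseline(pipeline_config)
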
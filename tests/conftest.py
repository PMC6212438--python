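import numpy as np
import pytest
from hypothesis import settings

from orpanel import synth, traceproc

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def affinity():
    return synth.acetophenone_analog_affinities()


@pytest.fixture(scope="session")
def design_1e2():
    return synth.analog_panel_design(dilutions=(1e-2,))


@pytest.fixture(scope="session")
def run_pair(design_1e2, affinity):
    """Two full-panel sessions on distinct days with default noise."""
    r1 = synth.simulate_plate_run(design_1e2, affinity, seed=11, run_id="r1", day="D1")
    r2 = synth.simulate_plate_run(design_1e2, affinity, seed=12, run_id="r2", day="D2")
    return r1, r2


@pytest.fixture(scope="session")
def matrix_pair(run_pair):
    r1, r2 = run_pair
    return (traceproc.build_response_matrix(r1), traceproc.build_response_matrix(r2))


@pytest.fixture(scope="session")
def zero_noise_run(design_1e2, affinity):
    return synth.simulate_plate_run(
        design_1e2, affinity, noise=synth.NoiseParams.zero(), seed=5,
        run_id="zn", day="D0",
    )


def make_trace(values, or_id="OR1", odorant="AC", phase="vapor", conc=1e-2,
               replicate=1, well="W1", interval=90.0):
    from orpanel.core import Condition, LuminescenceTrace
    return LuminescenceTrace(
        well_id=well, or_id=or_id,
        condition=Condition(odorant, phase, conc),
        replicate=replicate, values=np.asarray(values, float),
        cycle_interval_s=interval,
    )
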
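import numpy as np
import pytest

from purinesim.engine import ModelParams, Protocol, ReceptorExpression, run


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def rest_run(params):
    return run(Protocol(dose_uM=0.0, horizon_s=600.0), params)


@pytest.fixture(scope="session")
def wt50_run(params):
    """50 uM ATP, 5 min, wild type — the pAkt reference protocol."""
    return run(Protocol(dose_uM=50.0, horizon_s=300.0), params)


@pytest.fixture(scope="session")
def mm_x7ko_run(params):
    """1 mM ATP, 10 min, P2X7-null, CD39 on — the 180 nM calibration run."""
    return run(
        Protocol(dose_uM=1000.0, horizon_s=600.0,
                 expression=ReceptorExpression(1, 0, 1, 1)),
        params,
    )


@pytest.fixture(scope="session")
def mm_nocd39_run(params):
    """1 mM ATP, 10 min, CD39 knocked out — persistent oscillation regime."""
    return run(Protocol(dose_uM=1000.0, horizon_s=600.0, cd39_multiplier=0.0), params)


@pytest.fixture(scope="session")
def target_values(params):
    from purinesim.presets import compute_targets

    return compute_targets(params)
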
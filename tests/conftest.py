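import io

import pytest

from ipmrisk import (SimulationConfig, make_insilico_study, table1_fixture)


@pytest.fixture(scope="session")
def table1_ra():
    return table1_fixture()


@pytest.fixture(scope="session")
def insilico_ra():
    return make_insilico_study()


@pytest.fixture
def fast_config():
    """Small but non-trivial Monte Carlo for unit tests."""
    return SimulationConfig(n_cycles=2000, seed=7)


TABLE1_CSV = """\
uo,pp,judged_lower,judged_upper,setpoint,severity,occurrence,detectability,critical_delta_cqa_pct
UO-1,PP1,6,8,7,4,3,2,
UO-1,PP2,30,70,50,3,4,2,10
UO-2,PP1,6.8,7.6,7.2,5,2,2,
UO-2,PP2,32,38,35,2,4,4,10
"""


@pytest.fixture
def table1_csv():
    """The worked-example RA in the CSV dialect, delta once per UO block."""
    return io.StringIO(TABLE1_CSV)
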
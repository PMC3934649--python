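import io

import numpy as np
import pytest

from brachyeval import read_differential_dvh

# the published export-dialect sample: 15 rows of (dose cGy, cm³/cGy)
TABLE_DVH_TSV = """Differential dose volume graph coordinates
Dose (cGy)\tVolume/dose (cm3/cGy)
18.000\t0.000
30.000\t0.002
42.000\t0.052
54.000\t0.180
66.000\t0.244
78.000\t0.210
90.000\t0.164
102.000\t0.121
114.000\t0.100
126.000\t0.086
138.000\t0.086
150.000\t0.110
162.000\t0.136
174.000\t0.148
186.000\t0.141
"""

# hand-summed density column (independent of the parser): 1.780 cm³/cGy
TABLE_DVH_DENSITY_SUM = 1.780


@pytest.fixture
def table_dvh():
    return read_differential_dvh(io.StringIO(TABLE_DVH_TSV), "rectum")


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
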
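import numpy as np
import pytest

from mnasetools import gel, templates
from mnasetools.genome import GenomeSizes

# log-linear mobility shared by the gel fixtures: d = 160 - 20 ln(size)
MOBILITY = (160.0, 20.0)


@pytest.fixture
def fig1_template():
    return templates.figure1_template()


@pytest.fixture
def toy_nuc_template():
    """300-bp template with one centered 147-bp nucleosome."""
    return templates.build_template(300, [(76, 147)])


@pytest.fixture
def ladder():
    a, b = MOBILITY
    return gel.calibrate_ladder({s: a - b * np.log(s) for s in range(100, 1100, 100)})


@pytest.fixture
def small_genome():
    return GenomeSizes([("chrI", 100_000), ("chrII", 60_000)])
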
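import numpy as np
import pytest

from hpbody.polya import CELLS


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def polya_design():
    """Sample -> (genotype, condition) map for four replicates per cell."""
    design = {}
    for genotype, condition in CELLS:
        for rep in range(1, 5):
            design[f"{genotype}_{condition}_r{rep}"] = (genotype, condition)
    return design
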
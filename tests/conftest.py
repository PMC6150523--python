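import numpy as np
import pytest

from cytonuclear.genotype_core import Genotype, ModelParams

GENOTYPE_CODES = [
    m + s1 + s2 + a1 + a2
    for m in "af"
    for s1 in "AF"
    for s2 in "AF"
    for a1 in "Mm"
    for a2 in "Mm"
]


@pytest.fixture
def rng():
    return np.random.default_rng(20180925)


@pytest.fixture
def default_params():
    return ModelParams()


def G(code: str) -> Genotype:
    return Genotype.from_string(code)
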
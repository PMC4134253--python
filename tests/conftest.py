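import numpy as np
import pytest

from parkviable import LifeHistoryScenario
from parkviable.synth import sceaux_frequencies


@pytest.fixture(scope="session")
def sceaux_freqs():
    """Allele spectra matched to the published per-locus diversities."""
    return sceaux_frequencies()


@pytest.fixture
def scenario_factory():
    def make(afl=1, sj=0.5, breed=0.5, **kw):
        return LifeHistoryScenario(
            age_first_litter_f=afl,
            juvenile_survival=sj,
            prop_females_breeding=breed,
            **kw,
        )

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
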
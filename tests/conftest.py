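import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from altloci.synth import SimSpec, generate_region_pair


@pytest.fixture(scope="session")
def default_region():
    """One synthetic region under the generator defaults (all small events)."""
    return generate_region_pair(SimSpec(rng_seed=11))


@pytest.fixture(scope="session")
def sv_region():
    """A synthetic region that also carries one structural-variant indel."""
    return generate_region_pair(SimSpec(rng_seed=23, n_sv=1))
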
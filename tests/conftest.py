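import warnings

import pytest

from glycograft.fixtures import make_specificity_pocket
from glycograft.structure import assign_vdw_radii

# rotamer builds occasionally warn about tight intra-model contacts; tests
# assert on scores, not warnings
warnings.filterwarnings("ignore", message="intra-model heavy-atom distance")


@pytest.fixture(scope="session")
def specificity_pocket():
    """The canyon pocket engineered around the TF determinant (shared)."""
    pocket, selection = make_specificity_pocket(seed=0)
    assign_vdw_radii(pocket)
    return pocket, selection


@pytest.fixture(scope="session")
def std_scenario():
    from glycograft.fixtures import make_std_scenario

    return make_std_scenario(seed=0)
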
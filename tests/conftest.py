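import numpy as np
import pytest

from agroecosim import EconParams, LandUseGrid
from agroecosim.economics import CROP_UNTREATED, NCH


@pytest.fixture
def econ() -> EconParams:
    return EconParams()


def uniform_landuse(n: int, option: int, econ: EconParams) -> LandUseGrid:
    """Landscape-wide single land-use option with zero fertiliser."""
    opts = np.full((n, n), option, dtype=int)
    return LandUseGrid.from_options(opts, np.zeros((n, n)), econ)
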
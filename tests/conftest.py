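import numpy as np
import pytest

from sarcotomo.specs import BindingSpec, HelixSpec, LatticeSpec, ZdiscSpec
from sarcotomo.synth import build_aband_model, build_zdisc


@pytest.fixture(scope="session")
def aband_model():
    """Default A-band model: 4x4 thick lattice, 18 thin filaments, seed 1."""
    m = build_aband_model(seed=1)
    m.validate()
    return m


@pytest.fixture(scope="session")
def aband30():
    """30-thin-filament A-band at default binding parameters, seed 1."""
    m = build_aband_model(LatticeSpec(n_rows=5, n_cols=5), seed=1, n_thin=30)
    m.validate()
    return m


@pytest.fixture(scope="session")
def zdisc_thin_form():
    """Thin-form Z-disc (~128 deg actinin angle) with all-doublet links."""
    lat = LatticeSpec(n_rows=2, n_cols=6, band="Z", axis_length=150)
    return build_zdisc(ZdiscSpec(actinin_angle=128.0, doublet_prob=1.0),
                       lat, seed=5)


@pytest.fixture(scope="session")
def zdisc_pair():
    """Thin- and thick-form Z-discs for hinge comparisons."""
    lat = LatticeSpec(n_rows=2, n_cols=6, band="Z", axis_length=150)
    return [build_zdisc(ZdiscSpec(actinin_angle=a, doublet_prob=0.5),
                        lat, seed=5 + i)
            for i, a in enumerate((128.0, 158.0))]
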
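import numpy as np
import pytest

from hingekit.fixtures import RepeatSpec, build_repeat_protein, helix_segments_from_meta
from hingekit.geometry import HingeSpec, assemble_states
from hingekit.kinetics import RateConstants
from hingekit.structure import fit_helix_axis


@pytest.fixture(scope="session")
def default_scaffold():
    """Default 4-repeat (8-helix) synthetic scaffold with metadata."""
    return build_repeat_protein(RepeatSpec())


@pytest.fixture(scope="session")
def hinge_scaffold():
    """Scaffold with 24-residue helices: long enough lever arms for
    tens-of-angstrom label-site motions."""
    return build_repeat_protein(RepeatSpec(helix_len=24))


@pytest.fixture(scope="session")
def hinge_states(hinge_scaffold):
    """Canonical gate-passing hinge: pivot helix 4, register shift +6."""
    structure, meta = hinge_scaffold
    helices = [fit_helix_axis(structure, h)
               for h in helix_segments_from_meta(meta)]
    return assemble_states(structure, HingeSpec(4, 6), helices)


@pytest.fixture(scope="session")
def base_rates():
    """Hinge with F_Y = 0.5%: k_on = 5e3 M^-1 s^-1, K_D,app = 2 uM."""
    return RateConstants(k1=10.0, k_m1=1990.0, k2=1e6, k_m2=0.01)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
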
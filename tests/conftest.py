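import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from nmrdyn.constants import FieldParams
from nmrdyn.types import Conformation

settings.register_profile(
    "suite",
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def field():
    return FieldParams()


def build_conformation(n_res=10, seed=0, spread=5.0):
    """A random peptide-like conformation with N/H/CA/C atoms per residue."""
    rng = np.random.default_rng(seed)
    res_index, res_aa, names, elems, coords = [], [], [], [], []
    for i in range(1, n_res + 1):
        base = rng.normal(size=3) * spread
        offsets = {
            "N": ("N", np.zeros(3)),
            "H": ("H", rng.normal(size=3)),
            "CA": ("C", rng.normal(size=3)),
            "C": ("C", rng.normal(size=3)),
        }
        for nm, (el, off) in offsets.items():
            res_index.append(i)
            res_aa.append("A")
            names.append(nm)
            elems.append(el)
            coords.append(base + off)
    return Conformation(res_index, res_aa, names, elems, np.array(coords))


@pytest.fixture
def random_conf():
    return build_conformation()
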
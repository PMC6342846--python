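import pytest
import sympy as sp

from algmle.group_fourier import Z2, FiniteAbelianGroup, LabelingFunction
from algmle.model_param import RootedTree


@pytest.fixture(scope="session")
def group():
    return Z2


@pytest.fixture(scope="session")
def labeling(group):
    return LabelingFunction.identity_labeling(group)


@pytest.fixture(scope="session")
def tripod():
    return RootedTree.tripod()


@pytest.fixture(scope="session")
def rerooted_tripod(tripod):
    return tripod.rerooted()


def random_interior_fchecks(rng, rerooted=True):
    """Random rational Fourier edge parameters strictly inside (0, 1)."""
    names = (["root"] if rerooted else []) + ["e1", "e2", "e3"]
    out = {}
    for name in names:
        num = int(rng.integers(1, 99))
        out[name] = [sp.Integer(1), sp.Rational(num, 100)]
    return out
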
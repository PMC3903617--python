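import numpy as np
import pytest

from affimut.energy import ForceFieldParams, parameterize
from affimut.mutate import RotamerLibrary
from affimut.synth import ToyComplexSpec, make_toy_complex


@pytest.fixture(scope="session")
def library():
    return RotamerLibrary.default()


@pytest.fixture(scope="session")
def ff_params():
    return ForceFieldParams.default()


@pytest.fixture(scope="session")
def toy_complex(library, ff_params):
    """Small parameterized two-helix complex with a planted Ser/Glu pair."""
    spec = ToyComplexSpec(seq_a="ASASSASA", seq_b="ASAEASA",
                          separation=9.0, planted=(5, 4, 8.5), seed=0)
    return make_toy_complex(spec, library=library, params=ff_params)


def random_point_complex(rng, n_a=20, n_b=20, spread=8.0, offset=10.0):
    """A random parameterized 'complex' of two glycine-backbone chains.

    Atoms get random positions and random nonbonded parameters; used for
    brute-force energy oracles where chemistry does not matter.
    """
    from affimut.structure import Atom, ComplexStructure, Residue

    def chain(cid, n, shift):
        residues = []
        names = ["N", "CA", "C", "O"]
        for i in range(0, n, 4):
            res = Residue("GLY", cid, i // 4 + 1)
            for j in range(min(4, n - i)):
                pos = rng.uniform(-spread / 2, spread / 2, 3) + shift
                a = Atom(names[j], "C" if j in (1, 2) else "NO"[j > 0],
                         pos)
                a.charge = rng.uniform(-0.5, 0.5)
                a.lj_rmin = rng.uniform(1.5, 2.0)
                a.lj_eps = rng.uniform(0.05, 0.25)
                a.radius = 1.7
                res.atoms.append(a)
            residues.append(res)
        return residues

    return ComplexStructure(
        {"A": chain("A", n_a, np.zeros(3)),
         "B": chain("B", n_b, np.array([0.0, 0.0, offset]))},
        {"A": "A", "B": "B"},
    )
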
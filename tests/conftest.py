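import numpy as np
import pytest
from hypothesis import settings

from herbnet.chem import Atom, Molecule

settings.register_profile("stable", derandomize=True, deadline=None)
settings.load_profile("stable")


def random_molecule(rng: np.random.Generator, n_atoms: int, mol_id: str = "m",
                    scale: float = 1.5, element: str = "C") -> Molecule:
    """Loose random atom cloud for shape tests (no spacing constraint)."""
    pts = rng.normal(scale=scale, size=(n_atoms, 3))
    from herbnet.chem import vdw_radius
    return Molecule(mol_id, [Atom(element, p, vdw_radius(element)) for p in pts])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_molecule(rng):
    return random_molecule(rng, 8, "toy")
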
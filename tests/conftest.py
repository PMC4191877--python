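import numpy as np
import pytest

from memphase.core import Box, CompositionSpec, MembraneFrame
from memphase.synthetic import SyntheticSpec, generate_striped_membrane, striped_trajectory

#: Equal-thickness variant used wherever an analytic mixing limit is asserted:
#: the 0.61 / 0.39 / 0.5 reference values treat the two phospholipids as
#: geometrically interchangeable, which requires a single bilayer thickness.
EQUAL_THICKNESS = {"Lo": 4.0, "Ld": 4.0}


def po4_frame(coords, species, box=(10.0, 10.0, 10.0)):
    """Hand-built frame of single-bead PO4 'molecules' for toy contact tests."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return MembraneFrame(
        positions=coords,
        species=np.asarray(species),
        bead_names=np.array(["PO4"] * n),
        molecule_index=np.arange(n),
        box=Box(np.asarray(box)),
    )


@pytest.fixture(scope="session")
def striped_frame():
    """Default-composition striped membrane at lambda = 0 with 64 solutes."""
    spec = SyntheticSpec(seed=42, composition=CompositionSpec(n_solute=64))
    return generate_striped_membrane(spec)


@pytest.fixture(scope="session")
def separated_frame():
    """Fully phase-separated membrane: inter-stripe gap wider than 1.1 nm."""
    spec = SyntheticSpec(seed=42, interphase_buffer=1.2)
    return generate_striped_membrane(spec)


@pytest.fixture(scope="session")
def striped_traj():
    """Short stationary trajectory of the default striped membrane."""
    spec = SyntheticSpec(seed=7, composition=CompositionSpec(n_solute=64))
    return striped_trajectory(spec, 4)
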
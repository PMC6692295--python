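import numpy as np
import pytest

from filadyn.filament import HelicalParams, build_filament
from filadyn.structures import ProtomerStructure
from filadyn.synth import SyntheticConfig, make_protomer


@pytest.fixture(scope="session")
def default_protomer():
    return make_protomer(SyntheticConfig())


@pytest.fixture(scope="session")
def default_filament(default_protomer):
    return build_filament(default_protomer, HelicalParams(rise=10.0, twist=85.0), 30)


@pytest.fixture(scope="session")
def filament_modes(default_filament):
    """Modes of the 30-subunit filament (shared: the expensive fixture)."""
    from filadyn import anm

    H = anm.build_hessian(default_filament.all_coords())
    modes = anm.compute_modes(H, n_modes=12)
    anm.attach_topology(modes, default_filament)
    return modes


@pytest.fixture
def toy_protomer():
    """Small 10-residue zig-zag chain."""
    rng = np.random.default_rng(42)
    coords = np.cumsum(rng.normal(0, 1, (10, 3)), axis=0) + np.arange(10)[:, None] * [0, 0, 3.0]
    return ProtomerStructure(
        residue_ids=np.arange(1, 11),
        sequence="ACDEFGHIKL",
        ca_coords=coords,
    )


def random_rotation(seed=0):
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
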
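import numpy as np
import pytest

from poreflux import ChannelGeometry, SingleFileModelSpec, simulate_single_file


@pytest.fixture(scope="session")
def default_geom():
    return ChannelGeometry(z_lumen=(-0.7, 0.7), n_monomers=1)


@pytest.fixture(scope="session")
def hopping_traj():
    """A stock hopping trajectory shared across tests (moderate length)."""
    spec = SingleFileModelSpec(duration=100.0, seed=42)
    return spec, simulate_single_file(spec)


@pytest.fixture(scope="session")
def brownian_traj():
    """A stock Brownian single-file trajectory with dipoles."""
    from poreflux import reorienting_dipole_field

    spec = SingleFileModelSpec(
        variant="brownian",
        duration=60.0,
        timestep=0.005,
        diffusion=0.5,
        buffer_mean=0.41,
        seed=7,
        dipole_kappa=reorienting_dipole_field(),
    )
    return spec, simulate_single_file(spec)
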
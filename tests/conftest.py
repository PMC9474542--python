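import numpy as np
import pytest

from fibrilsite import (HoppingSpec, anle138b_topology, build_toy_fibril,
                        simulate_hopping)


@pytest.fixture(scope="session")
def ligand():
    return anle138b_topology()


@pytest.fixture(scope="session")
def fibril():
    """10-layer, 8-residues-per-layer toy protofilament."""
    return build_toy_fibril(n_layers=10, residues_per_layer=8, rise=0.48,
                            cavity_radius=0.5, seed=7)


@pytest.fixture(scope="session")
def small_fibril():
    return build_toy_fibril(n_layers=4, residues_per_layer=6, rise=0.48,
                            cavity_radius=0.5, seed=7)


@pytest.fixture(scope="session")
def hopping_run(ligand, fibril):
    """A modest hopping simulation shared across tests."""
    spec = HoppingSpec(n_sites=8, site_spacing=0.48, rate_up=0.25,
                       rate_down=0.25, jitter_sigma=0.048, n_frames=3000,
                       frame_interval=0.1, n_trajectories=2, seed=11)
    ens, truth = simulate_hopping(spec, ligand, fibril)
    return spec, ens, truth


def place_ligand_in_cavity(ligand, fibril, z: float,
                           offset=(0.0, 0.0)) -> np.ndarray:
    """Rigid ligand coordinates with the pyrazole-ring COM at the cavity
    axis at height z (nm)."""
    ring = ligand.group_indices("pyrazole_ring")
    w = ligand.masses[ring]
    template = ligand.reference_coords - np.average(
        ligand.reference_coords[ring], axis=0, weights=w)
    cx, cy = fibril.coords[:, 0].mean(), fibril.coords[:, 1].mean()
    return template + np.array([cx + offset[0], cy + offset[1], z])
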
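import numpy as np
import pytest

from emulsiphase import (
    AngleLaws,
    GallicAcidTemplate,
    Law,
    SpeciesSpec,
    sample_trajectory,
)
from emulsiphase.droplet import DropletFrame


@pytest.fixture(scope="session")
def template() -> GallicAcidTemplate:
    return GallicAcidTemplate.ideal()


@pytest.fixture(scope="session")
def small_traj():
    """Moderate ensemble with the default generative laws (seeded)."""
    spec = SpeciesSpec(n_oleic=100, n_surfactant=10, n_antioxidant=8,
                       n_water=2000, seed=11)
    return sample_trajectory(spec, 40)


@pytest.fixture(scope="session")
def delta_traj():
    """All gallic acid at exactly R = 31 A with a fixed (alpha, beta) pose."""
    spec = SpeciesSpec(
        n_oleic=100, n_surfactant=5, n_antioxidant=8, n_water=500,
        antioxidant_radial_law=Law.delta(31.0),
        antioxidant_angle_laws=AngleLaws(alpha=Law.delta(55.5),
                                         beta=Law.delta(64.5)),
        seed=21)
    return sample_trajectory(spec, 25)


def place_molecule(template: GallicAcidTemplate, rotation: np.ndarray,
                   position: np.ndarray, mol_id: int = 100) -> DropletFrame:
    """One rigid gallic-acid placement plus a symmetric 4-point oil core.

    The oil sites are arranged so the droplet COM is exactly the origin.
    """
    oil = np.array([[5.0, 0, 0], [-5.0, 0, 0], [0, 5.0, 0], [0, -5.0, 0]])
    body = template.centered() @ np.asarray(rotation).T + np.asarray(position)
    species = np.array(["OLE"] * 4 + ["GAL"] * 12, dtype=object)
    mols = np.array([0, 1, 2, 3] + [mol_id] * 12)
    labels = np.array(["COM"] * 4 + list(template.labels), dtype=object)
    coords = np.vstack([oil, body])
    from emulsiphase.droplet import SPECIES_MASSES
    mass = np.array([SPECIES_MASSES[(s, l)] for s, l in zip(species, labels)])
    return DropletFrame(species, mols, labels, coords, mass)
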
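"""In-memory containers for labelled droplet configurations.

A :class:`DropletFrame` is a flat per-atom table (species tag, molecule id,
atom label, coordinates in Angstrom, mass in amu) describing one spherical
oil-in-water droplet configuration; a :class:`DropletTrajectory` is an
ordered list of frames sharing one atom roster.  Species tags follow the
package convention: ``OLE`` (oleic acid, one centre-of-mass site), ``TW80``
(polysorbate-80 surfactant, three reference sites ``RNG``/``EOH``/``TAIL``),
``GAL`` (gallic acid, heavy atoms ``C1``..``C7``, ``O0``..``O4``) and
``HOH`` (water, one site).  Frames are assumed pre-imaged (no periodic
wrapping): the droplet is whole in Cartesian space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .errors import EmptyTrajectoryError, FormatError, MissingSpeciesError

__all__ = ["DropletFrame", "DropletTrajectory", "SPECIES_MASSES"]

# nominal site masses (amu); pseudo-sites carry the mass of the moiety they stand for
SPECIES_MASSES: dict[tuple[str, str], float] = {
    ("OLE", "COM"): 282.46,      # oleic acid, whole molecule
    ("HOH", "O"): 18.015,        # water, whole molecule
    ("TW80", "RNG"): 72.06,      # sorbitan five-carbon ring
    ("TW80", "EOH"): 17.007,     # hydroxyl termini of the ethylene-oxide arms
    ("TW80", "TAIL"): 265.4,     # oleate chain
}
_C, _O = 12.011, 15.999
for _lbl in ("C1", "C2", "C3", "C4", "C5", "C6", "C7"):
    SPECIES_MASSES[("GAL", _lbl)] = _C
for _lbl in ("O0", "O1", "O2", "O3", "O4"):
    SPECIES_MASSES[("GAL", _lbl)] = _O

GAL_LABELS = ("C1", "C2", "C3", "C4", "C5", "C6", "C7", "O0", "O1", "O2", "O3", "O4")


@dataclass
class DropletFrame:
    """One labelled droplet configuration (flat per-atom arrays)."""

    species: np.ndarray  # str tags, shape (n,)
    mol_id: np.ndarray   # int, shape (n,)
    label: np.ndarray    # str atom labels, shape (n,)
    coords: np.ndarray   # float Angstrom, shape (n, 3)
    mass: np.ndarray     # float amu, shape (n,)

    def __post_init__(self) -> None:
        self.species = np.asarray(self.species, dtype=object)
        self.mol_id = np.asarray(self.mol_id, dtype=int)
        self.label = np.asarray(self.label, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        n = self.species.size
        if not (self.mol_id.size == self.label.size == self.mass.size == n
                and self.coords.shape == (n, 3)):
            raise FormatError("inconsistent per-atom array shapes")
        if not np.all(np.isfinite(self.coords)):
            raise FormatError("non-finite coordinates in frame")

    @property
    def n_atoms(self) -> int:
        return self.species.size

    def mask(self, species: str) -> np.ndarray:
        return self.species == species

    def select(self, species: str, label: str | None = None) -> "DropletFrame":
        m = self.mask(species)
        if label is not None:
            m &= self.label == label
        if not m.any():
            raise MissingSpeciesError(f"no atoms for species {species!r}"
                                      + (f" label {label!r}" if label else ""))
        return DropletFrame(self.species[m], self.mol_id[m], self.label[m],
                            self.coords[m], self.mass[m])

    def molecule_ids(self, species: str) -> np.ndarray:
        m = self.mask(species)
        if not m.any():
            raise MissingSpeciesError(f"no atoms for species {species!r}")
        return np.unique(self.mol_id[m])

    def molecule_coords(self, species: str, mol: int) -> np.ndarray:
        m = self.mask(species) & (self.mol_id == mol)
        if not m.any():
            raise MissingSpeciesError(f"no atoms for {species!r} molecule {mol}")
        return self.coords[m]

    def molecule_coms(self, species: str) -> np.ndarray:
        """Mass-weighted centres of mass, one row per molecule of ``species``.

        Rows are ordered by ascending molecule id.
        """
        m = self.mask(species)
        if not m.any():
            raise MissingSpeciesError(f"no atoms for species {species!r}")
        ids = self.mol_id[m]
        w = self.mass[m]
        xyz = self.coords[m]
        uniq, inv = np.unique(ids, return_inverse=True)
        wsum = np.zeros(uniq.size)
        np.add.at(wsum, inv, w)
        com = np.zeros((uniq.size, 3))
        np.add.at(com, inv, xyz * w[:, None])
        return com / wsum[:, None]

    def translated(self, shift: Sequence[float]) -> "DropletFrame":
        return DropletFrame(self.species, self.mol_id, self.label,
                            self.coords + np.asarray(shift, float), self.mass)

    def rotated(self, rotation: np.ndarray, about: Sequence[float] = (0.0, 0.0, 0.0)) -> "DropletFrame":
        c = np.asarray(about, float)
        return DropletFrame(self.species, self.mol_id, self.label,
                            (self.coords - c) @ np.asarray(rotation, float).T + c,
                            self.mass)

    def roster(self) -> tuple[tuple[str, int, str], ...]:
        return tuple(zip(self.species.tolist(), self.mol_id.tolist(), self.label.tolist()))


@dataclass
class DropletTrajectory:
    """Ordered ensemble of frames sharing a common atom roster."""

    frames: list[DropletFrame]
    frame_interval: float | None = None  # optional metadata, time units

    def __post_init__(self) -> None:
        if not self.frames:
            raise EmptyTrajectoryError("trajectory must contain at least one frame")
        ref = self.frames[0].roster()
        for i, fr in enumerate(self.frames[1:], start=1):
            if fr.roster() != ref:
                raise FormatError(f"frame {i} atom roster differs from frame 0")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[DropletFrame]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> DropletFrame:
        return self.frames[i]
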
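"""In-memory containers for toy-bilayer topologies and trajectories.

A :class:`Topology` stores per-atom metadata (names, residues, elements,
vdW radii, hydrogen-bond donor/acceptor flags, bonded hydrogens, molecule
ids) plus a species label per molecule; a :class:`Trajectory` stores frames
of Å coordinates with orthorhombic box lengths and times.  Selections are
declarative predicates over atoms; leaflet and z-range predicates are
evaluated per frame against the bilayer centre (mean z of lipid atoms).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["Topology", "Trajectory", "Selection", "select", "bilayer_center"]

logger = logging.getLogger(__name__)

#: recognised molecule species labels
SPECIES = ("guaiacyl-like", "syringyl-like", "derivative", "lipid", "water")

SOLUTE_SPECIES = ("guaiacyl-like", "syringyl-like", "derivative")


@dataclass
class Topology:
    names: np.ndarray          # str per atom
    resnames: np.ndarray       # str per atom
    resids: np.ndarray         # int per atom
    elements: np.ndarray       # str per atom
    radii: np.ndarray          # float Å per atom
    donor: np.ndarray          # bool per atom
    acceptor: np.ndarray       # bool per atom
    bonded_h: list             # list[list[int]] hydrogen atom ids per atom
    mol_ids: np.ndarray        # int per atom, dense from 0
    mol_species: dict          # mol_id -> species label
    masses: Optional[np.ndarray] = None  # default: unit pseudo-atom masses

    def __post_init__(self) -> None:
        n = len(self.names)
        for arr in (self.resnames, self.resids, self.elements, self.radii,
                    self.donor, self.acceptor, self.mol_ids):
            if len(arr) != n:
                raise ValueError("per-atom arrays must share one length")
        if len(self.bonded_h) != n:
            raise ValueError("bonded_h must have one entry per atom")
        for i in np.flatnonzero(self.donor):
            if not self.bonded_h[i]:
                raise ValueError(f"donor atom {i} ({self.names[i]}) has no bonded hydrogen")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def n_molecules(self) -> int:
        return len(self.mol_species)

    def species_per_atom(self) -> np.ndarray:
        return np.array([self.mol_species[m] for m in self.mol_ids])

    def atom_masses(self) -> np.ndarray:
        if self.masses is not None:
            return self.masses
        return np.ones(self.n_atoms)

    def molecules_of_species(self, species: str) -> list[int]:
        return [m for m, s in self.mol_species.items() if s == species]

    def atoms_of_molecule(self, mol_id: int) -> np.ndarray:
        return np.flatnonzero(self.mol_ids == mol_id)


@dataclass
class Trajectory:
    coords: np.ndarray                 # (n_frames, n_atoms, 3) Å
    box: Optional[np.ndarray] = None   # (n_frames, 3) Å or None when absent
    times: Optional[np.ndarray] = None # ns, nondecreasing

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.times is None:
            self.times = np.arange(self.n_frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != self.n_frames:
            raise ValueError("times length must match frame count")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("frame times must be nondecreasing")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape == (3,):
                self.box = np.tile(self.box, (self.n_frames, 1))
            if self.box.shape != (self.n_frames, 3):
                raise ValueError("box must have shape (n_frames, 3)")
            if np.any(self.box <= 0):
                raise ValueError("box lengths must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1] if self.n_frames else 0


@dataclass(frozen=True)
class Selection:
    """Composable atom predicate; ``Selection()`` matches every atom."""

    names: Optional[frozenset] = None
    resnames: Optional[frozenset] = None
    species: Optional[frozenset] = None
    leaflet: Optional[str] = None           # "upper" | "lower"
    z_range: Optional[tuple] = None         # (z_min, z_max) absolute Å

    def __post_init__(self) -> None:
        for f in ("names", "resnames", "species"):
            v = getattr(self, f)
            if v is not None and not isinstance(v, frozenset):
                object.__setattr__(self, f, frozenset(v))
        if self.leaflet not in (None, "upper", "lower"):
            raise ValueError("leaflet must be 'upper' or 'lower'")

    @classmethod
    def parse(cls, text: str) -> "Selection":
        """Parse config strings like ``"name:NF leaflet:upper"``.

        Keys: name, resname, species, leaflet, zmin, zmax; multi-valued
        keys take comma-separated lists.
        """
        kw: dict = {}
        zmin = zmax = None
        for tok in text.split():
            key, _, val = tok.partition(":")
            if not val:
                raise ValueError(f"malformed selection token {tok!r}")
            if key == "name":
                kw["names"] = frozenset(val.split(","))
            elif key == "resname":
                kw["resnames"] = frozenset(val.split(","))
            elif key == "species":
                kw["species"] = frozenset(val.split(","))
            elif key == "leaflet":
                kw["leaflet"] = val
            elif key == "zmin":
                zmin = float(val)
            elif key == "zmax":
                zmax = float(val)
            else:
                raise ValueError(f"unknown selection key {key!r}")
        if zmin is not None or zmax is not None:
            kw["z_range"] = (-np.inf if zmin is None else zmin,
                             np.inf if zmax is None else zmax)
        return cls(**kw)


def bilayer_center(topology: Topology, frame: np.ndarray) -> float:
    """Per-frame bilayer centre: mean z over all lipid-species atoms."""
    lipid = topology.species_per_atom() == "lipid"
    if not lipid.any():
        return 0.0
    return float(frame[lipid, 2].mean())


def select(topology: Topology, frame: Optional[np.ndarray], selection: Selection) -> np.ndarray:
    """Atom ids matching ``selection`` (sorted, duplicate-free).

    ``frame`` is required only for the per-frame predicates (leaflet,
    z_range).  Unknown names/resnames/species yield an empty contribution
    with a logged warning rather than an error.
    """
    mask = np.ones(topology.n_atoms, dtype=bool)
    if selection.names is not None:
        known = set(topology.names)
        for nm in selection.names - known:
            logger.warning("selection references unknown atom name %r", nm)
        mask &= np.isin(topology.names, list(selection.names))
    if selection.resnames is not None:
        known = set(topology.resnames)
        for nm in selection.resnames - known:
            logger.warning("selection references unknown residue name %r", nm)
        mask &= np.isin(topology.resnames, list(selection.resnames))
    if selection.species is not None:
        for sp in selection.species - set(SPECIES):
            logger.warning("selection references unknown species %r", sp)
        mask &= np.isin(topology.species_per_atom(), list(selection.species))
    if selection.leaflet is not None or selection.z_range is not None:
        if frame is None:
            raise ValueError("leaflet/z-range selections require a frame")
        z = frame[:, 2]
        if selection.leaflet is not None:
            c = bilayer_center(topology, frame)
            mask &= (z > c) if selection.leaflet == "upper" else (z <= c)
        if selection.z_range is not None:
            lo, hi = selection.z_range
            mask &= (z >= lo) & (z <= hi)
    return np.flatnonzero(mask)
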
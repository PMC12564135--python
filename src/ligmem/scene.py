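"""Synthetic bilayer scenes with known ground truth.

Builds toy two-leaflet ceramide-like slabs: pseudo-lipids (one headgroup
nitrogen per leaflet plane at ±leaflet_z plus four chain carbons pointing
to the bilayer centre), water pseudo-atoms filling the |z| > leaflet_z
slabs at a requested number density, and an m×m lateral grid of solute
molecules whose centre-of-mass z follows externally supplied 1-D Langevin
paths.  Every feature an analyzer should recover can be planted exactly:
hydrogen-bond geometries (distance + angle), cluster memberships, and a
two-state compact/extended end-to-end conformer mixture.

All randomness comes from named substreams of the scene seed, so an
identical spec yields bit-identical topologies and coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np

from .dynamics import Path1D
from .trajectory import Topology, Trajectory

__all__ = [
    "SoluteTemplate",
    "PlantedFeatures",
    "SceneSpec",
    "SceneError",
    "build_bilayer_scene",
    "plant_hbond_frames",
    "expected_hbond_count",
    "compute_molar_ratio",
    "guaiacyl_template",
    "syringyl_template",
    "derivative_template",
]


class SceneError(ValueError):
    """Infeasible or inconsistent scene specification."""


@dataclass(frozen=True)
class SoluteTemplate:
    """Hinged two-arm pseudo-molecule.

    Two rigid arms of length ``arm`` meet at the hinge carbon CH; the
    end-to-end distance between the terminal oxygens is set by the hinge
    bend and ranges over (0, 2*arm].  ``conformer_modes`` are
    (end-to-end Å, weight) mixture components emulating the compact and
    extended states of the lignin units; ``dihedral_modes`` likewise set
    the arm dihedral (degrees).
    """

    species: str = "guaiacyl-like"
    resname: str = "GUA"
    arm: float = 4.2
    terminal_pair: tuple = ("O4", "O9")
    dihedral_quad: tuple = ("C2", "C1", "CH", "C3")
    conformer_modes: tuple = ((5.5, 0.5), (8.0, 0.5))
    conformer_sigma: float = 0.2
    dihedral_modes: tuple = ((15.0, 0.5), (90.0, 0.5))
    dihedral_sigma: float = 8.0

    #: (name, element, donor, acceptor); geometry is set by :meth:`place`
    atoms: tuple = (
        ("O4", "O", True, True),
        ("HO4", "H", False, False),
        ("C1", "C", False, False),
        ("C2", "C", False, False),
        ("CH", "C", False, False),
        ("C3", "C", False, False),
        ("C4", "C", False, False),
        ("O9", "O", False, True),
    )

    def __post_init__(self) -> None:
        names = [a[0] for a in self.atoms]
        for nm in (*self.terminal_pair, *self.dihedral_quad):
            if nm not in names:
                raise SceneError(f"template references missing atom {nm!r}")
        for modes in (self.conformer_modes, self.dihedral_modes):
            w = sum(m[1] for m in modes)
            if abs(w - 1.0) > 1e-9:
                raise SceneError("mixture weights must sum to 1")
        for r, _ in self.conformer_modes:
            if not 0 < r <= 2 * self.arm:
                raise SceneError(f"end-to-end mode {r} outside (0, {2*self.arm}]")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def atom_names(self) -> list:
        return [a[0] for a in self.atoms]

    def place(self, com: np.ndarray, r_ee: float, phi_deg: float, psi_deg: float) -> np.ndarray:
        """Coordinates (n_atoms, 3) with centroid at ``com``.

        ``r_ee`` is the O4–O9 distance, ``phi_deg`` the arm dihedral,
        ``psi_deg`` a rigid in-plane rotation about z (the molecule lies
        with its arms roughly perpendicular to the bilayer normal).
        """
        L = self.arm
        r_ee = float(np.clip(r_ee, 1e-3, 2 * L - 1e-6))
        alpha = 2.0 * np.arccos(r_ee / (2 * L))
        phi = np.deg2rad(-phi_deg)  # sign matches the IUPAC dihedral measured on the quad
        d = np.array([np.cos(alpha), np.sin(alpha) * np.cos(phi), np.sin(alpha) * np.sin(phi)])
        pos = {
            "O4": np.zeros(3),
            "HO4": np.array([-0.60, 0.80, 0.0]),
            "C1": np.array([1.4, 0.0, 0.0]),
            "C2": np.array([1.4 + 0.49, 1.31, 0.0]),
            "CH": np.array([L, 0.0, 0.0]),
        }
        pos["C3"] = pos["CH"] + 1.4 * d
        pos["C4"] = pos["CH"] + 0.5 * L * d
        pos["O9"] = pos["CH"] + L * d
        xyz = np.array([pos[a[0]] for a in self.atoms])
        c, s = np.cos(np.deg2rad(psi_deg)), np.sin(np.deg2rad(psi_deg))
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        xyz = xyz @ rot.T
        return xyz - xyz.mean(axis=0) + np.asarray(com, dtype=float)

    def sample_conformer(self, rng: np.random.Generator) -> tuple:
        """Draw (end_to_end, dihedral) from the planted mixtures."""
        rw = np.array([m[1] for m in self.conformer_modes])
        i = rng.choice(len(rw), p=rw / rw.sum())
        r = rng.normal(self.conformer_modes[i][0], self.conformer_sigma)
        r = float(np.clip(r, 1.0, 2 * self.arm - 0.05))
        dw = np.array([m[1] for m in self.dihedral_modes])
        j = rng.choice(len(dw), p=dw / dw.sum())
        phi = float(rng.normal(self.dihedral_modes[j][0], self.dihedral_sigma))
        return r, phi


def guaiacyl_template() -> SoluteTemplate:
    return SoluteTemplate()


def syringyl_template() -> SoluteTemplate:
    """Syringyl-like unit: sharper conformer preference (methoxy hindrance)."""
    return SoluteTemplate(
        species="syringyl-like", resname="SYR", conformer_sigma=0.12, dihedral_sigma=6.0
    )


def derivative_template() -> SoluteTemplate:
    """Trimer-like derivative: longer arms, rigid single conformer."""
    return SoluteTemplate(
        species="derivative",
        resname="LIG",
        arm=5.2,
        conformer_modes=((7.5, 1.0),),
        conformer_sigma=0.2,
        dihedral_modes=((-120.0, 1.0),),
        dihedral_sigma=10.0,
    )


@dataclass(frozen=True)
class PlantedFeatures:
    """Ground-truth features realised exactly by the builder.

    ``clusters`` partitions solute molecule indices (0..m²-1); members of
    one cluster are placed in mutual atomic contact (corresponding atoms
    3.2 Å apart), distinct clusters far beyond any clustering cutoff.
    """

    clusters: Optional[tuple] = None  # tuple of tuples of molecule indices

    def __post_init__(self) -> None:
        if self.clusters is not None:
            object.__setattr__(
                self, "clusters", tuple(tuple(int(i) for i in c) for c in self.clusters)
            )
            flat = [i for c in self.clusters for i in c]
            if len(flat) != len(set(flat)):
                raise SceneError("planted clusters must not share molecules")


@dataclass(frozen=True)
class SceneSpec:
    box: tuple = (128.0, 128.0, 96.0)
    n_lipids_per_leaflet: int = 400
    leaflet_z: float = 20.0
    lattice_jitter: float = 0.4
    water_number_density: float = 0.0334
    solute_grid: int = 3
    solute_template: SoluteTemplate = field(default_factory=guaiacyl_template)
    planted_features: Optional[PlantedFeatures] = None
    n_frames: int = 1
    solute_z0: Optional[float] = None  # default leaflet_z + 8
    seed: int = 0

    def __post_init__(self) -> None:
        if any(b <= 0 for b in self.box):
            raise SceneError("box lengths must be positive")
        if self.n_lipids_per_leaflet < 1:
            raise SceneError("need at least one lipid per leaflet")
        if self.leaflet_z <= 0 or self.leaflet_z >= self.box[2] / 2:
            raise SceneError("headgroup planes must satisfy 0 < leaflet_z < Lz/2")
        if self.water_number_density < 0:
            raise SceneError("water_number_density must be >= 0")
        if self.water_number_density > 0.1:
            raise SceneError("water_number_density infeasible (> 0.1 Å^-3): overfilled box")
        if self.solute_grid < 1:
            raise SceneError("solute_grid must be >= 1")
        if self.n_frames < 1:
            raise SceneError("n_frames must be >= 1")
        if self.planted_features and self.planted_features.clusters:
            m2 = self.solute_grid**2
            for c in self.planted_features.clusters:
                for i in c:
                    if not 0 <= i < m2:
                        raise SceneError(f"planted cluster references molecule {i} >= {m2}")


#: (name, element, donor, acceptor) of the 5-atom toy ceramide lipid
_LIPID_ATOMS = (
    ("NF", "N", False, True),
    ("CF1", "C", False, False),
    ("CF2", "C", False, False),
    ("CF3", "C", False, False),
    ("CF4", "C", False, False),
)

_ELEMENT_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52}


class _TopoBuilder:
    def __init__(self) -> None:
        self.names, self.resnames, self.resids, self.elements = [], [], [], []
        self.donor, self.acceptor, self.bonded_h = [], [], []
        self.mol_ids, self.mol_species = [], {}
        self._mol = -1

    def add_molecule(self, atoms, resname: str, species: str) -> int:
        """atoms: iterable of (name, element, donor, acceptor)."""
        self._mol += 1
        base = len(self.names)
        h_of: dict = {}
        for k, (name, element, don, acc) in enumerate(atoms):
            self.names.append(name)
            self.resnames.append(resname)
            self.resids.append(self._mol + 1)
            self.elements.append(element)
            self.donor.append(don)
            self.acceptor.append(acc)
            self.bonded_h.append([])
            self.mol_ids.append(self._mol)
            if element == "H":
                h_of[name] = base + k
        # attach hydrogens by naming convention (HO4 belongs to O4); a donor
        # without a same-named hydrogen takes any hydrogen in the molecule
        for k, (name, element, don, acc) in enumerate(atoms):
            if don:
                if "H" + name in h_of:
                    self.bonded_h[base + k] = [h_of["H" + name]]
                elif h_of:
                    self.bonded_h[base + k] = [next(iter(h_of.values()))]
        self.mol_species[self._mol] = species
        return self._mol

    def build(self) -> Topology:
        return Topology(
            names=np.array(self.names),
            resnames=np.array(self.resnames),
            resids=np.array(self.resids),
            elements=np.array(self.elements),
            radii=np.array([_ELEMENT_RADII.get(e, 1.70) for e in self.elements]),
            donor=np.array(self.donor, dtype=bool),
            acceptor=np.array(self.acceptor, dtype=bool),
            bonded_h=self.bonded_h,
            mol_ids=np.array(self.mol_ids, dtype=int),
            mol_species=self.mol_species,
        )


def _lateral_grid(n: int, Lx: float, Ly: float) -> np.ndarray:
    """n points on a centred square-ish lattice inside an Lx × Ly box."""
    m = int(np.ceil(np.sqrt(n)))
    xs = (np.arange(m) + 0.5) * Lx / m - Lx / 2
    ys = (np.arange(m) + 0.5) * Ly / m - Ly / 2
    pts = np.array([(x, y) for y in ys for x in xs])
    return pts[:n]


def build_bilayer_scene(
    spec: SceneSpec, paths: Optional[Sequence[Path1D]] = None
) -> tuple[Topology, Trajectory]:
    """Realise a scene: (Topology, Trajectory).

    If ``paths`` is given (one :class:`~ligmem.dynamics.Path1D` per solute
    molecule) the solute COM z in frame k is ``path.z[k]`` and the frame
    count is the shortest path length (capped at spec.n_frames if longer);
    otherwise solutes sit at ``solute_z0``.  Lipids and water are static
    across frames.  Deterministic under ``spec.seed``.
    """
    Lx, Ly, Lz = spec.box
    rng_scene = np.random.default_rng([spec.seed, 1])
    rng_conf = np.random.default_rng([spec.seed, 3])
    tb = _TopoBuilder()
    static_xyz: list = []

    # ---- lipids: two leaflets
    n_leaf = spec.n_lipids_per_leaflet
    pitch = Lx / int(np.ceil(np.sqrt(n_leaf)))
    if pitch < 2.0:
        raise SceneError(f"lipid lattice pitch {pitch:.2f} Å < 2 Å: overfilled box")
    grid = _lateral_grid(n_leaf, Lx, Ly)
    chain_dz = spec.leaflet_z / 5.0
    for sign in (+1.0, -1.0):
        for gx, gy in grid:
            jit = rng_scene.normal(0.0, spec.lattice_jitter, size=3)
            head = np.array([gx + jit[0], gy + jit[1], sign * spec.leaflet_z + jit[2]])
            coords = [head]
            for k in range(1, 5):
                coords.append(head - np.array([0.0, 0.0, sign * k * chain_dz]))
            tb.add_molecule(_LIPID_ATOMS, "CER", "lipid")
            static_xyz.extend(coords)

    # ---- water slabs |z| in (leaflet_z + 1.5, Lz/2 - 0.5)
    z_lo, z_hi = spec.leaflet_z + 1.5, Lz / 2 - 0.5
    n_water = 0
    if spec.water_number_density > 0 and z_hi > z_lo:
        vol = Lx * Ly * (z_hi - z_lo)
        n_per_slab = int(round(spec.water_number_density * vol))
        for sign in (+1.0, -1.0):
            xy = rng_scene.uniform([-Lx / 2, -Ly / 2], [Lx / 2, Ly / 2], size=(n_per_slab, 2))
            zz = sign * rng_scene.uniform(z_lo, z_hi, size=n_per_slab)
            for i in range(n_per_slab):
                tb.add_molecule((("OW", "O", False, True),), "HOH", "water")
                static_xyz.append(np.array([xy[i, 0], xy[i, 1], zz[i]]))
            n_water += n_per_slab

    static_xyz = np.array(static_xyz) if static_xyz else np.zeros((0, 3))

    # ---- solutes
    m2 = spec.solute_grid**2
    tpl = spec.solute_template
    z0 = spec.solute_z0 if spec.solute_z0 is not None else spec.leaflet_z + 8.0
    if paths is not None:
        if len(paths) != m2:
            raise SceneError(f"need {m2} COM paths, got {len(paths)}")
        n_frames = min(len(p.z) for p in paths)
        com_z = np.array([p.z[:n_frames] for p in paths])  # (m2, n_frames)
    else:
        n_frames = spec.n_frames
        com_z = np.full((m2, n_frames), z0)

    lateral = _solute_lateral_positions(spec)
    psis = rng_scene.uniform(0.0, 360.0, size=m2)
    if spec.planted_features and spec.planted_features.clusters:
        # identical orientation within a planted cluster keeps the planted
        # 3.2 Å corresponding-atom contacts exact
        for c in spec.planted_features.clusters:
            for i in c[1:]:
                psis[i] = psis[c[0]]

    solute_mols = []
    for i in range(m2):
        solute_mols.append(tb.add_molecule(tpl.atoms, tpl.resname, tpl.species))

    frames = np.empty((n_frames, len(static_xyz) + m2 * tpl.n_atoms, 3))
    frames[:, : len(static_xyz)] = static_xyz
    for k in range(n_frames):
        for i in range(m2):
            r_ee, phi = tpl.sample_conformer(rng_conf)
            com = np.array([lateral[i, 0], lateral[i, 1], com_z[i, k]])
            xyz = tpl.place(com, r_ee, phi, psis[i])
            a0 = len(static_xyz) + i * tpl.n_atoms
            frames[k, a0 : a0 + tpl.n_atoms] = xyz

    topo = tb.build()
    _check_solute_clashes(spec, topo, frames[0], solute_mols)
    times = paths[0].times[:n_frames] if paths is not None else np.arange(n_frames, dtype=float)
    traj = Trajectory(coords=frames, box=np.tile(np.array(spec.box), (n_frames, 1)), times=times)
    return topo, traj


def _solute_lateral_positions(spec: SceneSpec) -> np.ndarray:
    Lx, Ly, _ = spec.box
    m = spec.solute_grid
    m2 = m * m
    planted = spec.planted_features.clusters if spec.planted_features else None
    if not planted:
        return _lateral_grid(m2, Lx, Ly)
    # planted clusters: singletons for unlisted molecules
    listed = {i for c in planted for i in c}
    groups = list(planted) + [(i,) for i in range(m2) if i not in listed]
    max_len = max(len(g) for g in groups)
    pitch_needed = 2 * spec.solute_template.arm + 3.2 * max_len + 6.0
    g = int(np.ceil(np.sqrt(len(groups))))
    if g * pitch_needed > min(Lx, Ly):
        raise SceneError("planted clusters do not fit the box at safe separation")
    anchors = _lateral_grid(len(groups), Lx, Ly)
    lateral = np.zeros((m2, 2))
    for a, group in zip(anchors, groups):
        for j, mol in enumerate(group):
            lateral[mol] = a + np.array([0.0, 3.2 * j])
    return lateral


def _check_solute_clashes(spec, topo, frame, solute_mols, tol: float = 0.8) -> None:
    planted = spec.planted_features.clusters if spec.planted_features else ()
    group_of = {}
    for gi, c in enumerate(planted or ()):
        for i in c:
            group_of[i] = gi
    for ai, mi in enumerate(solute_mols):
        for aj, mj in enumerate(solute_mols):
            if aj <= ai:
                continue
            if group_of.get(ai, ("s", ai)) == group_of.get(aj, ("s", aj)):
                continue
            xi = frame[topo.atoms_of_molecule(mi)]
            xj = frame[topo.atoms_of_molecule(mj)]
            d2 = ((xi[:, None, :] - xj[None, :, :]) ** 2).sum(-1)
            if d2.min() < tol * tol:
                raise SceneError(
                    f"solute molecules {ai} and {aj} clash beyond tolerance ({np.sqrt(d2.min()):.2f} Å)"
                )


# ------------------------------------------------------------- H-bond planting

def plant_hbond_frames(
    spec: SceneSpec, pairs: Sequence[tuple]
) -> tuple[Topology, Trajectory]:
    """Single-frame scene containing exactly the requested donor/acceptor
    geometries.

    Each pair is (d_DA Å, angle_HDA degrees): a donor oxygen OD with its
    hydrogen HD (bond 1.0 Å) and an acceptor oxygen OA placed at distance
    d_DA with the H–D–A angle as requested.  Donor and acceptor are
    separate molecules (solute-like and water-like), pairs are mutually
    separated far beyond any realistic criterion, so the hydrogen-bond
    count expected under criteria (d_max, a_max) is exactly
    :func:`expected_hbond_count`.
    """
    Lx, Ly, _ = spec.box
    n = len(pairs)
    anchors = _lateral_grid(n, Lx, Ly)
    pitch = Lx / int(np.ceil(np.sqrt(max(n, 1))))
    if pitch < 10.0:
        raise SceneError("too many planted pairs for the box (pairs would interact)")
    tb = _TopoBuilder()
    xyz = []
    z_plane = spec.leaflet_z + 10.0
    for (d_da, ang), (ax, ay) in zip(pairs, anchors):
        if d_da <= 0:
            raise SceneError("planted D–A distance must be positive")
        theta = np.deg2rad(ang)
        D = np.array([ax, ay, z_plane])
        A = D + np.array([d_da, 0.0, 0.0])
        H = D + np.array([np.cos(theta), np.sin(theta), 0.0])  # 1.0 Å O–H bond
        if np.linalg.norm(H - A) < 0.5:
            raise SceneError("planted geometry violates atom-clash tolerance")
        tb.add_molecule((("OD", "O", True, False), ("HD", "H", False, False)), "GUA", "guaiacyl-like")
        xyz.extend([D, H])
        tb.add_molecule((("OA", "O", False, True),), "HOH", "water")
        xyz.append(A)
    topo = tb.build()
    traj = Trajectory(
        coords=np.array(xyz)[None, :, :], box=np.array(spec.box)[None, :], times=np.array([0.0])
    )
    return topo, traj


def expected_hbond_count(pairs: Sequence[tuple], d_max: float, angle_max: float) -> int:
    """Ground-truth count of planted geometries inside both cutoffs."""
    return sum(1 for d, a in pairs if d <= d_max and a <= angle_max)


# ---------------------------------------------------------------- molar ratio

def compute_molar_ratio(n_solute: int, n_lipids: int) -> tuple[str, Fraction]:
    """Solute:lipid ratio as the conventional "1:N" label plus the exact
    rational n_solute/n_lipids.
    """
    if n_solute <= 0 or n_lipids <= 0:
        raise ValueError("molecule counts must be positive")
    return f"1:{round(n_lipids / n_solute)}", Fraction(n_solute, n_lipids)
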
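"""Trajectory-derived observables for lignin–bilayer scenes.

Covers the quantities used to characterise surface adhesion and insertion:
solute COM z-distance to the upper-leaflet nitrogen plane, running
averages, distance distributions, number-density profiles across the
bilayer normal, geometric hydrogen bonds, distance-cutoff clustering, and
conformational (end-to-end, dihedral) maps.

Pair distances use the orthorhombic minimum-image convention in x and y
only; z is treated as non-periodic (slab geometry).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .trajectory import (
    SOLUTE_SPECIES,
    Selection,
    Topology,
    Trajectory,
    bilayer_center,
    select,
)

__all__ = [
    "Profile",
    "Density2D",
    "HBondCriteria",
    "HBondEvent",
    "ClusterResult",
    "com_z_distance",
    "running_average",
    "distance_distribution",
    "number_density_profile",
    "detect_hbonds",
    "hbond_timeseries",
    "hbond_distribution",
    "hbond_vs_z",
    "count_clusters",
    "cluster_timeseries",
    "end_to_end",
    "dihedral",
    "conformation_map",
]

SelectionLike = Union[Selection, np.ndarray, Sequence[int]]


# =============================================================== containers

@dataclass
class Profile:
    """Uniform-bin 1-D function of a coordinate."""

    centers: np.ndarray
    values: np.ndarray
    bin_width: float
    mode: str  # counts | number_density | probability_density
    n_frames: int = 1

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.centers.shape != self.values.shape:
            raise ValueError("centers and values must align")
        if len(self.centers) > 1:
            w = np.diff(self.centers)
            if not np.allclose(w, self.bin_width, rtol=1e-6, atol=1e-9):
                raise ValueError("bins must be uniform")
        if self.mode not in ("counts", "number_density", "probability_density"):
            raise ValueError(f"unknown normalization mode {self.mode!r}")
        if self.mode == "probability_density":
            q = self.integral()
            if abs(q - 1.0) > 1e-9:
                raise ValueError(f"probability density integrates to {q}, not 1")

    def integral(self) -> float:
        return float(self.values.sum() * self.bin_width)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"center": self.centers, "value": self.values})


@dataclass
class Density2D:
    """Normalised 2-D frequency map (cell masses sum to 1)."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    values: np.ndarray  # shape (nx, ny)

    def __post_init__(self) -> None:
        self.x_edges = np.asarray(self.x_edges, dtype=float)
        self.y_edges = np.asarray(self.y_edges, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.x_edges) <= 0) or np.any(np.diff(self.y_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if self.values.shape != (len(self.x_edges) - 1, len(self.y_edges) - 1):
            raise ValueError("values shape must match edges")

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def mode_location(self) -> tuple:
        i, j = np.unravel_index(np.argmax(self.values), self.values.shape)
        return float(self.x_centers[i]), float(self.y_centers[j])


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criterion.

    The default (3.5 Å donor–acceptor distance, 30° H–donor–acceptor
    angle) is a widely used MD-analysis choice; absolute counts are
    criterion-dependent and must be reported together with it.
    """

    d_DA_max: float = 3.5
    angle_HDA_max: float = 30.0

    def __post_init__(self) -> None:
        if self.d_DA_max <= 0:
            raise ValueError("d_DA_max must be > 0")
        if not 0 < self.angle_HDA_max <= 90:
            raise ValueError("angle_HDA_max must be in (0, 90] degrees")


@dataclass(frozen=True)
class HBondEvent:
    frame: int
    donor: int
    hydrogen: int
    acceptor: int
    d_DA: float
    angle_HDA: float


@dataclass
class ClusterResult:
    frame: int
    cutoff: float
    components: list            # list[list[mol_id]]
    normalized_count: dict      # species -> clusters containing species / n_molecules of species


# =============================================================== geometry

def _min_image_xy(dvec: np.ndarray, box: Optional[np.ndarray]) -> np.ndarray:
    """Wrap displacement vectors minimum-image in x and y (z non-periodic)."""
    if box is None:
        return dvec
    out = dvec.copy()
    for ax in (0, 1):
        L = box[ax]
        out[..., ax] -= L * np.round(out[..., ax] / L)
    return out


def _resolve(sel: SelectionLike, topology: Topology, frame: Optional[np.ndarray]) -> np.ndarray:
    if isinstance(sel, Selection):
        return select(topology, frame, sel)
    return np.asarray(sel, dtype=int)


# =============================================================== z distance

def com_z_distance(
    traj: Trajectory,
    topology: Topology,
    solute: SelectionLike,
    reference: SelectionLike,
) -> np.ndarray:
    """Per-frame COM_z(solute) − mean_z(reference), Å.

    Negative values mean the solute centre of mass sits below the
    reference plane (inserted below the upper-leaflet nitrogens).
    """
    out = np.empty(traj.n_frames)
    masses = topology.atom_masses()
    for k in range(traj.n_frames):
        frame = traj.coords[k]
        s = _resolve(solute, topology, frame)
        r = _resolve(reference, topology, frame)
        if len(s) == 0 or len(r) == 0:
            raise ValueError(f"empty selection at frame {k}")
        w = masses[s]
        out[k] = np.average(frame[s, 2], weights=w) - frame[r, 2].mean()
    return out


def running_average(series: np.ndarray, window: int) -> np.ndarray:
    """Centred moving mean; edges truncated to the available support.

    ``window`` is rounded up to the next odd integer so the window is
    symmetric; output length equals input length.
    """
    series = np.asarray(series, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(series):
        raise ValueError(f"window {window} exceeds series length {len(series)}")
    if window % 2 == 0:
        window += 1
    h = window // 2
    csum = np.concatenate(([0.0], np.cumsum(series)))
    n = len(series)
    idx = np.arange(n)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def distance_distribution(
    series: np.ndarray,
    bin_width: float = 1.0,
    value_range: Optional[tuple] = None,
) -> Profile:
    """Normalised probability density of a scalar series on uniform bins."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty series")
    if value_range is None:
        lo = np.floor(series.min() / bin_width) * bin_width
        hi = np.ceil(series.max() / bin_width) * bin_width
        hi = max(hi, lo + bin_width)
    else:
        lo, hi = value_range
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    hist, _ = np.histogram(series, bins=edges)
    dens = hist / (hist.sum() * bin_width)
    # exact unit quadrature regardless of float rounding
    dens /= dens.sum() * bin_width
    return Profile(
        centers=0.5 * (edges[:-1] + edges[1:]),
        values=dens,
        bin_width=bin_width,
        mode="probability_density",
        n_frames=len(series),
    )


# =============================================================== densities

def number_density_profile(
    traj: Trajectory,
    topology: Topology,
    selection: SelectionLike,
    bin_width: float = 0.5,
    mode: str = "number_density",
    symmetrize: bool = False,
) -> Profile:
    """Atom density vs z − bilayer centre, frame-averaged.

    ``counts`` mode returns mean atoms per bin per frame (so the bin sum
    equals the mean selected-atom count exactly); ``number_density``
    divides by box area × bin width (Å⁻³).  Optional symmetrisation
    averages the ±z bins.
    """
    if traj.box is None:
        raise ValueError("number density profile requires box metadata")
    half = traj.box[:, 2].max() / 2 + 2 * bin_width
    nbin = int(np.ceil(half / bin_width))
    edges = bin_width * np.arange(-nbin, nbin + 1)
    counts = np.zeros(len(edges) - 1)
    area = 0.0
    for k in range(traj.n_frames):
        frame = traj.coords[k]
        ids = _resolve(selection, topology, frame)
        zrel = frame[ids, 2] - bilayer_center(topology, frame)
        h, _ = np.histogram(zrel, bins=edges)
        counts += h
        area += traj.box[k, 0] * traj.box[k, 1]
    counts /= traj.n_frames
    area /= traj.n_frames
    if symmetrize:
        counts = 0.5 * (counts + counts[::-1])
    values = counts if mode == "counts" else counts / (area * bin_width)
    if mode not in ("counts", "number_density"):
        raise ValueError("mode must be 'counts' or 'number_density'")
    return Profile(
        centers=0.5 * (edges[:-1] + edges[1:]),
        values=values,
        bin_width=bin_width,
        mode=mode,
        n_frames=traj.n_frames,
    )


# =============================================================== H-bonds

def detect_hbonds(
    frame: np.ndarray,
    topology: Topology,
    criteria: HBondCriteria,
    groupA: SelectionLike,
    groupB: SelectionLike,
    box: Optional[np.ndarray] = None,
    intermolecular: bool = True,
    frame_index: int = 0,
) -> list:
    """Geometric hydrogen bonds between two atom groups in one frame.

    An event is a (donor, bonded hydrogen, acceptor) triple with the donor
    in one group and the acceptor in the other (both orientations are
    scanned), d(D,A) ≤ d_DA_max and angle(H–D–A) ≤ angle_HDA_max.  With
    ``intermolecular`` the donor and acceptor must belong to different
    molecules.
    """
    a_ids = _resolve(groupA, topology, frame)
    b_ids = _resolve(groupB, topology, frame)
    pairs = ((a_ids, b_ids),) if np.array_equal(a_ids, b_ids) else ((a_ids, b_ids), (b_ids, a_ids))
    events: list = []
    for d_ids, acc_ids in pairs:
        donors = d_ids[topology.donor[d_ids]]
        acceptors = acc_ids[topology.acceptor[acc_ids]]
        if len(donors) == 0 or len(acceptors) == 0:
            continue
        for don in donors:
            if not topology.bonded_h[don]:
                raise ValueError(f"donor atom {don} has no bonded hydrogen")
            dv = _min_image_xy(frame[acceptors] - frame[don], box)
            dist = np.linalg.norm(dv, axis=1)
            near = dist <= criteria.d_DA_max
            if intermolecular:
                near &= topology.mol_ids[acceptors] != topology.mol_ids[don]
            near &= acceptors != don
            for h in topology.bonded_h[don]:
                hv = _min_image_xy(frame[h] - frame[don], box)
                nh = np.linalg.norm(hv)
                for idx in np.flatnonzero(near):
                    av = dv[idx]
                    cosang = np.dot(hv, av) / (nh * dist[idx])
                    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                    if ang <= criteria.angle_HDA_max:
                        events.append(
                            HBondEvent(frame_index, int(don), int(h), int(acceptors[idx]),
                                       float(dist[idx]), float(ang))
                        )
    return events


def hbond_timeseries(
    traj: Trajectory,
    topology: Topology,
    criteria: HBondCriteria,
    groupA: SelectionLike,
    groupB: SelectionLike,
    intermolecular: bool = True,
) -> np.ndarray:
    """Hydrogen-bond count per frame."""
    counts = np.empty(traj.n_frames, dtype=int)
    for k in range(traj.n_frames):
        box = traj.box[k] if traj.box is not None else None
        counts[k] = len(
            detect_hbonds(traj.coords[k], topology, criteria, groupA, groupB,
                          box=box, intermolecular=intermolecular, frame_index=k)
        )
    return counts


def hbond_distribution(counts: np.ndarray) -> Profile:
    """Normalised distribution over integer hydrogen-bond counts."""
    counts = np.asarray(counts, dtype=int)
    if counts.size == 0:
        raise ValueError("empty count series")
    hi = counts.max()
    vals = np.bincount(counts, minlength=hi + 1) / counts.size
    return Profile(
        centers=np.arange(hi + 1, dtype=float),
        values=vals,
        bin_width=1.0,
        mode="probability_density",
        n_frames=len(counts),
    )


def hbond_vs_z(
    counts: np.ndarray,
    z_series: np.ndarray,
    z_bin_width: float = 1.0,
) -> Density2D:
    """Joint (z-distance, H-bond count) histogram over frames.

    ``counts`` and ``z_series`` must be frame-aligned; the count axis uses
    unit-width integer bins, the z axis uniform ``z_bin_width`` bins.
    """
    counts = np.asarray(counts, dtype=float)
    z_series = np.asarray(z_series, dtype=float)
    if counts.shape != z_series.shape:
        raise ValueError(f"length mismatch: {len(counts)} counts vs {len(z_series)} z values")
    lo = np.floor(z_series.min() / z_bin_width) * z_bin_width
    hi = np.ceil(z_series.max() / z_bin_width) * z_bin_width
    hi = max(hi, lo + z_bin_width)
    x_edges = np.arange(lo, hi + 0.5 * z_bin_width, z_bin_width)
    y_edges = np.arange(-0.5, counts.max() + 1.0, 1.0)
    h, _, _ = np.histogram2d(z_series, counts, bins=(x_edges, y_edges))
    return Density2D(x_edges=x_edges, y_edges=y_edges, values=h / h.sum())


# =============================================================== clustering

def count_clusters(
    frame: np.ndarray,
    topology: Topology,
    cutoff: float,
    box: Optional[np.ndarray] = None,
    frame_index: int = 0,
) -> ClusterResult:
    """Single-linkage clustering of solute molecules at an any-atom cutoff.

    Molecules are nodes; an edge joins two molecules when any interatomic
    distance (minimum image in x, y) is ≤ cutoff; components come from the
    sparse connected-components solver.  The per-species normalised count
    is (#clusters containing ≥ 1 molecule of that species) / (#molecules
    of that species).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    species_atoms = topology.species_per_atom()
    solute_mask = np.isin(species_atoms, SOLUTE_SPECIES)
    mols = np.unique(topology.mol_ids[solute_mask])
    if len(mols) == 0:
        raise ValueError("no solute molecules in topology")
    idx_of = {m: i for i, m in enumerate(mols)}
    rows, cols = [], []
    atom_groups = [np.flatnonzero(topology.mol_ids == m) for m in mols]
    for i in range(len(mols)):
        xi = frame[atom_groups[i]]
        for j in range(i + 1, len(mols)):
            xj = frame[atom_groups[j]]
            dv = _min_image_xy(xi[:, None, :] - xj[None, :, :], box)
            if (dv**2).sum(-1).min() <= cutoff * cutoff:
                rows.append(i)
                cols.append(j)
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(len(mols), len(mols)))
    n_comp, labels = connected_components(adj, directed=False)
    components = [[int(mols[i]) for i in np.flatnonzero(labels == c)] for c in range(n_comp)]
    normalized = {}
    for sp in SOLUTE_SPECIES:
        sp_mols = [m for m in mols if topology.mol_species[m] == sp]
        if not sp_mols:
            continue
        hit = sum(1 for comp in components if any(topology.mol_species[m] == sp for m in comp))
        normalized[sp] = hit / len(sp_mols)
    return ClusterResult(frame=frame_index, cutoff=cutoff, components=components,
                         normalized_count=normalized)


def cluster_timeseries(traj: Trajectory, topology: Topology, cutoff: float) -> pd.DataFrame:
    """Per-frame per-species normalised cluster counts (tidy frame)."""
    rows = []
    for k in range(traj.n_frames):
        box = traj.box[k] if traj.box is not None else None
        res = count_clusters(traj.coords[k], topology, cutoff, box=box, frame_index=k)
        for sp, val in res.normalized_count.items():
            rows.append({"frame": k, "time": traj.times[k], "species": sp,
                         "normalized_clusters": val, "n_clusters": len(res.components)})
    return pd.DataFrame(rows)


# =============================================================== conformers

def end_to_end(
    traj: Trajectory, topology: Topology, mol_id: int, terminal_pair: tuple = ("O4", "O9")
) -> np.ndarray:
    """Distance between the two named terminal atoms of one molecule, per frame."""
    atoms = topology.atoms_of_molecule(mol_id)
    ids = []
    for nm in terminal_pair:
        hit = atoms[topology.names[atoms] == nm]
        if len(hit) == 0:
            raise ValueError(f"molecule {mol_id} has no atom named {nm!r}")
        ids.append(hit[0])
    d = traj.coords[:, ids[0], :] - traj.coords[:, ids[1], :]
    return np.linalg.norm(d, axis=1)


def dihedral(
    traj: Trajectory, topology: Topology, mol_id: int, quad: tuple
) -> np.ndarray:
    """Signed dihedral (degrees, in (−180, 180]) of four named atoms.

    Standard convention: the angle from plane (1,2,3) to plane (2,3,4),
    positive for a clockwise rotation looking down the 2→3 bond.
    """
    atoms = topology.atoms_of_molecule(mol_id)
    ids = []
    for nm in quad:
        hit = atoms[topology.names[atoms] == nm]
        if len(hit) == 0:
            raise ValueError(f"molecule {mol_id} has no atom named {nm!r}")
        ids.append(hit[0])
    p = traj.coords[:, ids, :]
    b1 = p[:, 1] - p[:, 0]
    b2 = p[:, 2] - p[:, 1]
    b3 = p[:, 3] - p[:, 2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=1, keepdims=True))
    x = (n1 * n2).sum(axis=1)
    y = (m1 * n2).sum(axis=1)
    ang = np.degrees(np.arctan2(y, x))
    ang[ang <= -180.0] += 360.0
    return ang


def conformation_map(
    x: np.ndarray,
    y: np.ndarray,
    x_bin_width: float = 0.25,
    y_bin_width: float = 1.0,
) -> Density2D:
    """Normalised 2-D frequency map of two frame-aligned series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must be frame-aligned")

    def edges(v, w):
        lo = np.floor(v.min() / w) * w
        hi = max(np.ceil(v.max() / w) * w, lo + w)
        return np.arange(lo, hi + 0.5 * w, w)

    xe, ye = edges(x, x_bin_width), edges(y, y_bin_width)
    h, _, _ = np.histogram2d(x, y, bins=(xe, ye))
    return Density2D(x_edges=xe, y_edges=ye, values=h / h.sum())
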
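"""Structure and trajectory file formats.

PDB (wwPDB v3.3 fixed columns) carries the topology plus one frame;
multi-frame XYZ carries coordinates at a declared precision of 6 decimals,
with box lengths and time stored on the comment line.  DCD reading/writing
is optional and delegates to MDAnalysis.  PDB cannot carry radii or
hydrogen-bond roles, so :func:`read_pdb` assigns radii from a configurable
element table and leaves donor/acceptor flags to
:func:`assign_hbond_roles`.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .constants import BONDI_RADII, DEFAULT_RADIUS
from .trajectory import Topology, Trajectory

__all__ = [
    "FormatError",
    "read_pdb",
    "write_pdb",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "read_dcd",
    "write_dcd",
    "assign_hbond_roles",
    "infer_element",
]

#: residue name -> molecule species label
RESNAME_SPECIES = {
    "CER": "lipid",
    "LIP": "lipid",
    "HOH": "water",
    "WAT": "water",
    "SOL": "water",
    "GUA": "guaiacyl-like",
    "SYR": "syringyl-like",
    "LIG": "derivative",
}

_TWO_LETTER = {"CL", "NA", "BR", "MG", "FE", "ZN", "LI", "RB", "CS"}


class FormatError(ValueError):
    """Malformed or inconsistent structure/trajectory file."""


def infer_element(name: str) -> str:
    """Element from an atom name's leading characters.

    Leading digits are stripped; a two-letter symbol is used only for
    unambiguous cases (Cl, Na, Br, ...), otherwise the first letter wins
    (so CA/CH/C1 are carbon, NF nitrogen, HO4 hydrogen).
    """
    s = name.strip().lstrip("0123456789")
    letters = "".join(c for c in s if c.isalpha()).upper()
    if not letters:
        raise FormatError(f"cannot infer element from atom name {name!r}")
    if letters[:2] in _TWO_LETTER:
        return letters[:2].capitalize()
    return letters[0]


def _radius_for(element: str, radius_table: Optional[dict]) -> float:
    table = dict(BONDI_RADII)
    if radius_table:
        table.update({k.upper(): v for k, v in radius_table.items()})
    return table.get(element.upper(), DEFAULT_RADIUS)


# ----------------------------------------------------------------------- PDB

def read_pdb(path, radius_table: Optional[dict] = None):
    """Read a PDB file -> (Topology, coords (n,3), box or None).

    Raises :class:`FormatError` on malformed ATOM/HETATM records (with line
    and column), duplicate serials, or zero atoms.
    """
    names, resnames, resids, elements, coords = [], [], [], [], []
    serials: set = set()
    box = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "CRYST1":
                try:
                    box = np.array([float(line[6:15]), float(line[15:24]), float(line[24:33])])
                except ValueError as exc:
                    raise FormatError(f"{path}: line {lineno}: bad CRYST1 record: {exc}") from None
            elif rec in ("ATOM  ", "HETATM"):
                try:
                    serial = int(line[6:11])
                except ValueError:
                    raise FormatError(f"{path}: line {lineno}, columns 7-11: bad atom serial") from None
                if serial in serials:
                    raise FormatError(f"{path}: line {lineno}: duplicate atom serial {serial}")
                serials.add(serial)
                name = line[12:16].strip()
                if not name:
                    raise FormatError(f"{path}: line {lineno}, columns 13-16: empty atom name")
                resname = line[17:21].strip()
                try:
                    resid = int(line[22:26])
                except ValueError:
                    raise FormatError(f"{path}: line {lineno}, columns 23-26: bad residue number") from None
                try:
                    xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                except ValueError:
                    raise FormatError(f"{path}: line {lineno}, columns 31-54: bad coordinates") from None
                element = line[76:78].strip() if len(line) >= 78 else ""
                if not element:
                    element = infer_element(name)
                names.append(name)
                resnames.append(resname)
                resids.append(resid)
                elements.append(element.capitalize())
                coords.append(xyz)
    if not names:
        raise FormatError(f"{path}: no ATOM/HETATM records")

    resids_arr = np.array(resids)
    resnames_arr = np.array(resnames)
    # one molecule per contiguous (resname, resid) run
    breaks = np.flatnonzero(
        (resids_arr[1:] != resids_arr[:-1]) | (resnames_arr[1:] != resnames_arr[:-1])
    )
    mol_ids = np.zeros(len(names), dtype=int)
    for b in breaks:
        mol_ids[b + 1 :] += 1
    mol_species = {}
    for m in np.unique(mol_ids):
        rn = resnames_arr[mol_ids == m][0]
        mol_species[int(m)] = RESNAME_SPECIES.get(rn.upper(), "derivative")

    n = len(names)
    topo = Topology(
        names=np.array(names),
        resnames=resnames_arr,
        resids=resids_arr,
        elements=np.array(elements),
        radii=np.array([_radius_for(e, radius_table) for e in elements]),
        donor=np.zeros(n, dtype=bool),
        acceptor=np.zeros(n, dtype=bool),
        bonded_h=[[] for _ in range(n)],
        mol_ids=mol_ids,
        mol_species=mol_species,
    )
    return topo, np.asarray(coords, dtype=float), box


def write_pdb(path, topology: Topology, coords: np.ndarray, box: Optional[np.ndarray] = None) -> None:
    coords = np.asarray(coords, dtype=float)
    with open(path, "w") as fh:
        if box is not None:
            fh.write(f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}"
                     f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n")
        for i in range(topology.n_atoms):
            name = str(topology.names[i])
            if len(name) > 4:
                raise FormatError(f"atom name {name!r} longer than 4 characters")
            # short names start in column 14 per the PDB convention
            fname = f" {name:<3s}" if len(name) < 4 else name
            serial = (i % 99999) + 1
            resid = int(topology.resids[i]) % 10000
            fh.write(
                f"ATOM  {serial:5d} {fname}"
                f" {str(topology.resnames[i])[:4]:<4s}{' '}{resid:4d}    "
                f"{coords[i,0]:8.3f}{coords[i,1]:8.3f}{coords[i,2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {str(topology.elements[i]):>2s}\n"
            )
        fh.write("END\n")


def assign_hbond_roles(topology: Topology, coords: np.ndarray, attach_cutoff: float = 1.25) -> Topology:
    """Flag O/N atoms as acceptors, and as donors when an intra-molecular
    hydrogen lies within ``attach_cutoff`` Å (that H is recorded as bonded).
    Mutates and returns ``topology``.
    """
    is_on = np.isin(topology.elements, ["O", "N"])
    is_h = topology.elements == "H"
    topology.acceptor[:] = is_on
    topology.donor[:] = False
    for i in np.flatnonzero(is_on):
        same_mol = topology.mol_ids == topology.mol_ids[i]
        cand = np.flatnonzero(same_mol & is_h)
        if cand.size:
            d = np.linalg.norm(coords[cand] - coords[i], axis=1)
            hs = cand[d <= attach_cutoff]
            if hs.size:
                topology.donor[i] = True
                topology.bonded_h[i] = [int(h) for h in hs]
    return topology


# ----------------------------------------------------------------------- XYZ

def write_xyz_trajectory(path, topology: Topology, traj: Trajectory) -> None:
    """Multi-frame XYZ at 6-decimal precision; box/time on the comment line."""
    with open(path, "w") as fh:
        for k in range(traj.n_frames):
            fh.write(f"{topology.n_atoms}\n")
            comment = f"frame={k} time={traj.times[k]:.6f}"
            if traj.box is not None:
                b = traj.box[k]
                comment += f" box={b[0]:.6f} {b[1]:.6f} {b[2]:.6f}"
            fh.write(comment + "\n")
            for i in range(topology.n_atoms):
                x, y, z = traj.coords[k, i]
                fh.write(f"{topology.names[i]:<4s} {x:14.6f} {y:14.6f} {z:14.6f}\n")


def read_xyz_trajectory(path, topology: Topology) -> Trajectory:
    """Read a multi-frame XYZ written by :func:`write_xyz_trajectory`.

    Frame atom counts must match the topology; a truncated final frame is
    rejected with its frame index.  An empty file is a valid zero-frame
    trajectory.
    """
    frames, boxes, times = [], [], []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    frame_idx = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].strip())
        except ValueError:
            raise FormatError(f"{path}: frame {frame_idx}: bad atom-count line {pos + 1}") from None
        if n != topology.n_atoms:
            raise FormatError(
                f"{path}: frame {frame_idx}: atom count {n} != topology ({topology.n_atoms})"
            )
        if pos + 2 + n > len(lines):
            raise FormatError(f"{path}: frame {frame_idx} truncated")
        comment = lines[pos + 1]
        t, box = _parse_xyz_comment(comment)
        xyz = np.empty((n, 3))
        for i in range(n):
            parts = lines[pos + 2 + i].split()
            if len(parts) < 4:
                raise FormatError(f"{path}: frame {frame_idx}, atom {i}: short coordinate line")
            xyz[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(xyz)
        boxes.append(box)
        times.append(t if t is not None else float(frame_idx))
        pos += 2 + n
        frame_idx += 1
    if not frames:
        return Trajectory(coords=np.zeros((0, topology.n_atoms, 3)))
    box_arr = None
    if all(b is not None for b in boxes):
        box_arr = np.array(boxes)
    return Trajectory(coords=np.array(frames), box=box_arr, times=np.array(times))


def _parse_xyz_comment(comment: str):
    t = None
    box = None
    for tok in comment.split():
        if tok.startswith("time="):
            t = float(tok[5:])
    if "box=" in comment:
        tail = comment.split("box=", 1)[1].split()
        box = np.array([float(tail[0]), float(tail[1]), float(tail[2])])
    return t, box


# ----------------------------------------------------------------------- DCD

def write_dcd(path, topology: Topology, traj: Trajectory) -> None:
    """Optional DCD output (requires MDAnalysis)."""
    import MDAnalysis as mda

    u = mda.Universe.empty(topology.n_atoms, trajectory=True)
    with mda.Writer(str(path), n_atoms=topology.n_atoms) as w:
        for k in range(traj.n_frames):
            u.atoms.positions = traj.coords[k]
            if traj.box is not None:
                u.dimensions = [*traj.box[k], 90.0, 90.0, 90.0]
            w.write(u.atoms)


def read_dcd(path, topology: Topology) -> Trajectory:
    """Optional DCD input (requires MDAnalysis)."""
    import MDAnalysis as mda
    from MDAnalysis.coordinates.DCD import DCDReader

    reader = DCDReader(str(path))
    frames, boxes = [], []
    for ts in reader:
        if ts.positions.shape[0] != topology.n_atoms:
            raise FormatError(
                f"{path}: frame {ts.frame}: atom count {ts.positions.shape[0]} "
                f"!= topology ({topology.n_atoms})"
            )
        frames.append(ts.positions.astype(float).copy())
        boxes.append(None if ts.dimensions is None else ts.dimensions[:3].astype(float).copy())
    if not frames:
        return Trajectory(coords=np.zeros((0, topology.n_atoms, 3)))
    box_arr = np.array(boxes) if all(b is not None for b in boxes) else None
    return Trajectory(coords=np.array(frames), box=box_arr)
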
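"""Shrake–Rupley solvent-accessible surface area.

For each atom, test points are spread on the sphere of radius
r_vdw + probe by a deterministic golden-section spiral; the accessible
area is the exposed point fraction times 4π(r+probe)².  The point set is
seed-free, so results are exactly reproducible and converge monotonically
in expectation as the point count grows.  Occluders default to all
non-water atoms.  Distances are non-periodic (analysis scenes keep whole
molecules inside the box).
"""

from __future__ import annotations

from typing import Sequence, Union

import numpy as np
from scipy.spatial import cKDTree

from .trajectory import Selection, Topology, select

__all__ = ["sphere_points", "sasa"]


def sphere_points(n: int) -> np.ndarray:
    """n unit vectors on a golden-section spiral (deterministic)."""
    if n < 1:
        raise ValueError("need at least one sphere point")
    k = np.arange(n) + 0.5
    z = 1.0 - 2.0 * k / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * k
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(
    frame: np.ndarray,
    topology: Topology,
    subset: Union[Selection, np.ndarray, Sequence[int], None] = None,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    occluders: Union[Selection, np.ndarray, Sequence[int], None] = None,
) -> tuple[dict, dict]:
    """Per-atom and per-molecule solvent-accessible areas (Å²).

    Returns ``(per_atom, per_molecule)`` dicts keyed by atom id and
    molecule id.  ``subset`` defaults to all non-water atoms; so do the
    occluding spheres.
    """
    frame = np.asarray(frame, dtype=float)
    species = topology.species_per_atom()
    if subset is None:
        subset_ids = np.flatnonzero(species != "water")
    elif isinstance(subset, Selection):
        subset_ids = select(topology, frame, subset)
    else:
        subset_ids = np.asarray(subset, dtype=int)
    if occluders is None:
        occ_ids = np.flatnonzero(species != "water")
    elif isinstance(occluders, Selection):
        occ_ids = select(topology, frame, occluders)
    else:
        occ_ids = np.asarray(occluders, dtype=int)

    radii = topology.radii
    if not np.all(np.isfinite(radii[subset_ids])) or np.any(radii[subset_ids] <= 0):
        raise ValueError("every subset atom needs a positive vdW radius")

    pts = sphere_points(n_sphere_points)
    occ_xyz = frame[occ_ids]
    occ_r = radii[occ_ids] + probe_radius
    tree = cKDTree(occ_xyz)
    max_occ_r = occ_r.max() if len(occ_ids) else 0.0

    per_atom: dict = {}
    per_mol: dict = {}
    for a in subset_ids:
        ra = radii[a] + probe_radius
        surf = frame[a] + ra * pts
        # any occluder within max reach of any surface point
        neigh = tree.query_ball_point(frame[a], ra + max_occ_r)
        neigh = [j for j in neigh if occ_ids[j] != a]
        exposed = np.ones(n_sphere_points, dtype=bool)
        for j in neigh:
            d2 = ((surf - occ_xyz[j]) ** 2).sum(axis=1)
            exposed &= d2 > occ_r[j] ** 2
            if not exposed.any():
                break
        area = 4.0 * np.pi * ra * ra * exposed.sum() / n_sphere_points
        per_atom[int(a)] = float(area)
        m = int(topology.mol_ids[a])
        per_mol[m] = per_mol.get(m, 0.0) + float(area)
    return per_atom, per_mol
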
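"""Distance series, profiles, densities and conformational observables."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ligmem.dynamics import LangevinParams, simulate_langevin_1d
from ligmem.observables import (
    Profile,
    com_z_distance,
    conformation_map,
    distance_distribution,
    dihedral,
    end_to_end,
    hbond_distribution,
    hbond_vs_z,
    number_density_profile,
    running_average,
)
from ligmem.potentials import PotentialSpec
from ligmem.scene import SceneSpec, build_bilayer_scene
from ligmem.trajectory import Selection, Topology, Trajectory


def _single_atom_topology(n, species="derivative"):
    return Topology(
        names=np.array([f"A{i}" for i in range(n)]),
        resnames=np.array(["LIG"] * n),
        resids=np.arange(1, n + 1),
        elements=np.array(["C"] * n),
        radii=np.full(n, 1.7),
        donor=np.zeros(n, dtype=bool),
        acceptor=np.zeros(n, dtype=bool),
        bonded_h=[[] for _ in range(n)],
        mol_ids=np.arange(n),
        mol_species={i: species for i in range(n)},
    )


# ------------------------------------------------------------------ com_z

def test_com_z_simple_arithmetic():
    topo = _single_atom_topology(2)
    coords = np.array([[[0.0, 0.0, 30.0], [0.0, 0.0, 20.0]]])
    traj = Trajectory(coords=coords)
    out = com_z_distance(traj, topo, [0], [1])
    assert out[0] == pytest.approx(10.0)  # solute above the reference plane


def test_com_z_identity_is_zero():
    topo = _single_atom_topology(1)
    traj = Trajectory(coords=np.random.default_rng(0).normal(size=(4, 1, 3)))
    assert np.allclose(com_z_distance(traj, topo, [0], [0]), 0.0)


def test_com_z_recovers_scripted_path():
    pot = PotentialSpec.flat((20.0, 40.0))
    par = LangevinParams(D=50.0, T=300.0, dt=1e-4)
    paths = [simulate_langevin_1d(pot, par, 500, 30.0, seed=i, record_stride=100)
             for i in range(9)]
    spec = SceneSpec(box=(60.0, 60.0, 70.0), n_lipids_per_leaflet=16,
                     water_number_density=0.0, solute_grid=3,
                     lattice_jitter=0.0, seed=2)
    topo, traj = build_bilayer_scene(spec, paths=paths)
    sel_ref = Selection.parse("name:NF leaflet:upper")
    mols = topo.molecules_of_species("guaiacyl-like")
    series = com_z_distance(traj, topo, topo.atoms_of_molecule(mols[0]), sel_ref)
    # jitter off: reference plane sits exactly at +20 Å
    assert np.allclose(series, paths[0].z - 20.0, atol=1e-9)


def test_com_z_empty_selection_reports_frame():
    topo = _single_atom_topology(1)
    traj = Trajectory(coords=np.zeros((3, 1, 3)))
    with pytest.raises(ValueError, match="frame 0"):
        com_z_distance(traj, topo, np.array([], dtype=int), [0])


# --------------------------------------------------------------- running avg

def test_running_average_constant_and_window_one():
    s = np.full(20, 3.7)
    assert np.allclose(running_average(s, 5), 3.7)
    r = np.random.default_rng(1).normal(size=20)
    assert np.allclose(running_average(r, 1), r)


def test_running_average_matches_brute_force():
    rng = np.random.default_rng(2)
    s = rng.normal(size=50)
    w = 5
    got = running_average(s, w)
    h = w // 2
    expected = np.array([s[max(0, i - h): min(len(s), i + h + 1)].mean() for i in range(len(s))])
    assert np.allclose(got, expected)


def test_running_average_window_too_long():
    with pytest.raises(ValueError):
        running_average(np.zeros(5), 7)


# ------------------------------------------------------------- distributions

def test_distance_distribution_single_bin():
    prof = distance_distribution(np.full(100, 4.2), bin_width=0.5)
    occupied = prof.values > 0
    assert occupied.sum() == 1
    assert prof.values[occupied][0] == pytest.approx(1 / 0.5)
    assert prof.integral() == pytest.approx(1.0, abs=1e-12)


def test_distance_distribution_two_planted_modes():
    rng = np.random.default_rng(3)
    s = np.concatenate([rng.normal(5.5, 0.15, 4000), rng.normal(8.0, 0.15, 4000)])
    prof = distance_distribution(s, bin_width=0.25)
    # find local maxima
    v = prof.values
    peaks = [prof.centers[i] for i in range(1, len(v) - 1) if v[i] >= v[i - 1] and v[i] >= v[i + 1] and v[i] > 0.2]
    assert any(abs(p - 5.5) <= 0.25 for p in peaks)
    assert any(abs(p - 8.0) <= 0.25 for p in peaks)


def test_distance_distribution_uniform_is_flat():
    rng = np.random.default_rng(4)
    s = rng.uniform(0, 10, 100_000)
    prof = distance_distribution(s, bin_width=1.0, value_range=(0, 10))
    assert np.allclose(prof.values, 0.1, atol=4 * np.sqrt(0.1 * 0.9 / 10_000))


def test_distance_distribution_empty_series():
    with pytest.raises(ValueError):
        distance_distribution(np.array([]))


@given(st.lists(st.floats(-50, 50), min_size=1, max_size=200),
       st.sampled_from([0.25, 0.5, 1.0, 2.0]))
def test_probability_density_always_integrates_to_one(samples, width):
    prof = distance_distribution(np.array(samples), bin_width=width)
    assert abs(prof.integral() - 1.0) <= 1e-9


# ------------------------------------------------------------------ density

def test_density_counts_sum_rule_exact(small_scene):
    _, topo, traj = small_scene
    sel = Selection(species=frozenset({"water"}))
    prof = number_density_profile(traj, topo, sel, bin_width=0.5, mode="counts")
    n_water = len(topo.molecules_of_species("water"))
    assert prof.values.sum() == pytest.approx(n_water, abs=1e-12)


def test_density_planted_headgroup_peaks(small_scene):
    _, topo, traj = small_scene
    prof = number_density_profile(traj, topo, Selection(names=frozenset({"NF"})),
                                  bin_width=0.5)
    peak_up = prof.centers[prof.values.argmax()]
    sym = number_density_profile(traj, topo, Selection(names=frozenset({"NF"})),
                                 bin_width=0.5, symmetrize=True)
    assert abs(abs(peak_up) - 20.0) <= 0.5
    assert np.allclose(sym.values, sym.values[::-1])


def test_density_uniform_slab_flat_within_poisson(small_scene):
    spec, topo, traj = small_scene
    sel = Selection(species=frozenset({"water"}), z_range=(23.0, 32.0))
    prof = number_density_profile(traj, topo, sel, bin_width=1.0)
    vals = prof.values[(prof.centers > 23.5) & (prof.centers < 31.5)]
    expect = spec.water_number_density
    per_bin = expect * spec.box[0] * spec.box[1] * 1.0
    tol = 4 * np.sqrt(per_bin / traj.n_frames) / (spec.box[0] * spec.box[1])
    assert np.allclose(vals, expect, atol=tol)


def test_density_requires_box():
    topo = _single_atom_topology(3)
    traj = Trajectory(coords=np.zeros((1, 3, 3)))
    with pytest.raises(ValueError, match="box"):
        number_density_profile(traj, topo, np.arange(3))


# ----------------------------------------------------------------- hbond map

def test_hbond_distribution_and_joint_map_marginal():
    rng = np.random.default_rng(5)
    counts = rng.integers(0, 5, 400)
    z = rng.normal(0.0, 3.0, 400)
    dist = hbond_distribution(counts)
    assert dist.integral() == pytest.approx(1.0, abs=1e-12)
    joint = hbond_vs_z(counts, z, z_bin_width=1.0)
    marg = joint.values.sum(axis=1) / 1.0
    zprof = distance_distribution(z, bin_width=1.0,
                                  value_range=(joint.x_edges[0], joint.x_edges[-1]))
    assert np.allclose(marg, zprof.values, atol=1e-12)


def test_hbond_vs_z_single_cell_when_pinned():
    counts = np.full(50, 2)
    z = np.full(50, 4.2)
    joint = hbond_vs_z(counts, z, z_bin_width=1.0)
    assert (joint.values > 0).sum() == 1
    assert joint.values.max() == pytest.approx(1.0)


def test_hbond_vs_z_length_mismatch():
    with pytest.raises(ValueError, match="mismatch"):
        hbond_vs_z(np.zeros(3), np.zeros(4))


# --------------------------------------------------------------- conformers

def test_end_to_end_three_four_five():
    topo = Topology(
        names=np.array(["O4", "O9"]), resnames=np.array(["GUA"] * 2),
        resids=np.array([1, 1]), elements=np.array(["O", "O"]),
        radii=np.full(2, 1.52), donor=np.zeros(2, bool), acceptor=np.zeros(2, bool),
        bonded_h=[[], []], mol_ids=np.zeros(2, int), mol_species={0: "guaiacyl-like"},
    )
    traj = Trajectory(coords=np.array([[[0, 0, 0], [3, 4, 0]]], dtype=float))
    assert end_to_end(traj, topo, 0)[0] == pytest.approx(5.0)


def _quad_topology():
    return Topology(
        names=np.array(["A", "B", "C", "D"]), resnames=np.array(["LIG"] * 4),
        resids=np.ones(4, int), elements=np.array(["C"] * 4),
        radii=np.full(4, 1.7), donor=np.zeros(4, bool), acceptor=np.zeros(4, bool),
        bonded_h=[[] for _ in range(4)], mol_ids=np.zeros(4, int),
        mol_species={0: "derivative"},
    )


@pytest.mark.parametrize(
    "p4,expected",
    [(np.array([3.0, 1.0, 0.0]), 180.0), (np.array([3.0, -1.0, 0.0]), 0.0)],
)
def test_dihedral_defining_cases(p4, expected):
    topo = _quad_topology()
    coords = np.array([[[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [2.0, 0.0, 0.0], p4]])
    ang = dihedral(Trajectory(coords=coords), topo, 0, ("A", "B", "C", "D"))[0]
    assert abs(ang) == pytest.approx(expected, abs=1e-9) or ang == pytest.approx(expected, abs=1e-9)


def test_rigid_motion_leaves_internal_coordinates_unchanged():
    topo = _quad_topology()
    rng = np.random.default_rng(6)
    base = rng.normal(size=(4, 3))
    # random rotation via QR
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    moved = base @ q.T + np.array([5.0, -3.0, 11.0])
    traj = Trajectory(coords=np.stack([base, moved]))
    e = end_to_end(traj, topo, 0, ("A", "D"))
    d = dihedral(traj, topo, 0, ("A", "B", "C", "D"))
    assert e[0] == pytest.approx(e[1], abs=1e-9)
    assert d[0] == pytest.approx(d[1], abs=1e-9)


def test_missing_atom_name_raises():
    topo = _quad_topology()
    traj = Trajectory(coords=np.zeros((1, 4, 3)))
    with pytest.raises(ValueError, match="no atom named"):
        end_to_end(traj, topo, 0, ("A", "Z"))


def test_conformation_map_recovers_two_state_mixture():
    spec = SceneSpec(box=(60.0, 60.0, 70.0), n_lipids_per_leaflet=9,
                     water_number_density=0.0, solute_grid=3, n_frames=400, seed=9)
    topo, traj = build_bilayer_scene(spec)
    mols = topo.molecules_of_species("guaiacyl-like")
    tpl = spec.solute_template
    ree = np.concatenate([end_to_end(traj, topo, m, tpl.terminal_pair) for m in mols])
    zs = np.concatenate([np.full(traj.n_frames, 28.0) for _ in mols])
    cmap = conformation_map(ree, zs, x_bin_width=0.25, y_bin_width=1.0)
    profile = cmap.values.sum(axis=1)
    centers = cmap.x_centers
    near_55 = profile[np.abs(centers - 5.5) <= 0.25].max()
    near_80 = profile[np.abs(centers - 8.0) <= 0.25].max()
    away = profile[(np.abs(centers - 5.5) > 0.5) & (np.abs(centers - 8.0) > 0.5)]
    # both planted modes dominate everything off-mode, within one bin
    assert near_55 > away.max() and near_80 > away.max()
    assert cmap.values.sum() == pytest.approx(1.0, abs=1e-12)


def test_profile_invariant_rejects_bad_density():
    with pytest.raises(ValueError, match="integrates"):
        Profile(centers=np.array([0.0, 1.0]), values=np.array([1.0, 1.0]),
                bin_width=1.0, mode="probability_density")
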
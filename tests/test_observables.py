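import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from gbnet import (
    AtomRecord,
    MolecularStructure,
    Selection,
    Trajectory,
    centroid_distance,
    contact_number,
    detect_hbonds,
    extract_snapshots,
    kabsch_superpose,
    make_ring_pair,
    plane_angle,
    radius_of_gyration,
    rmsd_series,
    rmsf,
)
from gbnet.observables import DegenerateFitError, SelectionError, active_site_selection
from gbnet.synth import FixtureSpec, make_complex_fixture, make_trajectory


def _random_rigid(rng):
    rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    trans = rng.uniform(-20, 20, 3)
    return rot, trans


# ---------------------------------------------------------------------------
# Kabsch

def test_kabsch_identity_and_translation(rng):
    pts = rng.uniform(-5, 5, (10, 3))
    _, _, r0 = kabsch_superpose(pts, pts)
    assert r0 == pytest.approx(0.0, abs=1e-12)
    _, _, r1 = kabsch_superpose(pts + np.array([5.0, -2.0, 7.0]), pts)
    assert r1 == pytest.approx(0.0, abs=1e-9)


def test_kabsch_rejects_degenerate_sets():
    line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
    with pytest.raises(DegenerateFitError):
        kabsch_superpose(line, line + 0.1)
    with pytest.raises(DegenerateFitError):
        kabsch_superpose(line[:2], line[:2])


def test_kabsch_returns_proper_rotation(rng):
    a = rng.uniform(-5, 5, (6, 3))
    b = -a  # a mirror image tempts an improper solution
    rot, _, _ = kabsch_superpose(a, b)
    assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)


def _rmsd_under_rotation(rotvec, mobile_c, ref_c):
    rot = Rotation.from_rotvec(rotvec).as_matrix()
    return float(np.sqrt(np.mean(np.sum((mobile_c @ rot.T - ref_c) ** 2, axis=1))))


def test_kabsch_matches_quaternion_grid_oracle(rng):
    """Brute-force minimum over rotations equals the Kabsch RMSD."""
    mobile = np.array([[0.0, 0, 0], [2, 0, 0], [0, 3, 0], [1, 1, 2]])
    rot, trans = _random_rigid(rng)
    reference = mobile @ rot.T + trans + rng.normal(0, 0.3, mobile.shape)
    _, _, rmsd = kabsch_superpose(mobile, reference)
    mc = mobile - mobile.mean(0)
    rc = reference - reference.mean(0)
    quats = Rotation.random(20000, random_state=7)
    vals = [
        _rmsd_under_rotation(q.as_rotvec(), mc, rc) for q in quats
    ]
    best = quats[int(np.argmin(vals))].as_rotvec()
    res = minimize(
        _rmsd_under_rotation, best, args=(mc, rc), method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
    )
    assert rmsd == pytest.approx(res.fun, abs=1e-6)


def test_rmsd_invariant_under_common_rigid_transforms(rng):
    pts = rng.uniform(-5, 5, (12, 3))
    other = pts + rng.normal(0, 0.5, pts.shape)
    _, _, base = kabsch_superpose(pts, other)
    for _ in range(50):
        rot, trans = _random_rigid(rng)
        _, _, r = kabsch_superpose(pts @ rot.T + trans, other @ rot.T + trans)
        assert r == pytest.approx(base, abs=1e-9)


# ---------------------------------------------------------------------------
# RMSD series / RMSF

def test_rmsd_series_zero_for_quiet_trajectory(small_system):
    spec, structure, params, _ = small_system
    quiet = FixtureSpec(
        **{**spec.__dict__, "fluctuation_profile": tuple([0.0] * spec.n_residues)}
    )
    traj = make_trajectory(structure, quiet, 4, 100.0)
    series = rmsd_series(traj, params=params)
    np.testing.assert_allclose(series.values, 0.0, atol=1e-9)


def test_rmsd_series_consistent_with_kabsch(small_traj, small_system):
    _, structure, params, _ = small_system
    ca = Selection.ca() & Selection.receptor()
    series = rmsd_series(small_traj, fit_selection=ca, params=params)
    idx = ca.resolve(structure, params)
    ref = small_traj.template.coordinates
    for frame, value in zip(small_traj.frames, series.values):
        _, _, r = kabsch_superpose(frame[idx], ref[idx])
        assert value == pytest.approx(r, abs=1e-9)


def test_rmsd_series_matches_scipy_align_vectors(small_traj, small_system):
    """Independent recomputation via scipy's rotational alignment."""
    _, structure, params, _ = small_system
    ca = Selection.ca() & Selection.receptor()
    idx = ca.resolve(structure, params)
    series = rmsd_series(small_traj, fit_selection=ca, params=params)
    ref = small_traj.template.coordinates[idx]
    for frame, value in zip(small_traj.frames, series.values):
        mob = frame[idx]
        rot, _ = Rotation.align_vectors(ref - ref.mean(0), mob - mob.mean(0))
        fitted = (mob - mob.mean(0)) @ rot.as_matrix().T
        r = np.sqrt(np.mean(np.sum((fitted - (ref - ref.mean(0))) ** 2, axis=1)))
        assert value == pytest.approx(r, abs=1e-7)


def test_empty_selection_errors(small_traj, small_system):
    _, _, params, _ = small_system
    with pytest.raises(SelectionError):
        rmsd_series(small_traj, fit_selection=Selection.atom_name("XX"), params=params)


def test_rmsf_zero_for_rigid_motion(small_system, rng):
    """Per-frame rigid transforms of one structure give zero RMSF."""
    _, structure, params, _ = small_system
    base = structure.coordinates
    frames, times = [], []
    for k in range(6):
        rot, trans = _random_rigid(rng)
        frames.append(base @ rot.T + trans)
        times.append(float(k + 1))
    traj = Trajectory(frames=frames, times=times, template=structure)
    df = rmsf(traj, Selection.ca() & Selection.receptor(), params)
    np.testing.assert_allclose(df["rmsf"], 0.0, atol=1e-9)


def test_rmsf_invariant_under_per_frame_rigid_transforms(small_system, rng):
    spec, structure, params, _ = small_system
    traj = make_trajectory(structure, spec, 20, 100.0)
    sel = Selection.ca() & Selection.receptor()
    base_df = rmsf(traj, sel, params)
    frames = []
    for f in traj.frames:
        rot, trans = _random_rigid(rng)
        frames.append(f @ rot.T + trans)
    moved = Trajectory(frames=frames, times=list(traj.times), template=structure)
    moved_df = rmsf(moved, sel, params)
    np.testing.assert_allclose(moved_df["rmsf"], base_df["rmsf"], atol=1e-8)


def test_rmsf_needs_two_frames(small_system):
    _, structure, params, _ = small_system
    traj = Trajectory(
        frames=[structure.coordinates], times=[1.0], template=structure
    )
    with pytest.raises(ValueError):
        rmsf(traj, params=params)


# ---------------------------------------------------------------------------
# radius of gyration

def test_rg_closed_forms():
    assert radius_of_gyration(np.zeros((1, 3))) == pytest.approx(0.0)
    two = np.array([[0.0, 0, 0], [2.0, 0, 0]])
    assert radius_of_gyration(two) == pytest.approx(1.0, abs=1e-12)


def test_rg_matches_direct_formula(rng):
    xyz = rng.uniform(-10, 10, (50, 3))
    masses = rng.uniform(1, 16, 50)
    com = (masses[:, None] * xyz).sum(0) / masses.sum()
    expected = np.sqrt(
        sum(m * np.dot(p - com, p - com) for m, p in zip(masses, xyz)) / masses.sum()
    )
    assert radius_of_gyration(xyz, masses=masses) == pytest.approx(expected, abs=1e-9)


def test_rg_zero_mass_errors():
    with pytest.raises(ValueError):
        radius_of_gyration(np.zeros((2, 3)), masses=np.zeros(2))


# ---------------------------------------------------------------------------
# contacts

def test_contact_number_far_ligand_zero(small_system):
    spec, structure, params, _ = small_system
    apo = FixtureSpec(**{**spec.__dict__, "bound": False})
    s, p, _ = make_complex_fixture(apo)
    n = contact_number(
        s.coordinates, s, Selection.ca(), Selection.ligand(), 6.0, p
    )
    assert n == 0


def test_contact_number_constructed_case():
    atoms = []
    for i in range(3):
        atoms.append(
            AtomRecord(i + 1, "CA", "C", "LEU", i + 1, "A", np.array([3.0, 0, i * 100.0]))
        )
    atoms.append(AtomRecord(4, "C1", "C", "LIG", 9, "L", np.array([0.0, 0, 0])))
    atoms.append(AtomRecord(5, "C1", "C", "LIG", 9, "L", np.array([0.0, 0, 100.0])))
    atoms.append(AtomRecord(6, "C1", "C", "LIG", 9, "L", np.array([0.0, 0, 200.0])))
    s = MolecularStructure(atoms)
    n = contact_number(
        s.coordinates, s, Selection.ca(), Selection.chain("L"), 6.0
    )
    assert n == 3


def test_contact_number_matches_bruteforce(bound_system, bound_traj):
    _, structure, params, _ = bound_system
    rec_sel = Selection.ca() & Selection.hydrophobic()
    lig_sel = Selection.ligand() & Selection.heavy()
    rec = rec_sel.resolve(structure, params)
    lig = [i for i in lig_sel.resolve(structure, params)
           if structure.atoms[i].element != "H"]
    for frame in bound_traj.frames[:10]:
        expected = 0
        for i in rec:
            if any(np.linalg.norm(frame[i] - frame[j]) < 6.0 for j in lig):
                expected += 1
        got = contact_number(frame, structure, rec_sel, lig_sel, 6.0, params)
        assert got == expected


def test_contact_cutoff_must_be_positive(bound_system):
    _, structure, params, _ = bound_system
    with pytest.raises(ValueError):
        contact_number(
            structure.coordinates, structure, Selection.ca(), Selection.ligand(),
            0.0, params,
        )


# ---------------------------------------------------------------------------
# ring geometry

def test_plane_angle_complement_identity(rng):
    for _ in range(50):
        xyz = make_ring_pair(
            angle=float(rng.uniform(0, 180)), centroid_distance=3.8
        ).coordinates
        rot, trans = _random_rigid(rng)
        a = xyz[:6] @ rot.T + trans
        b = xyz[6:] @ rot.T + trans
        assert plane_angle(a, b) + plane_angle(a, b[::-1]) == pytest.approx(
            180.0, abs=1e-9
        )


def test_plane_angle_coplanar_same_sense_zero():
    hexa = make_ring_pair(angle=0.0, centroid_distance=4.0).coordinates
    assert plane_angle(hexa[:6], hexa[6:]) == pytest.approx(0.0, abs=1e-9)


def test_plane_angle_collinear_rejected():
    line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
    with pytest.raises(DegenerateFitError):
        plane_angle(line, line)


def test_centroid_distance_values(small_system):
    spec, structure, params, _ = small_system
    xyz = make_ring_pair(angle=20.0, centroid_distance=3.8).coordinates
    assert centroid_distance(xyz[:6], xyz[6:]) == pytest.approx(3.8, abs=1e-9)
    assert centroid_distance(xyz[:6], xyz[:6]) == pytest.approx(0.0)
    # per-frame values match independent recomputation on a fixture trajectory
    traj = make_trajectory(structure, spec, 10, 100.0)
    ga = [params.ligand_selection[i] for i in spec.ligand_rings[0]]
    gb = [params.ligand_selection[i] for i in spec.ligand_rings[1]]
    for f in traj.frames:
        expected = np.linalg.norm(f[ga].mean(0) - f[gb].mean(0))
        assert centroid_distance(f[ga], f[gb]) == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# hydrogen bonds

def _hbond_structure(da_dist):
    """Donor N with H on the x-axis pointing at acceptor O."""
    atoms = [
        AtomRecord(1, "N", "N", "ALA", 1, "A", np.array([0.0, 0, 0])),
        AtomRecord(2, "H", "H", "ALA", 1, "A", np.array([1.0, 0, 0])),
        AtomRecord(3, "O", "O", "LIG", 2, "L", np.array([da_dist, 0, 0])),
        AtomRecord(4, "C", "C", "LIG", 2, "L", np.array([da_dist + 1.2, 0, 0])),
    ]
    return MolecularStructure(atoms)


def test_hbond_inside_thresholds():
    s = _hbond_structure(2.8)
    bonds = detect_hbonds(
        s.coordinates, s, Selection.atom_name("N"), Selection.atom_name("O")
    )
    assert bonds == [(0, 2)]


def test_hbond_outside_distance():
    s = _hbond_structure(4.0)
    bonds = detect_hbonds(
        s.coordinates, s, Selection.atom_name("N"), Selection.atom_name("O")
    )
    assert bonds == []


def test_hbond_donor_without_hydrogen_warns():
    atoms = [
        AtomRecord(1, "N", "N", "ALA", 1, "A", np.array([0.0, 0, 0])),
        AtomRecord(2, "O", "O", "LIG", 2, "L", np.array([2.8, 0, 0])),
    ]
    s = MolecularStructure(atoms)
    with pytest.warns(UserWarning, match="no attached hydrogen"):
        bonds = detect_hbonds(
            s.coordinates, s, Selection.atom_name("N"), Selection.atom_name("O")
        )
    assert bonds == []


def test_hbonds_match_bruteforce_scan(rng):
    """Randomly placed donors/acceptors: detection equals an O(n^2) scan."""
    atoms = []
    serial = 1
    for r in range(8):
        pos = rng.uniform(-4, 4, 3)
        atoms.append(AtomRecord(serial, "N", "N", "GLY", r + 1, "A", pos))
        serial += 1
        h = pos + rng.normal(0, 1, 3)
        h = pos + (h - pos) / np.linalg.norm(h - pos) * 1.0
        atoms.append(AtomRecord(serial, "H", "H", "GLY", r + 1, "A", h))
        serial += 1
    for r in range(8, 14):
        atoms.append(
            AtomRecord(serial, "O", "O", "HOH", r + 1, "B", rng.uniform(-4, 4, 3))
        )
        serial += 1
    s = MolecularStructure(atoms)
    xyz = s.coordinates
    donors = Selection.atom_name("N")
    acceptors = Selection.atom_name("O")
    got = set(detect_hbonds(xyz, s, donors, acceptors))
    expected = set()
    for d in donors.resolve(s):
        hs = [
            i for i in s.residue_index[(s.atoms[d].chain, s.atoms[d].residue_id)]
            if s.atoms[i].element == "H"
            and np.linalg.norm(xyz[i] - xyz[d]) <= 1.25
        ]
        for a in acceptors.resolve(s):
            if np.linalg.norm(xyz[a] - xyz[d]) > 3.5:
                continue
            for h in hs:
                v1, v2 = xyz[d] - xyz[h], xyz[a] - xyz[h]
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= 135.0:
                    expected.add((d, a))
                    break
    assert got == expected


# ---------------------------------------------------------------------------
# snapshots

def _flat_trajectory(n, dt):
    atoms = [
        AtomRecord(i + 1, "CA", "C", "GLY", i + 1, "A", np.array([float(i), 0, 0]))
        for i in range(4)
    ]
    s = MolecularStructure(atoms)
    return Trajectory(
        frames=[s.coordinates + k for k in range(n)],
        times=[dt * (k + 1) for k in range(n)],
        template=s,
    )


def test_snapshot_rule_yields_1000():
    """200,000 ps window at 200 ps spacing gives exactly 1000 snapshots."""
    traj = _flat_trajectory(1000, 200.0)
    snaps = extract_snapshots(traj, 0.0, 200_000.0, 200.0)
    assert len(snaps) == 1000


def test_snapshot_arithmetic_and_boundary():
    traj = _flat_trajectory(20, 1000.0)
    assert len(extract_snapshots(traj, 0.0, 10_000.0, 1000.0)) == 10
    one = extract_snapshots(traj, 1000.0, 2000.0, 1000.0)
    assert len(one) == 1 and one.times == [2000.0]


def test_snapshot_empty_window_errors():
    traj = _flat_trajectory(5, 100.0)
    with pytest.raises(ValueError):
        extract_snapshots(traj, 100.0, 150.0, 100.0)


def test_active_site_selection(bound_system):
    _, structure, params, manifest = bound_system
    sel = active_site_selection(structure, params, radius=5.0)
    resids = sorted({structure.atoms[i].residue_id for i in sel.resolve(structure, params)})
    assert resids  # the pocket is populated
    assert set(resids) <= set(manifest.nearest_residues)


def test_selection_parser(bound_system):
    _, structure, params, _ = bound_system
    ca = Selection.parse("ca & receptor").resolve(structure, params)
    assert len(ca) == 100
    lig = Selection.parse("ligand & heavy").resolve(structure, params)
    assert lig == params.ligand_selection
    both = Selection.parse("resid 1-3 & name CA").resolve(structure, params)
    assert len(both) == 3
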
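"""Seeded synthetic receptor-ligand systems and pseudo-trajectories.

The generator emulates the statistical structure the downstream analyses
assume, at toy scale: a compact ~100-residue receptor traced as a coarse
two-atoms-per-residue chain (Calpha plus a pseudo-sidechain) wrapped on a
sphere with an open polar cap forming a concave ligand pocket; a
small-molecule ligand built around two stacked aromatic six-rings; and
pseudo-trajectories whose per-residue fluctuation amplitudes are controlled
inputs, so parameter-recovery tests have ground truth.  Two "loop" segments
of the chain play the role of the pocket-flanking flexible loops: their
fluctuation scale is high in the apo state and reduced in the holo state
(ligand-bound rigidification).

Displacements are i.i.d. Gaussian per frame and per coordinate — the
observables under test are time-marginal statistics, so autocorrelation is
deliberately absent.  Randomness comes from numpy's seeded PCG64 generator;
the seed is recorded in the manifest.  Determinism is bitwise within one
platform/numpy version; across implementations only statistical agreement
is promised.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np

from .io import AtomRecord, MolecularStructure, TopologyParams, Trajectory

__all__ = [
    "FixtureSpec",
    "FixtureManifest",
    "HYDROPHOBIC_RESIDUES",
    "make_complex_fixture",
    "make_trajectory",
    "make_ring_pair",
]

HYDROPHOBIC_RESIDUES = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP"}
)

_AMINO_ACIDS = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()

_BOND_LENGTH = 1.4          # aromatic C-C, A
_CA_SPACING = 3.8           # consecutive Calpha arc spacing, A
_TURN_SPACING = 4.6         # spacing between spiral turns, A
_CAP_ANGLE = 0.45           # open polar cap half-angle, rad (the pocket mouth)
_POCKET_CLEARANCE = 4.2     # minimum bound receptor-ligand distance, A
                            # (just outside the LJ minimum: attractive, no clash)
_UNBOUND_PLACEMENT = 110.0  # target receptor-ligand separation when unbound, A
_UNBOUND_MINIMUM = 100.0    # enforced minimum unbound distance, A (>= the
                            # 50 A contract, far enough that multipole
                            # electrostatic tails are negligible)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic receptor-ligand system."""

    n_residues: int = 100
    loop_spans: tuple[tuple[int, int], tuple[int, int]] | None = None
    ligand_n_atoms: int = 16
    ligand_rings: tuple[tuple[int, ...], tuple[int, ...]] = (
        (0, 1, 2, 3, 4, 5),
        (6, 7, 8, 9, 10, 11),
    )
    fluctuation_profile: tuple[float, ...] = ()
    bound: bool = True
    seed: int = 0
    ring_angle: float = 40.0            # deg, at construction
    ring_centroid_distance: float = 3.8  # A, at construction

    def __post_init__(self) -> None:
        if self.loop_spans is None:
            # pocket-flanking segments near the mouth, scaled to chain length
            n = self.n_residues
            a0 = max(round(0.04 * n), 1)
            a1 = max(round(0.18 * n), a0 + 1)
            b0 = max(round(0.22 * n), a1 + 2)
            b1 = max(round(0.36 * n), b0 + 1)
            object.__setattr__(self, "loop_spans", ((a0, a1), (b0, b1)))
        (a0, a1), (b0, b1) = self.loop_spans
        if not (1 <= a0 <= a1 <= self.n_residues and 1 <= b0 <= b1 <= self.n_residues):
            raise ValueError("loop_spans must lie within [1, n_residues]")
        if not (a1 < b0 or b1 < a0):
            raise ValueError("loop_spans must be disjoint")
        ring_atoms = set(self.ligand_rings[0]) | set(self.ligand_rings[1])
        if len(ring_atoms) != len(self.ligand_rings[0]) + len(self.ligand_rings[1]):
            raise ValueError("ligand_rings overlap in atom indices")
        if max(ring_atoms) >= self.ligand_n_atoms:
            raise ValueError("ligand_rings reference atoms beyond ligand_n_atoms")
        if self.fluctuation_profile:
            if len(self.fluctuation_profile) != self.n_residues:
                raise ValueError("fluctuation_profile length must equal n_residues")
            if any(s < 0 for s in self.fluctuation_profile):
                raise ValueError("fluctuation scales must be >= 0")
        else:
            object.__setattr__(
                self, "fluctuation_profile", self._default_profile()
            )

    def _default_profile(self) -> tuple[float, ...]:
        # apo loops are floppy; ligand binding rigidifies them
        base, loop = 0.30, (0.40 if self.bound else 1.00)
        prof = [base] * self.n_residues
        for lo, hi in self.loop_spans:
            for r in range(lo, hi + 1):
                prof[r - 1] = loop
        return tuple(prof)

    def loop_residues(self) -> list[int]:
        out: list[int] = []
        for lo, hi in self.loop_spans:
            out.extend(range(lo, hi + 1))
        return out


@dataclass
class FixtureManifest:
    """Ground truth recorded at construction, for parameter-recovery tests."""

    seed: int
    bound: bool
    n_atoms: int
    n_receptor_atoms: int
    n_ligand_atoms: int
    net_charge_receptor: float
    net_charge_ligand: float
    net_charge: float
    fluctuation_profile: list[float]
    ring_angle: float
    ring_centroid_distance: float
    nearest_residues: list[int]
    min_receptor_ligand_distance: float

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def _hexagon(center: np.ndarray, normal_rotation: np.ndarray) -> np.ndarray:
    """Regular hexagon of circumradius 1.4 A, vertex order giving +z normal
    before rotation (right-hand rule)."""
    angles = np.arange(6) * (math.pi / 3.0)
    pts = np.stack(
        [_BOND_LENGTH * np.cos(angles), _BOND_LENGTH * np.sin(angles), np.zeros(6)],
        axis=1,
    )
    return pts @ normal_rotation.T + center


def _rotation_x(angle_rad: float) -> np.ndarray:
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def make_ring_pair(angle: float, centroid_distance: float) -> MolecularStructure:
    """Two regular planar hexagons whose directed plane normals subtend
    exactly ``angle`` degrees and whose centroids are ``centroid_distance``
    apart.

    Ring A lies in the xy-plane with counterclockwise vertex order (normal
    +z); ring B is ring A rotated about x by ``angle`` and shifted along z.
    """
    if not (0.0 <= angle <= 180.0):
        raise ValueError("angle must be in [0, 180] degrees")
    if centroid_distance <= 0:
        raise ValueError("centroid_distance must be positive")
    ring_a = _hexagon(np.zeros(3), np.eye(3))
    rot = _rotation_x(math.radians(angle))
    ring_b = _hexagon(np.zeros(3), rot) + np.array([0.0, 0.0, centroid_distance])
    atoms = []
    for i, p in enumerate(np.vstack([ring_a, ring_b])):
        atoms.append(
            AtomRecord(i + 1, f"C{i + 1}", "C", "LIG", 1, "L", p)
        )
    return MolecularStructure(atoms)


def _spiral_backbone(n_residues: int) -> np.ndarray:
    """Calpha trace: equal-arc-length points on a spherical spiral with an
    open polar cap (the pocket mouth).  Radius and turn count are solved so
    consecutive Calpha are ~3.8 A apart and turns ~4.6 A apart."""
    theta0, theta1 = _CAP_ANGLE, math.pi - _CAP_ANGLE
    dtheta = theta1 - theta0
    target_len = _CA_SPACING * (n_residues - 1)
    radius = 2.2 * math.sqrt(n_residues)  # initial guess
    t = np.linspace(0.0, 1.0, 20000)
    # area-uniform parametrization (z linear in t) keeps turns evenly
    # spaced and avoids crowding near the poles
    theta = np.arccos(math.cos(theta0) + (math.cos(theta1) - math.cos(theta0)) * t)
    for _ in range(12):
        turns = max(radius * dtheta / _TURN_SPACING, 1.0)
        phi = 2.0 * math.pi * turns * t
        xyz = radius * np.stack(
            [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)],
            axis=1,
        )
        seg = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
        length = float(seg.sum())
        radius *= (target_len / length) ** 0.5
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    want = np.linspace(0.0, arc[-1], n_residues)
    out = np.empty((n_residues, 3))
    for d in range(3):
        out[:, d] = np.interp(want, arc, xyz[:, d])
    return out


def _build_ligand(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    """Ligand coordinates centered at origin: two stacked rings plus linker
    atoms fanned out in ring A's plane."""
    rings = make_ring_pair(spec.ring_angle, spec.ring_centroid_distance)
    ring_xyz = rings.coordinates  # 12 atoms
    n_extra = spec.ligand_n_atoms - 12
    if n_extra < 0:
        raise ValueError("ligand needs at least 12 atoms for its two rings")
    extra = []
    for k in range(n_extra):
        ang = 2.0 * math.pi * (k + 0.5) / max(n_extra, 1)
        r = _BOND_LENGTH + 1.5
        extra.append([r * math.cos(ang), r * math.sin(ang), -1.2])
    coords = np.vstack([ring_xyz] + ([np.array(extra)] if extra else []))
    coords -= coords.mean(axis=0)
    # map spec ring indices onto construction order (rings come first)
    order = np.empty(spec.ligand_n_atoms, dtype=int)
    ring_flat = list(spec.ligand_rings[0]) + list(spec.ligand_rings[1])
    rest = [i for i in range(spec.ligand_n_atoms) if i not in ring_flat]
    for src, dst in enumerate(ring_flat + rest):
        order[dst] = src
    return coords[order]


def make_complex_fixture(
    spec: FixtureSpec,
) -> tuple[MolecularStructure, TopologyParams, FixtureManifest]:
    """Build one synthetic complex: structure, parameter sidecar, manifest.

    Deterministic per seed.  When ``spec.bound`` the ligand sits inside the
    pocket (on the cap axis, below the mouth); otherwise it is translated
    along +z until every receptor-ligand distance is >= 50 A.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    ca = _spiral_backbone(n)
    radial = ca / np.linalg.norm(ca, axis=1, keepdims=True)
    cb = ca + 1.5 * radial

    lig_local = _build_ligand(spec, rng)
    radius = float(np.linalg.norm(ca, axis=1).mean())
    # seat the ligand on the pocket axis: among positions with proper
    # van-der-Waals clearance, take the snuggest (closest wall contact)
    rec_xyz = np.vstack([ca, cb])
    grid = np.arange(0.0, radius + 15.0, 0.25)
    dmin_at = np.array(
        [_min_cross_distance(rec_xyz, lig_local + [0.0, 0.0, z]) for z in grid]
    )
    feasible = dmin_at >= _POCKET_CLEARANCE
    if feasible.any():
        z = grid[feasible][np.argmin(dmin_at[feasible])]
    else:  # cavity too small for this ligand: least-bad seat
        z = grid[np.argmax(dmin_at)]
    pocket_center = np.array([0.0, 0.0, float(z)])
    lig = lig_local + pocket_center
    if not spec.bound:
        shift = radius + _UNBOUND_PLACEMENT
        while True:
            lig_try = lig_local + pocket_center + np.array([0.0, 0.0, shift])
            rec_xyz = np.vstack([ca, cb])
            dmin = _min_cross_distance(rec_xyz, lig_try)
            if dmin >= _UNBOUND_MINIMUM:
                lig = lig_try
                break
            shift += 10.0

    res_names = [str(rng.choice(_AMINO_ACIDS)) for _ in range(n)]

    atoms: list[AtomRecord] = []
    serial = 1
    for i in range(n):
        atoms.append(AtomRecord(serial, "CA", "C", res_names[i], i + 1, "A", ca[i]))
        serial += 1
        atoms.append(AtomRecord(serial, "CB", "C", res_names[i], i + 1, "A", cb[i]))
        serial += 1
    lig_start = len(atoms)
    for j in range(spec.ligand_n_atoms):
        atoms.append(
            AtomRecord(serial, f"C{j + 1}", "C", "LIG", n + 1, "L", lig[j])
        )
        serial += 1
    structure = MolecularStructure(atoms)

    n_atoms = len(atoms)
    n_rec = 2 * n
    charge = rng.uniform(-0.2, 0.2, size=n_atoms)
    # force each molecule's net charge to the nearest integer via its last atom
    for lo, hi in ((0, n_rec), (n_rec, n_atoms)):
        net = charge[lo:hi].sum()
        charge[hi - 1] += round(net) - net
    sigma = rng.uniform(3.2, 3.6, size=n_atoms)
    epsilon = rng.uniform(0.05, 0.15, size=n_atoms)
    born = rng.uniform(1.4, 2.2, size=n_atoms)
    intrinsic = rng.uniform(1.5, 1.9, size=n_atoms)

    hydrophobic = {
        ("A", i + 1): res_names[i] in HYDROPHOBIC_RESIDUES for i in range(n)
    }
    hydrophobic[("L", n + 1)] = False
    params = TopologyParams(
        charge=charge,
        lj_sigma=sigma,
        lj_epsilon=epsilon,
        born_radius=born,
        intrinsic_radius=intrinsic,
        hydrophobic=hydrophobic,
        ligand_selection=list(range(lig_start, n_atoms)),
    )

    dmin = _min_cross_distance(np.vstack([ca, cb]), lig)
    near = sorted(
        i + 1
        for i in range(n)
        if np.min(np.linalg.norm(lig - ca[i], axis=1)) < 8.0
    )
    manifest = FixtureManifest(
        seed=spec.seed,
        bound=spec.bound,
        n_atoms=n_atoms,
        n_receptor_atoms=n_rec,
        n_ligand_atoms=spec.ligand_n_atoms,
        net_charge_receptor=float(round(charge[:n_rec].sum())),
        net_charge_ligand=float(round(charge[n_rec:].sum())),
        net_charge=float(round(charge.sum())),
        fluctuation_profile=list(spec.fluctuation_profile),
        ring_angle=spec.ring_angle,
        ring_centroid_distance=spec.ring_centroid_distance,
        nearest_residues=near,
        min_receptor_ligand_distance=float(dmin),
    )
    return structure, params, manifest


def _min_cross_distance(a: np.ndarray, b: np.ndarray) -> float:
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    return float(d.min())


def make_trajectory(
    structure: MolecularStructure,
    spec: FixtureSpec,
    n_frames: int,
    dt: float,
) -> Trajectory:
    """Pseudo-trajectory: frame k = base + isotropic Gaussian displacements.

    Per-coordinate standard deviation for a receptor atom is its residue's
    entry in ``spec.fluctuation_profile``; ligand atoms move with the scale
    of the nearest receptor residue (the nearest pocket residue, when
    bound).  Frame k (1-based) is stamped ``k * dt`` ps.  The noise stream
    is seeded from ``spec.seed`` independently of the structure stream.
    """
    if n_frames < 2:
        raise ValueError("observables need >= 2 frames")
    base = structure.coordinates
    n_atoms = len(structure)
    sigma = np.zeros(n_atoms)
    ca_by_res: dict[int, np.ndarray] = {}
    for (chain, rid), idx in structure.residue_index.items():
        if chain != "L":
            for i in idx:
                if structure.atoms[i].name == "CA":
                    ca_by_res[rid] = base[i]
            for i in idx:
                sigma[i] = spec.fluctuation_profile[rid - 1]
    if ca_by_res:
        res_ids = sorted(ca_by_res)
        ca_arr = np.array([ca_by_res[r] for r in res_ids])
        for (chain, rid), idx in structure.residue_index.items():
            if chain == "L":
                for i in idx:
                    nearest = res_ids[
                        int(np.argmin(np.linalg.norm(ca_arr - base[i], axis=1)))
                    ]
                    sigma[i] = spec.fluctuation_profile[nearest - 1]
    rng = np.random.default_rng([spec.seed, 7919])
    frames = [
        base + rng.standard_normal((n_atoms, 3)) * sigma[:, None]
        for _ in range(n_frames)
    ]
    times = [dt * (k + 1) for k in range(n_frames)]
    return Trajectory(frames=frames, times=times, template=structure)
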
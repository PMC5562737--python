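"""Trajectory diagnostics: RMSD/RMSF, radius of gyration, contacts,
ring geometry, hydrogen bonds and snapshot extraction.

All superpositions use the Kabsch algorithm (SVD-based, proper rotation
enforced).  RMSD series are measured against the starting structure after
fitting on a selection; RMSF is measured about the iteratively superposed
time-average.  Ring-plane angles are DIRECTED: the plane normal is oriented
by the right-hand rule over the ring's atom ordering, so an angle of 40 deg
and its ordering-reversed complement 140 deg are distinct observables —
stacking geometries on either face differ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .io import MolecularStructure, TopologyParams, Trajectory

__all__ = [
    "Selection",
    "SeriesReport",
    "SelectionError",
    "DegenerateFitError",
    "ATOMIC_MASSES",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf",
    "radius_of_gyration",
    "contact_number",
    "plane_angle",
    "centroid_distance",
    "detect_hbonds",
    "extract_snapshots",
    "active_site_selection",
]

ATOMIC_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "P": 30.974}


class SelectionError(ValueError):
    """Raised when a selection cannot be resolved or resolves to no atoms."""


class DegenerateFitError(ValueError):
    """Raised when a superposition fit set is too small or collinear."""


class Selection:
    """A predicate over atoms, resolving to a deterministic ordered index list.

    Construct via the class methods and combine with ``&`` and ``|``; or
    parse the mini-language used by the CLI::

        ca & resid 100-160
        ligand & heavy
        name CA | name CB
        chain A & hydrophobic

    Terms: ``all``, ``ca`` (atom name CA), ``heavy`` (element != H),
    ``ligand``, ``hydrophobic`` (both need a :class:`TopologyParams`),
    ``name <N>``, ``chain <C>``, ``resid <lo>-<hi>`` (inclusive).
    """

    def __init__(self, predicate: Callable, label: str = "<custom>"):
        self._predicate = predicate
        self.label = label

    def resolve(
        self, structure: MolecularStructure, params: TopologyParams | None = None
    ) -> list[int]:
        """Ordered atom indices matched in ``structure``."""
        lig = set(params.ligand_selection) if params is not None else None
        hydro = params.hydrophobic if params is not None else None
        out = []
        for i, a in enumerate(structure.atoms):
            if self._predicate(a, i, lig, hydro):
                out.append(i)
        return out

    def resolve_nonempty(
        self, structure: MolecularStructure, params: TopologyParams | None = None
    ) -> list[int]:
        idx = self.resolve(structure, params)
        if not idx:
            raise SelectionError(f"selection {self.label!r} matched no atoms")
        return idx

    def __and__(self, other: "Selection") -> "Selection":
        return Selection(
            lambda a, i, lig, hyd: self._predicate(a, i, lig, hyd)
            and other._predicate(a, i, lig, hyd),
            f"({self.label} & {other.label})",
        )

    def __or__(self, other: "Selection") -> "Selection":
        return Selection(
            lambda a, i, lig, hyd: self._predicate(a, i, lig, hyd)
            or other._predicate(a, i, lig, hyd),
            f"({self.label} | {other.label})",
        )

    # -- constructors -------------------------------------------------
    @classmethod
    def all(cls) -> "Selection":
        return cls(lambda a, i, lig, hyd: True, "all")

    @classmethod
    def atom_name(cls, name: str) -> "Selection":
        return cls(lambda a, i, lig, hyd, n=name: a.name == n, f"name {name}")

    @classmethod
    def ca(cls) -> "Selection":
        return cls.atom_name("CA")

    @classmethod
    def heavy(cls) -> "Selection":
        return cls(lambda a, i, lig, hyd: a.element != "H", "heavy")

    @classmethod
    def chain(cls, chain: str) -> "Selection":
        return cls(lambda a, i, lig, hyd, c=chain: a.chain == c, f"chain {chain}")

    @classmethod
    def residue_range(cls, lo: int, hi: int) -> "Selection":
        return cls(
            lambda a, i, lig, hyd: lo <= a.residue_id <= hi, f"resid {lo}-{hi}"
        )

    @classmethod
    def ligand(cls) -> "Selection":
        def pred(a, i, lig, hyd):
            if lig is None:
                raise SelectionError("'ligand' selection needs TopologyParams")
            return i in lig

        return cls(pred, "ligand")

    @classmethod
    def receptor(cls) -> "Selection":
        def pred(a, i, lig, hyd):
            if lig is None:
                raise SelectionError("'receptor' selection needs TopologyParams")
            return i not in lig

        return cls(pred, "receptor")

    @classmethod
    def hydrophobic(cls) -> "Selection":
        def pred(a, i, lig, hyd):
            if hyd is None:
                raise SelectionError("'hydrophobic' selection needs TopologyParams")
            return hyd.get((a.chain, a.residue_id), False)

        return cls(pred, "hydrophobic")

    @classmethod
    def residue_set(cls, keys: set) -> "Selection":
        return cls(
            lambda a, i, lig, hyd: (a.chain, a.residue_id) in keys,
            f"residues[{len(keys)}]",
        )

    @classmethod
    def parse(cls, expr: str) -> "Selection":
        """Parse the mini-language (``|`` binds looser than ``&``)."""

        def parse_term(term: str) -> "Selection":
            toks = term.split()
            if not toks:
                raise SelectionError(f"empty selection term in {expr!r}")
            head = toks[0].lower()
            if head == "all":
                return cls.all()
            if head == "ca":
                return cls.ca()
            if head == "heavy":
                return cls.heavy()
            if head == "ligand":
                return cls.ligand()
            if head == "receptor":
                return cls.receptor()
            if head == "hydrophobic":
                return cls.hydrophobic()
            if head == "name" and len(toks) == 2:
                return cls.atom_name(toks[1])
            if head == "chain" and len(toks) == 2:
                return cls.chain(toks[1])
            if head == "resid" and len(toks) == 2:
                lo, _, hi = toks[1].partition("-")
                return cls.residue_range(int(lo), int(hi) if hi else int(lo))
            raise SelectionError(f"cannot parse selection term {term!r}")

        def parse_and(chunk: str) -> "Selection":
            parts = [p.strip() for p in chunk.split("&")]
            sel = parse_term(parts[0])
            for p in parts[1:]:
                sel = sel & parse_term(p)
            return sel

        parts = [p.strip() for p in expr.split("|")]
        sel = parse_and(parts[0])
        for p in parts[1:]:
            sel = sel | parse_and(p)
        sel.label = expr
        return sel


@dataclass
class SeriesReport:
    """A named per-frame observable with units."""

    name: str
    times: np.ndarray  # ps
    values: np.ndarray
    units: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_ps": self.times, f"{self.name}_{self.units}": self.values}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Superposition

def _check_fit_set(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise DegenerateFitError("superposition needs >= 3 fit atoms")
    centered = coords - coords.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise DegenerateFitError("fit atoms are collinear; rotation underdetermined")


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_indices: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` with the proper rotation
    (det +1) and translation minimizing the least-squares deviation over
    ``fit_indices`` (default: all atoms), and the post-fit RMSD over those
    atoms.  Apply as ``mobile @ rotation.T + translation``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference must have identical shapes")
    idx = np.arange(len(mobile)) if fit_indices is None else np.asarray(fit_indices)
    m = mobile[idx]
    r = reference[idx]
    _check_fit_set(r)
    _check_fit_set(m)
    mc, rc = m.mean(axis=0), r.mean(axis=0)
    h = (m - mc).T @ (r - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = rc - rot @ mc
    fitted = m @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - r) ** 2, axis=1))))
    return rot, trans, rmsd


def rmsd_series(
    traj: Trajectory,
    reference: MolecularStructure | None = None,
    fit_selection: Selection | None = None,
    measure_selection: Selection | None = None,
    params: TopologyParams | None = None,
    name: str = "rmsd",
) -> SeriesReport:
    """Per-frame RMSD with respect to the starting structure.

    Each frame is superposed on ``fit_selection`` (default: Calpha atoms)
    and the RMSD reported over ``measure_selection`` (default: the fit
    selection).  ``reference`` defaults to the trajectory template.
    """
    ref = reference if reference is not None else traj.template
    fit_sel = fit_selection if fit_selection is not None else Selection.ca()
    meas_sel = measure_selection if measure_selection is not None else fit_sel
    fit_idx = fit_sel.resolve_nonempty(traj.template, params)
    meas_idx = meas_sel.resolve_nonempty(traj.template, params)
    ref_xyz = ref.coordinates
    values = []
    for frame in traj.frames:
        rot, trans, _ = kabsch_superpose(frame, ref_xyz, fit_idx)
        fitted = frame @ rot.T + trans
        dev = fitted[meas_idx] - ref_xyz[meas_idx]
        values.append(np.sqrt(np.mean(np.sum(dev**2, axis=1))))
    return SeriesReport(name, np.array(traj.times), np.array(values), "A")


def _superpose_all(frames: list[np.ndarray], ref: np.ndarray, idx) -> list[np.ndarray]:
    out = []
    for f in frames:
        rot, trans, _ = kabsch_superpose(f, ref, idx)
        out.append(f @ rot.T + trans)
    return out


def rmsf(
    traj: Trajectory,
    selection: Selection | None = None,
    params: TopologyParams | None = None,
    n_passes: int = 2,
) -> pd.DataFrame:
    """Per-residue root-mean-square fluctuation about the time average.

    Frames are superposed onto their time-average structure over
    ``selection`` (default: Calpha), iterating ``n_passes`` times starting
    from the first frame as reference.  RMSF(i) = sqrt(mean_t |x_i(t) -
    <x_i>|^2); reported per residue via its Calpha atom.  Returns a
    DataFrame with columns ``chain``, ``residue_id``, ``rmsf`` (A).
    """
    if len(traj) < 2:
        raise ValueError("RMSF needs >= 2 frames")
    sel = selection if selection is not None else Selection.ca()
    idx = sel.resolve_nonempty(traj.template, params)
    ref = traj.frames[0]
    aligned = traj.frames
    for _ in range(n_passes):
        aligned = _superpose_all(aligned, ref, idx)
        ref = np.mean(aligned, axis=0)
    stack = np.stack([f[idx] for f in aligned])
    mean = stack.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((stack - mean) ** 2, axis=2), axis=0))
    rows = []
    for j, i in enumerate(idx):
        a = traj.template.atoms[i]
        if a.name == "CA":
            rows.append((a.chain, a.residue_id, per_atom[j]))
    if not rows:  # selection without Calpha: report per selected atom's residue
        for j, i in enumerate(idx):
            a = traj.template.atoms[i]
            rows.append((a.chain, a.residue_id, per_atom[j]))
    return pd.DataFrame(rows, columns=["chain", "residue_id", "rmsf"])


# ---------------------------------------------------------------------------
# Scalar geometry observables

def radius_of_gyration(
    frame: np.ndarray,
    indices: Sequence[int] | None = None,
    masses: np.ndarray | None = None,
) -> float:
    """Mass-weighted RMS distance from the mass-weighted centroid, in A."""
    frame = np.asarray(frame, dtype=float)
    xyz = frame if indices is None else frame[np.asarray(indices)]
    if len(xyz) == 0:
        raise SelectionError("radius_of_gyration: empty selection")
    m = np.ones(len(xyz)) if masses is None else np.asarray(masses, dtype=float)
    total = m.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    com = (m[:, None] * xyz).sum(axis=0) / total
    return float(np.sqrt((m * np.sum((xyz - com) ** 2, axis=1)).sum() / total))


def masses_for(structure: MolecularStructure, indices: Sequence[int]) -> np.ndarray:
    return np.array(
        [ATOMIC_MASSES.get(structure.atoms[i].element, 12.011) for i in indices]
    )


def contact_number(
    frame: np.ndarray,
    structure: MolecularStructure,
    receptor_sel: Selection,
    ligand_sel: Selection,
    cutoff: float = 6.0,
    params: TopologyParams | None = None,
) -> int:
    """Number of receptor atoms with >= 1 ligand heavy atom strictly within
    ``cutoff`` A."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    rec_idx = receptor_sel.resolve_nonempty(structure, params)
    lig_idx = [
        i for i in ligand_sel.resolve_nonempty(structure, params)
        if structure.atoms[i].element != "H"
    ]
    if not lig_idx:
        raise SelectionError("ligand selection has no heavy atoms")
    frame = np.asarray(frame, dtype=float)
    d = np.linalg.norm(frame[rec_idx][:, None, :] - frame[lig_idx][None, :, :], axis=2)
    return int(np.sum(np.any(d < cutoff, axis=1)))


def _directed_normal(ring: np.ndarray) -> np.ndarray:
    """Total-least-squares plane normal, oriented by the right-hand rule
    over the ring's atom ordering (Newell's method)."""
    ring = np.asarray(ring, dtype=float)
    if len(ring) < 3:
        raise DegenerateFitError("ring needs >= 3 atoms")
    c = ring.mean(axis=0)
    centered = ring - c
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise DegenerateFitError("ring atoms are collinear; plane undefined")
    _, _, vt = np.linalg.svd(centered)
    normal = vt[2]
    orient = np.zeros(3)
    for i in range(len(ring)):
        orient += np.cross(centered[i], centered[(i + 1) % len(ring)])
    if np.dot(normal, orient) < 0:
        normal = -normal
    return normal / np.linalg.norm(normal)


def plane_angle(ring_a: np.ndarray, ring_b: np.ndarray) -> float:
    """Angle in degrees [0, 180] between the two rings' directed plane
    normals.  Not folded to [0, 90]: 40 deg and 140 deg are distinct."""
    na = _directed_normal(ring_a)
    nb = _directed_normal(ring_b)
    cosang = float(np.clip(np.dot(na, nb), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def centroid_distance(ring_a: np.ndarray, ring_b: np.ndarray) -> float:
    """Euclidean distance between unweighted ring centroids, in A."""
    a = np.asarray(ring_a, dtype=float)
    b = np.asarray(ring_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise SelectionError("rings must be non-empty")
    return float(np.linalg.norm(a.mean(axis=0) - b.mean(axis=0)))


# ---------------------------------------------------------------------------
# Hydrogen bonds

_H_ATTACH_MAX = 1.25  # A, covalent D-H upper bound


def detect_hbonds(
    frame: np.ndarray,
    structure: MolecularStructure,
    donors: Selection,
    acceptors: Selection,
    d_max: float = 3.5,
    angle_min: float = 135.0,
    params: TopologyParams | None = None,
) -> list[tuple[int, int]]:
    """Geometric hydrogen-bond detection.

    A (donor, acceptor) heavy-atom pair is reported iff their distance is
    <= ``d_max`` AND some hydrogen attached to the donor (same residue,
    element H, within 1.25 A) makes a donor-H...acceptor angle >=
    ``angle_min`` degrees.  Donors without an attached hydrogen are skipped
    with a warning.
    """
    frame = np.asarray(frame, dtype=float)
    don_idx = donors.resolve_nonempty(structure, params)
    acc_idx = acceptors.resolve_nonempty(structure, params)
    bonds = []
    for d in don_idx:
        da = structure.atoms[d]
        hyds = [
            i
            for i in structure.residue_index[(da.chain, da.residue_id)]
            if structure.atoms[i].element == "H"
            and np.linalg.norm(frame[i] - frame[d]) <= _H_ATTACH_MAX
        ]
        if not hyds:
            warnings.warn(
                f"donor {da.name} {da.residue_name}{da.residue_id} has no attached "
                "hydrogen; skipped",
                stacklevel=2,
            )
            continue
        for a in acc_idx:
            if a == d:
                continue
            if np.linalg.norm(frame[a] - frame[d]) > d_max:
                continue
            for h in hyds:
                v1 = frame[d] - frame[h]
                v2 = frame[a] - frame[h]
                n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
                if n1 == 0 or n2 == 0:
                    continue
                ang = np.degrees(np.arccos(np.clip(np.dot(v1, v2) / (n1 * n2), -1, 1)))
                if ang >= angle_min:
                    bonds.append((d, a))
                    break
    return bonds


# ---------------------------------------------------------------------------
# Snapshots

def extract_snapshots(
    traj: Trajectory, window_start: float, window_end: float, interval: float
) -> Trajectory:
    """Frames at times ``window_start + k*interval`` for k = 1 ..
    floor((window_end - window_start)/interval) — half-open at the start,
    closed at the end, so a 200,000 ps window at 200 ps yields exactly 1000
    snapshots.  Each target time is matched to the nearest frame within
    ``interval/2``.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    span = window_end - window_start
    n = int(np.floor(span / interval + 1e-9))
    if n < 1:
        raise ValueError("window shorter than one interval: no snapshots")
    times = np.asarray(traj.times)
    picked = []
    for k in range(1, n + 1):
        target = window_start + k * interval
        j = int(np.argmin(np.abs(times - target)))
        if abs(times[j] - target) > interval / 2 + 1e-9:
            raise ValueError(
                f"no frame within {interval / 2} ps of target time {target} ps"
            )
        picked.append(j)
    if len(set(picked)) != len(picked):
        raise ValueError("snapshot interval finer than frame spacing")
    return Trajectory(
        frames=[traj.frames[j] for j in picked],
        times=[traj.times[j] for j in picked],
        template=traj.template,
    )


def active_site_selection(
    structure: MolecularStructure,
    params: TopologyParams,
    radius: float = 5.0,
) -> Selection:
    """Residues with any atom within ``radius`` A of the ligand in the
    reference structure (the working definition of the 'active site')."""
    xyz = structure.coordinates
    lig = np.asarray(params.ligand_selection, dtype=int)
    if len(lig) == 0:
        raise SelectionError("no ligand defined in TopologyParams")
    lig_xyz = xyz[lig]
    keys = set()
    for key, idx in structure.residue_index.items():
        res_xyz = xyz[idx]
        d = np.linalg.norm(res_xyz[:, None, :] - lig_xyz[None, :, :], axis=2)
        if np.any(d < radius) and not set(idx) <= set(params.ligand_selection):
            keys.add(key)
    return Selection.residue_set(keys)
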
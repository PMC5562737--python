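"""MM-GBSA energetics: gas-phase terms, implicit solvation, binding free
energy and per-residue decomposition.

The binding free energy of a receptor-ligand complex is estimated end-point
style over trajectory snapshots::

    dG_bind = <G(complex) - G(receptor) - G(ligand)>

with, for each species,

    G = E_ele + E_vdw + E_int + G_sol_polar + G_sol_np

* ``E_ele``  — pairwise Coulomb sum, k q_i q_j / r_ij, vacuum dielectric,
  no cutoff (k = 332.0637 kcal*A/(mol*e^2));
* ``E_vdw`` — Lennard-Jones 12-6 with Lorentz-Berthelot combining;
* ``G_sol_polar`` — generalized-Born (Still pairwise form)::

      G_pol = -1/2 (1/eps_in - 1/eps_out) k sum_ij q_i q_j / f_GB
      f_GB  = sqrt(r^2 + R_i R_j exp(-r^2 / (4 R_i R_j)))

  with the double sum including i = j, so an isolated ion reduces to the
  Born formula; effective Born radii come from the topology sidecar;
* ``G_sol_np`` — gamma * SASA (no offset), SASA by deterministic
  Shrake-Rupley sphere sampling with a 1.4 A water probe.

The protocol is single-trajectory: receptor and ligand coordinates are
extracted from each complex snapshot, so every intramolecular gas-phase
term cancels in the difference and dE_int is identically zero.  The report
stops at the enthalpic estimate dH; no entropy term is computed, and dG is
reported equal to dH with that caveat.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MolecularStructure, TopologyParams, Trajectory
from .observables import extract_snapshots

__all__ = [
    "GBSettings",
    "EnergyReport",
    "ResidueContribution",
    "COULOMB_CONSTANT",
    "coulomb_energy",
    "lj_energy",
    "shrake_rupley_sasa",
    "nonpolar_solvation",
    "gb_polar_energy",
    "born_radii_cfa",
    "binding_free_energy",
    "per_residue_decomposition",
]

COULOMB_CONSTANT = 332.0637  # kcal*A/(mol*e^2)
_MIN_DISTANCE = 0.1  # A; closer pairs are treated as geometry errors


@dataclass(frozen=True)
class GBSettings:
    """Dielectric, surface and sampling settings for the solvation terms."""

    eps_in: float = 1.0
    eps_out: float = 80.0
    gamma: float = 0.0072        # kcal/(mol*A^2)
    probe: float = 1.4           # A
    coulomb_constant: float = COULOMB_CONSTANT
    sasa_points: int = 960

    def __post_init__(self) -> None:
        if not (self.eps_out > self.eps_in >= 1.0):
            raise ValueError("require eps_out > eps_in >= 1")
        if self.gamma < 0 or self.probe < 0:
            raise ValueError("gamma and probe must be non-negative")
        if self.sasa_points < 1:
            raise ValueError("sasa_points must be positive")


def _as_pairs(n: int, pairs) -> tuple[np.ndarray, np.ndarray]:
    if pairs is None:
        iu = np.triu_indices(n, k=1)
        return iu[0], iu[1]
    arr = np.asarray(pairs, dtype=int)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pair_set must be an (m, 2) index array")
    if np.any(arr[:, 0] == arr[:, 1]):
        raise ValueError("pair_set must exclude self-pairs")
    return arr[:, 0], arr[:, 1]


def _pair_distances(coords: np.ndarray, i: np.ndarray, j: np.ndarray) -> np.ndarray:
    r = np.linalg.norm(coords[i] - coords[j], axis=1)
    if np.any(r < _MIN_DISTANCE):
        raise ValueError(
            f"near-singular geometry: pair distance below {_MIN_DISTANCE} A"
        )
    return r


def coulomb_energy(
    coords: np.ndarray,
    charges: np.ndarray,
    pair_set=None,
    k: float = COULOMB_CONSTANT,
) -> float:
    """Vacuum Coulomb energy, sum over pairs of k q_i q_j / r_ij, kcal/mol.

    ``pair_set`` is an (m, 2) index array, or None for all unordered pairs.
    """
    coords = np.asarray(coords, dtype=float)
    charges = np.asarray(charges, dtype=float)
    i, j = _as_pairs(len(coords), pair_set)
    if len(i) == 0:
        return 0.0
    r = _pair_distances(coords, i, j)
    return float(np.sum(k * charges[i] * charges[j] / r))


def lj_energy(
    coords: np.ndarray,
    sigma: np.ndarray,
    epsilon: np.ndarray,
    pair_set=None,
) -> float:
    """Lennard-Jones 12-6 energy with Lorentz-Berthelot combining, kcal/mol.

    sigma_ij is the arithmetic mean, epsilon_ij the geometric mean; no
    cutoff.
    """
    coords = np.asarray(coords, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    epsilon = np.asarray(epsilon, dtype=float)
    i, j = _as_pairs(len(coords), pair_set)
    if len(i) == 0:
        return 0.0
    r = _pair_distances(coords, i, j)
    sij = 0.5 * (sigma[i] + sigma[j])
    eij = np.sqrt(epsilon[i] * epsilon[j])
    sr6 = (sij / r) ** 6
    return float(np.sum(4.0 * eij * (sr6**2 - sr6)))


# ---------------------------------------------------------------------------
# SASA

def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere sample (golden-angle spiral)."""
    k = np.arange(n)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * math.pi * (3.0 - math.sqrt(5.0))
    s = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=1)


def shrake_rupley_sasa(
    coords: np.ndarray,
    intrinsic_radii: np.ndarray,
    settings: GBSettings = GBSettings(),
) -> np.ndarray:
    """Per-atom solvent-accessible surface area, A^2 (Shrake-Rupley).

    Each atom's sphere of radius (r_i + probe) is sampled with
    ``settings.sasa_points`` deterministic quasi-uniform points; a point is
    buried iff it lies strictly inside any other atom's expanded sphere.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(intrinsic_radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("intrinsic radii must be positive")
    n = len(coords)
    expanded = radii + settings.probe
    unit = _fibonacci_sphere(settings.sasa_points)
    areas = np.zeros(n)
    if n == 0:
        return areas
    # neighbour prefilter: only atoms whose expanded spheres can overlap
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    for i in range(n):
        ri = expanded[i]
        nbr = np.where((d[i] < ri + expanded) & (np.arange(n) != i))[0]
        pts = coords[i] + ri * unit
        if len(nbr) == 0:
            accessible = settings.sasa_points
        else:
            pd_ = np.linalg.norm(pts[:, None, :] - coords[nbr][None, :, :], axis=2)
            buried = np.any(pd_ < expanded[nbr][None, :], axis=1)
            accessible = int(np.sum(~buried))
        areas[i] = 4.0 * math.pi * ri * ri * accessible / settings.sasa_points
    return areas


def nonpolar_solvation(total_sasa: float, settings: GBSettings = GBSettings()) -> float:
    """Nonpolar solvation free energy gamma * SASA, kcal/mol (no offset)."""
    if total_sasa < 0:
        raise ValueError("SASA must be non-negative")
    return settings.gamma * total_sasa


# ---------------------------------------------------------------------------
# Generalized Born

def _f_gb(r2: np.ndarray, born_i: np.ndarray, born_j: np.ndarray) -> np.ndarray:
    rirj = born_i * born_j
    return np.sqrt(r2 + rirj * np.exp(-r2 / (4.0 * rirj)))


def gb_polar_energy(
    coords: np.ndarray,
    charges: np.ndarray,
    born_radii: np.ndarray,
    settings: GBSettings = GBSettings(),
) -> float:
    """Generalized-Born polar solvation energy, kcal/mol.

    Still's pairwise form over the full double sum including i = j, so a
    single ion reduces to the Born formula -1/2 (1/eps_in - 1/eps_out)
    k q^2 / R.
    """
    coords = np.asarray(coords, dtype=float)
    charges = np.asarray(charges, dtype=float)
    born = np.asarray(born_radii, dtype=float)
    if np.any(born <= 0):
        raise ValueError("Born radii must be positive")
    diff = coords[:, None, :] - coords[None, :, :]
    r2 = np.sum(diff * diff, axis=2)
    f = _f_gb(r2, born[:, None], born[None, :])
    tau = 1.0 / settings.eps_in - 1.0 / settings.eps_out
    qq = charges[:, None] * charges[None, :]
    return float(-0.5 * tau * settings.coulomb_constant * np.sum(qq / f))


def gb_cross_energy(
    coords: np.ndarray,
    charges: np.ndarray,
    born_radii: np.ndarray,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    settings: GBSettings = GBSettings(),
) -> np.ndarray:
    """Per-pair GB screening terms between two disjoint atom groups.

    Returns the (len(a), len(b)) matrix whose total equals
    G_pol(complex) - G_pol(a) - G_pol(b) when Born radii are held fixed.
    """
    coords = np.asarray(coords, dtype=float)
    charges = np.asarray(charges, dtype=float)
    born = np.asarray(born_radii, dtype=float)
    a = np.asarray(idx_a, dtype=int)
    b = np.asarray(idx_b, dtype=int)
    diff = coords[a][:, None, :] - coords[b][None, :, :]
    r2 = np.sum(diff * diff, axis=2)
    f = _f_gb(r2, born[a][:, None], born[b][None, :])
    tau = 1.0 / settings.eps_in - 1.0 / settings.eps_out
    qq = charges[a][:, None] * charges[b][None, :]
    return -tau * settings.coulomb_constant * qq / f


def born_radii_cfa(
    coords: np.ndarray, intrinsic_radii: np.ndarray
) -> np.ndarray:
    """Coulomb-field-approximation estimate of effective Born radii from
    intrinsic radii (optional convenience; fixtures normally supply Born
    radii directly in the sidecar)::

        1/R_i = 1/rho_i - sum_{j != i} rho_j^3 / r_ij^4  (clamped)
    """
    coords = np.asarray(coords, dtype=float)
    rho = np.asarray(intrinsic_radii, dtype=float)
    n = len(coords)
    inv = 1.0 / rho
    for i in range(n):
        r = np.linalg.norm(coords - coords[i], axis=1)
        mask = np.arange(n) != i
        inv_i = inv[i] - np.sum(rho[mask] ** 3 / np.maximum(r[mask], rho[i]) ** 4)
        inv[i] = max(inv_i, 1e-3)
    return 1.0 / inv


# ---------------------------------------------------------------------------
# Binding free energy

_REPORT_TERMS = (
    "dE_ele",
    "dE_vdw",
    "dE_int",
    "dE_gas",
    "dG_sol_np",
    "dG_sol_polar",
    "dG_sol",
    "dH",
    "dG",
)

# CSV/JSON row labels (GB flavour made explicit on the solvation terms)
_REPORT_LABELS = {
    "dE_ele": "dE_ele",
    "dE_vdw": "dE_vdw",
    "dE_int": "dE_int",
    "dE_gas": "dE_gas",
    "dG_sol_np": "dG_sol_np_GB",
    "dG_sol_polar": "dG_sol_polar_GB",
    "dG_sol": "dG_sol_GB",
    "dH": "dH_GB",
    "dG": "dG_GB",
}


@dataclass
class EnergyReport:
    """Binding-energy terms for one complex: mean +/- SEM over snapshots.

    Additivity holds by construction on the means: dE_gas = dE_ele + dE_vdw
    + dE_int, dG_sol = dG_sol_np + dG_sol_polar, dH = dE_gas + dG_sol.
    dE_int is identically 0 (single-trajectory protocol) and dG equals dH
    because no entropy term is computed.
    """

    dE_ele: tuple[float, float]
    dE_vdw: tuple[float, float]
    dE_int: tuple[float, float]
    dE_gas: tuple[float, float]
    dG_sol_np: tuple[float, float]
    dG_sol_polar: tuple[float, float]
    dG_sol: tuple[float, float]
    dH: tuple[float, float]
    dG: tuple[float, float]
    n_snapshots: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (_REPORT_LABELS[t], getattr(self, t)[0], getattr(self, t)[1])
            for t in _REPORT_TERMS
        ]
        return pd.DataFrame(rows, columns=["term", "mean_kcal_mol", "sem_kcal_mol"])

    def to_json(self) -> str:
        payload = {
            _REPORT_LABELS[t]: {"mean": getattr(self, t)[0], "sem": getattr(self, t)[1]}
            for t in _REPORT_TERMS
        }
        payload["n_snapshots"] = self.n_snapshots
        return json.dumps(payload, indent=2)


def _mean_sem(x: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    mean = float(x.mean())
    sem = float(x.std(ddof=1) / math.sqrt(len(x))) if len(x) > 1 else 0.0
    return mean, sem


def binding_free_energy(
    traj: Trajectory,
    topology: TopologyParams,
    settings: GBSettings = GBSettings(),
    snapshot_plan: tuple[float, float, float] | None = None,
) -> EnergyReport:
    """Single-trajectory MM-GBSA binding free energy over snapshots.

    Receptor and ligand coordinates are extracted from each complex
    snapshot, so every intramolecular gas-phase term cancels identically
    in term(complex) - term(receptor) - term(ligand); that cancellation is
    applied analytically, leaving dE_ele and dE_vdw as sums over
    receptor-ligand cross pairs (numerically exact rather than a
    difference of large intramolecular sums) and dE_int = 0.  The
    solvation terms are not pairwise-additive and are computed as
    complex-minus-parts.  ``snapshot_plan`` is ``(window_start,
    window_end, interval)`` in ps passed to
    :func:`~gbnet.observables.extract_snapshots`; None uses every frame.
    """
    if not topology.ligand_selection:
        raise ValueError("topology defines no ligand_selection")
    snaps = (
        traj
        if snapshot_plan is None
        else extract_snapshots(traj, *snapshot_plan)
    )
    if len(snaps) == 0:
        raise ValueError("no snapshots to average over")
    n_atoms = len(snaps.template)
    lig = np.asarray(topology.ligand_selection, dtype=int)
    rec = np.setdiff1d(np.arange(n_atoms), lig)
    top_rec = topology.subset(rec)
    top_lig = topology.subset(lig)
    cross = np.array([(i, j) for i in rec for j in lig], dtype=int)

    d_ele, d_vdw, d_pol, d_np = [], [], [], []
    for frame in snaps.frames:
        d_ele.append(
            coulomb_energy(frame, topology.charge, cross, settings.coulomb_constant)
        )
        d_vdw.append(
            lj_energy(frame, topology.lj_sigma, topology.lj_epsilon, cross)
        )
        c_pol = gb_polar_energy(frame, topology.charge, topology.born_radius, settings)
        r_pol = gb_polar_energy(
            frame[rec], top_rec.charge, top_rec.born_radius, settings
        )
        l_pol = gb_polar_energy(
            frame[lig], top_lig.charge, top_lig.born_radius, settings
        )
        d_pol.append(c_pol - r_pol - l_pol)
        c_np = nonpolar_solvation(
            float(shrake_rupley_sasa(frame, topology.intrinsic_radius, settings).sum()),
            settings,
        )
        r_np = nonpolar_solvation(
            float(
                shrake_rupley_sasa(frame[rec], top_rec.intrinsic_radius, settings).sum()
            ),
            settings,
        )
        l_np = nonpolar_solvation(
            float(
                shrake_rupley_sasa(frame[lig], top_lig.intrinsic_radius, settings).sum()
            ),
            settings,
        )
        d_np.append(c_np - r_np - l_np)
    d_ele = np.array(d_ele)
    d_vdw = np.array(d_vdw)
    d_pol = np.array(d_pol)
    d_np = np.array(d_np)
    d_int = np.zeros_like(d_ele)  # single-trajectory protocol
    d_gas = d_ele + d_vdw + d_int
    d_sol = d_np + d_pol
    d_h = d_gas + d_sol
    return EnergyReport(
        dE_ele=_mean_sem(d_ele),
        dE_vdw=_mean_sem(d_vdw),
        dE_int=(0.0, 0.0),
        dE_gas=_mean_sem(d_gas),
        dG_sol_np=_mean_sem(d_np),
        dG_sol_polar=_mean_sem(d_pol),
        dG_sol=_mean_sem(d_sol),
        dH=_mean_sem(d_h),
        dG=_mean_sem(d_h),
        n_snapshots=len(snaps),
    )


# ---------------------------------------------------------------------------
# Per-residue decomposition

@dataclass
class ResidueContribution:
    """Per-residue share of the receptor-ligand interaction energy.

    ``table`` has one row per residue (ligand residue included) with
    columns chain, residue_id, residue_name, ele, vdw, polar, np,
    contribution, labeled.  The contributions sum to the snapshot's total
    cross-interaction energy (the same scheme's dH).
    """

    table: pd.DataFrame
    threshold: float

    def total(self) -> float:
        return float(self.table["contribution"].sum())

    def labeled_residues(self) -> list[tuple[str, int]]:
        lab = self.table[self.table["labeled"]]
        return list(zip(lab["chain"], lab["residue_id"]))

    def to_json(self) -> str:
        return json.dumps(
            {
                "threshold_kcal_mol": self.threshold,
                "residues": self.table.to_dict(orient="records"),
            },
            indent=2,
        )


def per_residue_decomposition(
    snapshot: np.ndarray,
    structure: MolecularStructure,
    topology: TopologyParams,
    settings: GBSettings = GBSettings(),
    threshold: float = 0.4,
) -> ResidueContribution:
    """Decompose one snapshot's binding energy into residue contributions.

    A receptor residue R collects the full Coulomb, Lennard-Jones and GB
    screening terms of its atom pairs with the ligand, plus gamma times its
    SASA change upon complexation (negative when buried); the ligand
    residue collects only its own SASA change term, so the grand total
    equals the snapshot's complete cross-interaction energy.  A residue is
    labeled iff |contribution| > ``threshold`` (default 0.4 kcal/mol).
    """
    coords = np.asarray(snapshot, dtype=float)
    n_atoms = len(structure)
    lig = np.asarray(topology.ligand_selection, dtype=int)
    if len(lig) == 0:
        raise ValueError("topology defines no ligand_selection")
    rec = np.setdiff1d(np.arange(n_atoms), lig)

    # pairwise cross matrices, receptor rows x ligand columns
    diff = coords[rec][:, None, :] - coords[lig][None, :, :]
    r = np.sqrt(np.sum(diff * diff, axis=2))
    if np.any(r < _MIN_DISTANCE):
        raise ValueError("near-singular receptor-ligand contact")
    q = topology.charge
    ele = settings.coulomb_constant * q[rec][:, None] * q[lig][None, :] / r
    sij = 0.5 * (topology.lj_sigma[rec][:, None] + topology.lj_sigma[lig][None, :])
    eij = np.sqrt(topology.lj_epsilon[rec][:, None] * topology.lj_epsilon[lig][None, :])
    sr6 = (sij / r) ** 6
    vdw = 4.0 * eij * (sr6**2 - sr6)
    gb = gb_cross_energy(coords, q, topology.born_radius, rec, lig, settings)

    # SASA change per residue upon complexation
    sasa_complex = shrake_rupley_sasa(coords, topology.intrinsic_radius, settings)
    sasa_rec = np.zeros(n_atoms)
    sasa_rec[rec] = shrake_rupley_sasa(
        coords[rec], topology.intrinsic_radius[rec], settings
    )
    sasa_lig = np.zeros(n_atoms)
    sasa_lig[lig] = shrake_rupley_sasa(
        coords[lig], topology.intrinsic_radius[lig], settings
    )
    d_sasa = sasa_complex - (sasa_rec + sasa_lig)

    rec_row = {int(a): k for k, a in enumerate(rec)}
    lig_set = set(int(i) for i in lig)
    rows = []
    for (chain, rid), idx in structure.residue_index.items():
        res_name = structure.atoms[idx[0]].residue_name
        np_term = settings.gamma * float(d_sasa[idx].sum())
        if set(idx) <= lig_set:
            e_ele = e_vdw = e_pol = 0.0
        else:
            ridx = [rec_row[i] for i in idx if i in rec_row]
            e_ele = float(ele[ridx].sum())
            e_vdw = float(vdw[ridx].sum())
            e_pol = float(gb[ridx].sum())
        contrib = e_ele + e_vdw + e_pol + np_term
        rows.append((chain, rid, res_name, e_ele, e_vdw, e_pol, np_term, contrib))
    table = pd.DataFrame(
        rows,
        columns=[
            "chain",
            "residue_id",
            "residue_name",
            "ele",
            "vdw",
            "polar",
            "np",
            "contribution",
        ],
    )
    table["labeled"] = table["contribution"].abs() > threshold
    return ResidueContribution(table=table, threshold=threshold)
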
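"""Structure, trajectory and parameter-sidecar I/O.

The interchange formats are deliberately plain text:

* structures and pseudo-trajectories travel as fixed-column PDB
  (``ATOM``/``HETATM`` records, models wrapped in ``MODEL``/``ENDMDL``);
* per-atom force-field-lite parameters travel as a TSV sidecar keyed by
  atom serial (charge in e, Lennard-Jones sigma/epsilon in A and kcal/mol,
  effective Born radius and intrinsic radius in A), plus per-residue
  hydrophobicity flags and the ligand atom span.

Only the first ``MODEL`` of a PDB is read as a single structure;
:func:`read_trajectory` reads all models.  mmCIF, binary trajectory
formats, altlocs and insertion codes are out of scope.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "MolecularStructure",
    "Trajectory",
    "TopologyParams",
    "PDBFormatError",
    "TopologyError",
    "read_pdb",
    "write_pdb",
    "read_trajectory",
    "write_trajectory",
    "read_topology",
    "write_topology",
]


class PDBFormatError(ValueError):
    """Raised for malformed or empty PDB input/output."""


class TopologyError(ValueError):
    """Raised when a parameter sidecar does not cover the structure."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom as printed in a PDB ATOM/HETATM record."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain: str
    position: np.ndarray  # (3,) float, Angstrom

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


class MolecularStructure:
    """An ordered list of atoms with residue/chain bookkeeping.

    ``residue_index`` maps ``(chain, residue_id)`` to the ordered atom
    indices of that residue; atom order is preserved from the source.
    """

    def __init__(self, atoms: Sequence[AtomRecord]):
        self.atoms: list[AtomRecord] = list(atoms)
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serials must be unique within a structure")
        self.residue_index: dict[tuple[str, int], list[int]] = {}
        for i, a in enumerate(self.atoms):
            self.residue_index.setdefault((a.chain, a.residue_id), []).append(i)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Angstrom."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms], dtype=float)

    def residues(self) -> list[tuple[str, int]]:
        """Residue keys in order of first appearance."""
        return list(self.residue_index)

    def with_coordinates(self, coords: np.ndarray) -> "MolecularStructure":
        """Copy of the structure with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [
            AtomRecord(a.serial, a.name, a.element, a.residue_name, a.residue_id, a.chain, c)
            for a, c in zip(self.atoms, coords)
        ]
        return MolecularStructure(atoms)

    def subset(self, indices: Sequence[int]) -> "MolecularStructure":
        """Sub-structure over the given atom indices (order preserved)."""
        return MolecularStructure([self.atoms[i] for i in indices])


@dataclass
class Trajectory:
    """Time-ordered coordinate frames sharing one atom template.

    ``frames`` is a list of (n_atoms, 3) arrays in Angstrom, ``times`` the
    matching timestamps in ps (strictly increasing).
    """

    frames: list[np.ndarray]
    times: list[float]
    template: MolecularStructure

    def __post_init__(self) -> None:
        n = len(self.template)
        self.frames = [np.asarray(f, dtype=float) for f in self.frames]
        for f in self.frames:
            if f.shape != (n, 3):
                raise ValueError("every frame must match the template atom count")
        if len(self.frames) != len(self.times):
            raise ValueError("frames and times must have equal length")
        if any(t2 <= t1 for t1, t2 in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def frame_structure(self, k: int) -> MolecularStructure:
        return self.template.with_coordinates(self.frames[k])


@dataclass
class TopologyParams:
    """Per-atom charge/LJ/Born/radius parameters plus per-residue flags.

    Arrays are aligned with the paired structure's atom order.  ``hydrophobic``
    maps residue key ``(chain, residue_id)`` to a flag; ``ligand_selection``
    lists the ligand's atom indices.
    """

    charge: np.ndarray        # e
    lj_sigma: np.ndarray      # A
    lj_epsilon: np.ndarray    # kcal/mol
    born_radius: np.ndarray   # A
    intrinsic_radius: np.ndarray  # A
    hydrophobic: dict[tuple[str, int], bool] = field(default_factory=dict)
    ligand_selection: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("charge", "lj_sigma", "lj_epsilon", "born_radius", "intrinsic_radius"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.charge)
        for name in ("lj_sigma", "lj_epsilon", "born_radius", "intrinsic_radius"):
            if len(getattr(self, name)) != n:
                raise ValueError("parameter arrays must have equal length")
        if np.any(self.born_radius <= 0):
            raise ValueError("born_radius must be positive")
        if np.any(self.intrinsic_radius <= 0):
            raise ValueError("intrinsic_radius must be positive")

    def subset(self, indices: Sequence[int]) -> "TopologyParams":
        idx = list(indices)
        remap = {old: new for new, old in enumerate(idx)}
        return TopologyParams(
            charge=self.charge[idx],
            lj_sigma=self.lj_sigma[idx],
            lj_epsilon=self.lj_epsilon[idx],
            born_radius=self.born_radius[idx],
            intrinsic_radius=self.intrinsic_radius[idx],
            hydrophobic=dict(self.hydrophobic),
            ligand_selection=[remap[i] for i in self.ligand_selection if i in remap],
        )


# ---------------------------------------------------------------------------
# PDB reading/writing

def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        residue_name = line[17:20].strip()
        chain = line[21] if len(line) > 21 and line[21] != " " else "A"
        residue_id = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBFormatError(f"line {lineno}: malformed fixed-width field: {exc}") from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = name[:1]
    return AtomRecord(serial, name, element, residue_name, residue_id, chain, np.array([x, y, z]))


def _ensure_stream(source: str | IO[str]) -> IO[str]:
    if isinstance(source, str):
        return _io.StringIO(source)
    return source


def read_pdb(stream: str | IO[str]) -> MolecularStructure:
    """Parse the first model of a PDB stream into a :class:`MolecularStructure`.

    ``MODEL``/``ENDMDL`` cards are honoured: only model 1 is read.  Raises
    :class:`PDBFormatError` on malformed coordinate fields (naming the line)
    or on input without any ATOM/HETATM record.
    """
    stream = _ensure_stream(stream)
    atoms: list[AtomRecord] = []
    in_model = 0
    for lineno, line in enumerate(stream, start=1):
        rec = line[:6]
        if rec == "MODEL ":
            in_model += 1
            if in_model > 1:
                break
        elif rec == "ENDMDL":
            break
        elif rec in ("ATOM  ", "HETATM"):
            atoms.append(_parse_atom_line(line, lineno))
    if not atoms:
        raise PDBFormatError("no ATOM/HETATM records found (empty structure)")
    return MolecularStructure(atoms)


def _format_atom_line(a: AtomRecord) -> str:
    fields = [f"{c:8.3f}" for c in a.position]
    if any(len(f) > 8 for f in fields):  # >= 10000 or <= -1000: 8.3f overflows
        raise PDBFormatError(
            f"atom {a.serial}: coordinate does not fit the fixed 8-column "
            "field (overflow)"
        )
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    return (
        f"ATOM  {a.serial:>5d} {name:<4.4s} {a.residue_name:<3.3s} {a.chain:1.1s}"
        f"{a.residue_id:>4d}    {fields[0]}{fields[1]}{fields[2]}"
        f"  1.00  0.00          {a.element:>2.2s}"
    )


def write_pdb(structure: MolecularStructure, stream: IO[str] | None = None) -> str:
    """Serialize a structure to fixed-column PDB text (3-decimal coordinates)."""
    if not structure.atoms:
        raise PDBFormatError("cannot write an empty structure")
    lines = [_format_atom_line(a) for a in structure.atoms]
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if stream is not None:
        stream.write(text)
    return text


def read_trajectory(stream: str | IO[str], dt: float) -> Trajectory:
    """Read a multi-model PDB as a pseudo-trajectory.

    Frame ``k`` (1-based) is stamped ``k * dt`` ps — frames are snapshots at
    interval ends.  The template comes from model 1.  A single-model file
    yields a one-frame trajectory.  Inconsistent atom counts across models
    raise :class:`PDBFormatError`.
    """
    stream = _ensure_stream(stream)
    models: list[list[AtomRecord]] = []
    current: list[AtomRecord] = []
    saw_model_card = False
    for lineno, line in enumerate(stream, start=1):
        rec = line[:6]
        if rec == "MODEL ":
            saw_model_card = True
            current = []
        elif rec == "ENDMDL":
            models.append(current)
            current = []
        elif rec in ("ATOM  ", "HETATM"):
            current.append(_parse_atom_line(line, lineno))
    if current:
        models.append(current)
    models = [m for m in models if m]
    if not models:
        raise PDBFormatError("no ATOM/HETATM records found (empty trajectory)")
    n0 = len(models[0])
    for k, m in enumerate(models, start=1):
        if len(m) != n0:
            raise PDBFormatError(
                f"model {k} has {len(m)} atoms, expected {n0}: inconsistent atom count"
            )
    template = MolecularStructure(models[0])
    frames = [np.array([a.position for a in m], dtype=float) for m in models]
    times = [dt * (k + 1) for k in range(len(frames))]
    return Trajectory(frames=frames, times=times, template=template)


def write_trajectory(traj: Trajectory, stream: IO[str] | None = None) -> str:
    """Serialize a trajectory as a multi-model PDB (MODEL/ENDMDL wrapped)."""
    if len(traj) == 0:
        raise PDBFormatError("cannot write a trajectory with no frames")
    chunks = []
    for k in range(len(traj)):
        chunks.append(f"MODEL     {k + 1:>4d}")
        s = traj.frame_structure(k)
        chunks.extend(_format_atom_line(a) for a in s.atoms)
        chunks.append("ENDMDL")
    chunks.append("END")
    text = "\n".join(chunks) + "\n"
    if stream is not None:
        stream.write(text)
    return text


# ---------------------------------------------------------------------------
# Topology sidecar (TSV)

_TOPOLOGY_COLUMNS = ("serial", "charge", "sigma", "epsilon", "born_radius", "intrinsic_radius")


def read_topology(stream: str | IO[str], structure: MolecularStructure) -> TopologyParams:
    """Read the TSV parameter sidecar for ``structure``.

    One row per atom, keyed by serial.  Optional header directives:
    ``#ligand_serials`` (space-separated atom serials marking the ligand) and
    ``#hydrophobic`` (space-separated ``chain:resid`` keys).  Raises
    :class:`TopologyError` listing any structure serial without a row.
    """
    stream = _ensure_stream(stream)
    rows: dict[int, tuple[float, ...]] = {}
    ligand_serials: list[int] = []
    hydrophobic_keys: set[tuple[str, int]] = set()
    header_seen = False
    for line in stream:
        line = line.strip()
        if not line:
            continue
        if line.startswith("#ligand_serials"):
            ligand_serials = [int(tok) for tok in line.split()[1:]]
            continue
        if line.startswith("#hydrophobic"):
            for tok in line.split()[1:]:
                chain, rid = tok.split(":")
                hydrophobic_keys.add((chain, int(rid)))
            continue
        if line.startswith("#"):
            continue
        if not header_seen:
            header_seen = True
            if line.split("\t")[0] == "serial":
                continue
        parts = line.split("\t")
        serial = int(parts[0])
        rows[serial] = tuple(float(p) for p in parts[1:6])
    missing = [a.serial for a in structure.atoms if a.serial not in rows]
    if missing:
        raise TopologyError(f"sidecar missing parameters for atom serials: {missing}")
    vals = np.array([rows[a.serial] for a in structure.atoms], dtype=float)
    serial_to_index = {a.serial: i for i, a in enumerate(structure.atoms)}
    hydrophobic = {
        key: (key in hydrophobic_keys) for key in structure.residue_index
    }
    return TopologyParams(
        charge=vals[:, 0],
        lj_sigma=vals[:, 1],
        lj_epsilon=vals[:, 2],
        born_radius=vals[:, 3],
        intrinsic_radius=vals[:, 4],
        hydrophobic=hydrophobic,
        ligand_selection=[serial_to_index[s] for s in ligand_serials],
    )


def write_topology(
    params: TopologyParams, structure: MolecularStructure, stream: IO[str] | None = None
) -> str:
    """Serialize a :class:`TopologyParams` sidecar as TSV."""
    lines = []
    if params.ligand_selection:
        serials = " ".join(str(structure.atoms[i].serial) for i in params.ligand_selection)
        lines.append(f"#ligand_serials {serials}")
    hydro = [f"{c}:{r}" for (c, r), flag in sorted(params.hydrophobic.items()) if flag]
    if hydro:
        lines.append("#hydrophobic " + " ".join(hydro))
    lines.append("\t".join(_TOPOLOGY_COLUMNS))
    for i, a in enumerate(structure.atoms):
        lines.append(
            f"{a.serial}\t{params.charge[i]:.6f}\t{params.lj_sigma[i]:.6f}\t"
            f"{params.lj_epsilon[i]:.6f}\t{params.born_radius[i]:.6f}\t"
            f"{params.intrinsic_radius[i]:.6f}"
        )
    text = "\n".join(lines) + "\n"
    if stream is not None:
        stream.write(text)
    return text
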
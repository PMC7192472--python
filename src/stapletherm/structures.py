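"""Domain types and structure I/O for peptide–protein complex analysis.

Defines the atom/structure/trajectory containers used throughout the
package, PDB reading and writing (multi-MODEL files become multi-frame
trajectories), force-field parameter assignment from a columnar table,
and the peptide/receptor partition of a complex.

Units are fixed globally: Ångström for lengths, kcal/mol for energies,
elementary charge units for partial charges, Kelvin for temperatures.
"""

from __future__ import annotations

import copy
import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

logger = logging.getLogger("stapletherm")

LINKER_GROUP = "LINKER"


class StructureError(ValueError):
    """Raised for malformed structures, trajectories or PDB files."""


class SelectionError(ValueError):
    """Raised when an atom selection is empty, overlapping or unresolvable."""


class ParameterError(ValueError):
    """Raised when force-field parameter assignment fails."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class AtomRecord:
    """A single atom with coordinates and nonbonded parameters.

    Attributes
    ----------
    atom_id : int
        Unique (within a structure) 1-based serial number.
    atom_name, element : str
        PDB atom name and chemical element symbol.
    residue_index : int
        1-based sequential residue number within the chain.
    residue_name, chain_id : str
        Residue name and single-letter chain identifier.
    position : ndarray, shape (3,)
        Cartesian coordinates in Å (reference/topology coordinates).
    partial_charge : float
        Partial charge in elementary charge units.
    lj_sigma, lj_epsilon : float
        Lennard-Jones σ (Å) and ε (kcal/mol).
    intrinsic_radius : float
        Intrinsic (unscreened) Born/solvation radius in Å.
    group_label : str
        Decomposition group key, by default the residue key
        ``chain:resindex:resname``; staple atoms carry ``"LINKER"``.
    """

    atom_id: int
    atom_name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    position: np.ndarray
    partial_charge: float = 0.0
    lj_sigma: float = 1.0
    lj_epsilon: float = 0.0
    intrinsic_radius: float = 1.5
    group_label: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise StructureError(
                f"atom {self.atom_id}: position must be a finite 3-vector"
            )
        if self.lj_sigma <= 0:
            raise StructureError(f"atom {self.atom_id}: lj_sigma must be > 0")
        if self.lj_epsilon < 0:
            raise StructureError(f"atom {self.atom_id}: lj_epsilon must be >= 0")
        if self.intrinsic_radius <= 0:
            raise StructureError(f"atom {self.atom_id}: intrinsic_radius must be > 0")
        if not self.group_label:
            self.group_label = self.residue_key

    @property
    def residue_key(self) -> str:
        """Residue key ``chain:resindex:resname`` used in all reports."""
        return f"{self.chain_id}:{self.residue_index}:{self.residue_name}"


@dataclass
class Structure:
    """An ordered collection of atoms (one conformation)."""

    atoms: list[AtomRecord]
    title: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError("structure must contain at least one atom")
        ids = [a.atom_id for a in self.atoms]
        if len(set(ids)) != len(ids):
            raise StructureError("atom_id values must be unique within a structure")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) array of the topology's own coordinates."""
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def atom_ids(self) -> np.ndarray:
        return np.array([a.atom_id for a in self.atoms], dtype=int)

    def index_of(self, atom_ids: Iterable[int]) -> np.ndarray:
        """Positions (0-based) of the given atom ids in atom order."""
        lookup = {a.atom_id: i for i, a in enumerate(self.atoms)}
        try:
            return np.array([lookup[i] for i in atom_ids], dtype=int)
        except KeyError as exc:
            raise StructureError(f"unknown atom_id {exc.args[0]}") from exc

    def residue_keys(self) -> list[str]:
        """Ordered unique residue keys."""
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_key)
        return list(seen)


@dataclass
class Trajectory:
    """Ordered frames of coordinates over a fixed topology.

    ``frames`` has shape (n_frames, n_atoms, 3) in Å; the frame interval
    is in nanoseconds (snapshots saved at a fixed interval).
    """

    topology: Structure
    frames: np.ndarray
    frame_interval_ns: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim == 2:
            self.frames = self.frames[None, :, :]
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise StructureError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != len(self.topology):
            raise StructureError(
                f"inconsistent atom count: topology has {len(self.topology)} atoms, "
                f"frames have {self.frames.shape[1]}"
            )
        if self.frame_interval_ns <= 0:
            raise StructureError("frame_interval_ns must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


@dataclass
class ComplexSystem:
    """A trajectory partitioned into peptide and receptor atom sets."""

    trajectory: Trajectory
    peptide_atom_ids: frozenset[int]
    receptor_atom_ids: frozenset[int]

    def __post_init__(self) -> None:
        self.peptide_atom_ids = frozenset(self.peptide_atom_ids)
        self.receptor_atom_ids = frozenset(self.receptor_atom_ids)
        if not self.peptide_atom_ids or not self.receptor_atom_ids:
            raise SelectionError("empty selection: peptide and receptor must be non-empty")
        if self.peptide_atom_ids & self.receptor_atom_ids:
            raise SelectionError("overlap: peptide and receptor selections intersect")
        known = set(self.topology.atom_ids.tolist())
        stray = (self.peptide_atom_ids | self.receptor_atom_ids) - known
        if stray:
            raise SelectionError(f"selection references unknown atom ids {sorted(stray)}")

    @property
    def topology(self) -> Structure:
        return self.trajectory.topology

    @property
    def peptide_index(self) -> np.ndarray:
        """0-based positions of peptide atoms, in topology order."""
        mask = np.isin(self.topology.atom_ids, sorted(self.peptide_atom_ids))
        return np.nonzero(mask)[0]

    @property
    def receptor_index(self) -> np.ndarray:
        mask = np.isin(self.topology.atom_ids, sorted(self.receptor_atom_ids))
        return np.nonzero(mask)[0]


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _renumber_residues(chain_ids: np.ndarray, res_ids: np.ndarray) -> np.ndarray:
    """1-based sequential residue numbering per chain (PDB order)."""
    out = np.empty(len(res_ids), dtype=int)
    current_chain = None
    counter = 0
    last = None
    for i, (ch, rid) in enumerate(zip(chain_ids, res_ids)):
        if ch != current_chain:
            current_chain, counter, last = ch, 0, None
        if rid != last:
            counter += 1
            last = rid
        out[i] = counter
    return out


def read_pdb(path: str | Path) -> Trajectory:
    """Read a PDB file into a :class:`Trajectory`.

    Each MODEL block becomes one frame (a single frame if the file has
    no MODEL records). HETATM records are read like ATOM records so that
    non-standard staple/linker residues parse. For atoms with alternate
    locations the highest-occupancy conformer is kept (ties resolved
    toward altloc 'A'). Atom ids are assigned sequentially from 1.

    Raises
    ------
    StructureError
        If the file is missing, contains no atoms, or its MODEL blocks
        have inconsistent atom counts.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such PDB file: {path}")
    pdb = PDBFile.read(str(path))
    try:
        stack = pdb.get_structure(model=None, altloc="occupancy")
    except Exception as exc:  # biotite raises on ragged MODEL blocks
        raise StructureError(f"inconsistent atom count across MODEL blocks: {exc}") from exc
    if stack.array_length() == 0:
        raise StructureError(f"{path}: no ATOM/HETATM records")
    if not np.all(np.isfinite(stack.coord)):
        raise StructureError(f"{path}: unparseable/non-finite coordinates")

    res_index = _renumber_residues(stack.chain_id, stack.res_id)
    first = stack.coord[0]
    atoms = []
    for i in range(stack.array_length()):
        elem = str(stack.element[i]).strip() or str(stack.atom_name[i])[:1]
        atoms.append(
            AtomRecord(
                atom_id=i + 1,
                atom_name=str(stack.atom_name[i]),
                element=elem,
                residue_index=int(res_index[i]),
                residue_name=str(stack.res_name[i]),
                chain_id=str(stack.chain_id[i]),
                position=first[i],
            )
        )
    topo = Structure(atoms=atoms, title=path.stem)
    return Trajectory(topology=topo, frames=np.array(stack.coord, dtype=float))


def _to_atom_array(topology: Structure, coords: np.ndarray) -> struc.AtomArray:
    n = len(topology)
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.chain_id = np.array([a.chain_id for a in topology.atoms])
    arr.res_id = np.array([a.residue_index for a in topology.atoms])
    arr.res_name = np.array([a.residue_name for a in topology.atoms])
    arr.atom_name = np.array([a.atom_name for a in topology.atoms])
    arr.element = np.array([a.element.upper() for a in topology.atoms])
    arr.hetero = np.array([not _is_standard(a.residue_name) for a in topology.atoms])
    return arr


_STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def _is_standard(res_name: str) -> bool:
    return res_name in _STANDARD_RESIDUES


def write_pdb(trajectory: Trajectory, path: str | Path) -> None:
    """Write a trajectory as PDB, one MODEL block per frame.

    Single-frame trajectories are written without MODEL records;
    multi-frame ones with MODEL/ENDMDL pairs. Coordinates use the
    standard fixed %8.3f columns, so round-tripping through
    :func:`read_pdb` preserves coordinates to 1e-3 Å.
    """
    pdb = PDBFile()
    if trajectory.n_frames == 1:
        pdb.set_structure(_to_atom_array(trajectory.topology, trajectory.frames[0]))
    else:
        arrays = [_to_atom_array(trajectory.topology, f) for f in trajectory.frames]
        stack = struc.stack(arrays)
        pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Parameter tables
# ---------------------------------------------------------------------------

@dataclass
class ParameterTable:
    """Nonbonded parameters keyed by (residue_name, atom_name).

    ``entries`` maps each key to (charge, lj_sigma, lj_epsilon,
    intrinsic_radius); ``formal_charges`` optionally declares the net
    charge each residue type must sum to, which is checked at
    assignment time.
    """

    entries: dict[tuple[str, str], tuple[float, float, float, float]]
    formal_charges: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ParameterTable":
        """Load from CSV with header residue_name,atom_name,charge,sigma,epsilon,radius.

        Lines of the form ``# formal_charge <residue_name> <charge>``
        declare residue net charges.
        """
        entries: dict[tuple[str, str], tuple[float, float, float, float]] = {}
        formal: dict[str, float] = {}
        with open(path, newline="") as fh:
            rows = []
            for raw in fh:
                line = raw.strip()
                if line.startswith("# formal_charge"):
                    _, _, res, q = line.split()
                    formal[res] = float(q)
                elif line and not line.startswith("#"):
                    rows.append(line)
        reader = csv.DictReader(rows)
        for row in reader:
            key = (row["residue_name"].strip(), row["atom_name"].strip())
            entries[key] = (
                float(row["charge"]),
                float(row["sigma"]),
                float(row["epsilon"]),
                float(row["radius"]),
            )
        return cls(entries=entries, formal_charges=formal)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            for res, q in sorted(self.formal_charges.items()):
                fh.write(f"# formal_charge {res} {q:.6f}\n")
            fh.write("residue_name,atom_name,charge,sigma,epsilon,radius\n")
            for (res, name), (q, s, e, r) in self.entries.items():
                fh.write(f"{res},{name},{q:.6f},{s:.6f},{e:.6f},{r:.6f}\n")


def assign_parameters(
    trajectory: Trajectory, table: ParameterTable, strict: bool = True
) -> Trajectory:
    """Return a copy of the trajectory with nonbonded parameters assigned.

    Every atom is looked up by (residue_name, atom_name). In strict mode
    an atom with no table entry raises :class:`ParameterError` naming
    every missing key; otherwise such atoms keep their current
    parameters. If the table declares residue formal charges, the summed
    per-residue charges are checked against them to 1e-6 e.

    The operation is idempotent: assigning the same table twice yields
    identical atoms.
    """
    missing = []
    new_atoms = []
    for atom in trajectory.topology.atoms:
        key = (atom.residue_name, atom.atom_name)
        if key in table.entries:
            q, s, e, r = table.entries[key]
            new_atoms.append(
                replace(atom, partial_charge=q, lj_sigma=s, lj_epsilon=e,
                        intrinsic_radius=r, position=atom.position.copy())
            )
        else:
            if strict:
                missing.append(key)
            new_atoms.append(copy.deepcopy(atom))
    if missing:
        raise ParameterError(
            "no parameter entry for atoms: "
            + ", ".join(f"({r}, {a})" for r, a in sorted(set(missing)))
        )

    # per-residue net charge check against declared formal charges
    sums: dict[tuple[str, int, str], float] = {}
    for atom in new_atoms:
        k = (atom.chain_id, atom.residue_index, atom.residue_name)
        sums[k] = sums.get(k, 0.0) + atom.partial_charge
    for (ch, idx, res), total in sums.items():
        if res in table.formal_charges:
            declared = table.formal_charges[res]
            if abs(total - declared) > 1e-6:
                raise ParameterError(
                    f"residue {ch}:{idx}:{res} charge sum {total:.6f} != "
                    f"declared formal charge {declared:.6f}"
                )

    topo = Structure(atoms=new_atoms, title=trajectory.topology.title)
    return Trajectory(topo, trajectory.frames.copy(), trajectory.frame_interval_ns)


# ---------------------------------------------------------------------------
# Selections and complex definition
# ---------------------------------------------------------------------------

def select_atoms(structure: Structure, expression: str) -> frozenset[int]:
    """Resolve a selection expression to a set of atom ids.

    Supported clauses, joined with ``and``:

    - ``chain <id>``
    - ``resid <n>`` / ``resid <a>-<b>`` / ``resid <n> <m> ...``
    - ``resname <name>``
    - ``all``
    """
    selected = set(structure.atom_ids.tolist())
    for clause in expression.split(" and "):
        tokens = clause.split()
        if not tokens:
            continue
        kind = tokens[0].lower()
        if kind == "all":
            continue
        if kind == "chain":
            keep = {a.atom_id for a in structure.atoms if a.chain_id in tokens[1:]}
        elif kind == "resname":
            keep = {a.atom_id for a in structure.atoms if a.residue_name in tokens[1:]}
        elif kind == "resid":
            wanted: set[int] = set()
            for tok in tokens[1:]:
                if "-" in tok[1:]:
                    lo, hi = tok.split("-")
                    wanted.update(range(int(lo), int(hi) + 1))
                else:
                    wanted.add(int(tok))
            keep = {a.atom_id for a in structure.atoms if a.residue_index in wanted}
        else:
            raise SelectionError(f"unknown selection clause: {clause!r}")
        selected &= keep
    return frozenset(selected)


def define_complex(
    trajectory: Trajectory, peptide_selector: str, receptor_selector: str
) -> ComplexSystem:
    """Partition a trajectory into a peptide/receptor :class:`ComplexSystem`.

    The two selectors must resolve to disjoint non-empty atom sets.
    Atoms matched by neither selector are excluded from binding
    analysis; their count is reported in the log.
    """
    topo = trajectory.topology
    pep = select_atoms(topo, peptide_selector)
    rec = select_atoms(topo, receptor_selector)
    if not pep:
        raise SelectionError(f"empty selection: {peptide_selector!r} matches no atoms")
    if not rec:
        raise SelectionError(f"empty selection: {receptor_selector!r} matches no atoms")
    if pep & rec:
        raise SelectionError(
            f"overlap: selectors {peptide_selector!r} and {receptor_selector!r} "
            f"share {len(pep & rec)} atoms"
        )
    leftover = set(topo.atom_ids.tolist()) - pep - rec
    if leftover:
        logger.info(
            "define_complex: %d atoms matched by neither selector are excluded "
            "from binding analysis", len(leftover),
        )
    return ComplexSystem(trajectory, pep, rec)


def label_linker(trajectory: Trajectory, atom_ids: Iterable[int]) -> Trajectory:
    """Return a copy where the given atoms carry group_label ``"LINKER"``.

    All other atoms keep their residue-derived labels. An empty id set
    returns an unchanged copy; unknown ids raise.
    """
    wanted = set(atom_ids)
    known = set(trajectory.topology.atom_ids.tolist())
    unknown = wanted - known
    if unknown:
        raise StructureError(f"label_linker: unknown atom ids {sorted(unknown)}")
    new_atoms = [
        replace(a, group_label=LINKER_GROUP, position=a.position.copy())
        if a.atom_id in wanted
        else copy.deepcopy(a)
        for a in trajectory.topology.atoms
    ]
    topo = Structure(atoms=new_atoms, title=trajectory.topology.title)
    return Trajectory(topo, trajectory.frames.copy(), trajectory.frame_interval_ns)
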
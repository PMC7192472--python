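"""Synthetic stapled-peptide/receptor complexes with planted ground truth.

The generator emulates the statistical shape of a stapled p53-mimetic
bound to a hydrophobic surface pocket: an 11-residue α-helical peptide
(default sequence modelled on Ac-TSFXEYWALLX-NH2, X = staple positions)
with three epitope residues (F3, W7, L10) whose side chains reach into
a concave receptor shell, an 8-pseudo-atom hydrocarbon staple bridging
the two X positions on a helix face adjacent to the pocket rim, and a
receptor made of uncharged Lennard-Jones spheres plus charged probe
atoms facing the epitope side chains and a hydrophobic patch facing
the staple.

Parameters are planted so that the three epitope groups and the staple
(group ``LINKER``) dominate the effective binding free energy — the
generator records this as machine-checkable ground truth. Replica
trajectories are the base conformation plus isotropic Gaussian
positional noise (no physics: the analysis layer, not the sampler, is
the artifact under test).

Coordinates are reduced-detail: 4 backbone atoms (N, CA, C, O) plus one
side-chain pseudo-atom per residue, which keeps pair counts desk-scale
while preserving the full per-group decomposition structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .structures import (
    AtomRecord,
    ComplexSystem,
    LINKER_GROUP,
    ParameterTable,
    Structure,
    StructureError,
    Trajectory,
)


class SynthesisError(ValueError):
    """Raised for invalid synthetic specifications or unresolvable clashes."""


# default 11-mer modelled on the stapled p53 mimetic sequence
_DEFAULT_SEQUENCE = (
    "THR", "SER", "PHE", "XLK", "GLU", "TYR", "TRP", "ALA", "LEU", "LEU", "XLK"
)

# ideal α-helix backbone dihedrals and geometry (Engh–Huber-like values)
_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0
_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231}
_ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7, "CA-C-O": 120.8}


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic complex ensemble.

    Defaults mirror the ensemble shape the analysis expects: an
    11-residue peptide with epitope residues 3, 7, 10 and staple
    positions 4 and 11, ten independent replicas of 100 frames each
    (1 ns frame interval) with 0.3 Å isotropic positional noise.
    ``attenuation`` scales the planted epitope/staple interaction
    strengths (1.0 = full strength); ``linker_face_angle_deg`` sets
    where on the helix surface the staple sits relative to the pocket
    direction.
    """

    n_peptide_residues: int = 11
    epitope_positions: tuple[int, ...] = (3, 7, 10)
    linker_positions: tuple[int, int] = (4, 11)
    n_receptor_atoms: int = 48
    pocket_depth: float = 6.0
    n_frames: int = 100
    n_replicas: int = 10
    noise_sigma: float = 0.3
    seed: int = 0
    attenuation: float = 1.0
    linker_face_angle_deg: float = 65.0
    peptide_drift: float = 0.0

    def __post_init__(self) -> None:
        n = self.n_peptide_residues
        for p in (*self.epitope_positions, *self.linker_positions):
            if not 1 <= p <= n:
                raise SynthesisError(f"residue position {p} outside [1, {n}]")
        if self.linker_positions[0] == self.linker_positions[1]:
            raise SynthesisError("linker positions must differ")
        if self.noise_sigma < 0:
            raise SynthesisError("noise_sigma must be >= 0")
        if self.n_replicas < 1:
            raise SynthesisError("n_replicas must be >= 1")
        if not 0 < self.attenuation <= 1:
            raise SynthesisError("attenuation must be in (0, 1]")


@dataclass
class GroundTruth:
    """Planted interaction structure of a synthetic complex.

    ``planted_interaction_strength`` gives the relative scale planted
    for each peptide-side group; ``per_group_expected_rank`` orders the
    groups by that scale (rank 1 = strongest). The epitope groups and
    ``LINKER`` carry the largest strengths by construction.
    """

    per_group_expected_rank: dict[str, int]
    planted_interaction_strength: dict[str, float]

    @property
    def hotspot_groups(self) -> set[str]:
        """The planted top-4 groups (3 epitope residues + LINKER)."""
        return {g for g, r in self.per_group_expected_rank.items() if r <= 4}


# ---------------------------------------------------------------------------
# Ideal helix construction (NeRF internal-coordinate build)
# ---------------------------------------------------------------------------

def _place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float):
    """Place atom D given A-B-C with |C-D|, angle(B,C,D) and dihedral(A,B,C,D)."""
    angle = math.radians(angle_deg)
    dihedral = math.radians(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(dihedral),
        bond * math.sin(angle) * math.sin(dihedral),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_ideal_helix(n_residues: int) -> dict[str, np.ndarray]:
    """Backbone coordinates of an ideal α-helix (φ=−57°, ψ=−47°).

    Returns arrays of shape (n_residues, 3) for the atoms "N", "CA",
    "C", "O". The construction yields the canonical ~1.5 Å rise and
    ~100° twist per residue.
    """
    if n_residues < 1:
        raise SynthesisError("need at least one residue")
    N = np.zeros((n_residues, 3))
    CA = np.zeros((n_residues, 3))
    C = np.zeros((n_residues, 3))
    O = np.zeros((n_residues, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_BOND["N-CA"], 0.0, 0.0)
    ang = math.radians(_ANGLE["N-CA-C"])
    C[0] = CA[0] + _BOND["CA-C"] * np.array([-math.cos(ang), math.sin(ang), 0.0])
    for i in range(1, n_residues):
        N[i] = _place_atom(N[i - 1], CA[i - 1], C[i - 1],
                           _BOND["C-N"], _ANGLE["CA-C-N"], _PSI)
        CA[i] = _place_atom(CA[i - 1], C[i - 1], N[i],
                            _BOND["N-CA"], _ANGLE["C-N-CA"], _OMEGA)
        C[i] = _place_atom(C[i - 1], N[i], CA[i],
                           _BOND["CA-C"], _ANGLE["N-CA-C"], _PHI)
    for i in range(n_residues):
        # carbonyl O anti to the next amide N (dihedral ψ+180 about CA-C)
        ref_n = N[i]
        O[i] = _place_atom(ref_n, CA[i], C[i],
                           _BOND["C-O"], _ANGLE["CA-C-O"], _PSI + 180.0)
    return {"N": N, "CA": CA, "C": C, "O": O}


def _helix_axis(ca: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares helix axis: (point on axis, unit direction)."""
    center = ca.mean(axis=0)
    _, _, vt = np.linalg.svd(ca - center)
    axis = vt[0]
    if axis @ (ca[-1] - ca[0]) < 0:
        axis = -axis
    return center, axis


def _radial_direction(point: np.ndarray, center: np.ndarray, axis: np.ndarray) -> np.ndarray:
    rel = point - center
    rad = rel - (rel @ axis) * axis
    norm = np.linalg.norm(rad)
    if norm < 1e-9:
        raise SynthesisError("point lies on the helix axis")
    return rad / norm


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation of v about a unit axis."""
    t = math.radians(angle_deg)
    return (v * math.cos(t) + np.cross(axis, v) * math.sin(t)
            + axis * (axis @ v) * (1.0 - math.cos(t)))


# ---------------------------------------------------------------------------
# Parameter plant
# ---------------------------------------------------------------------------

# (charge e, lj_sigma Å, lj_epsilon kcal/mol, intrinsic_radius Å)
_BACKBONE_PARAMS = {
    "N": (-0.20, 3.25, 0.17, 1.55),
    "CA": (0.05, 3.40, 0.11, 1.70),
    "C": (0.25, 3.40, 0.09, 1.70),
    "O": (-0.25, 2.96, 0.21, 1.50),
}
_SC_PARAMS = (0.15, 3.60, 0.08, 2.00)        # ordinary side-chain pseudo-atom
_SCE_PARAMS = (0.15, 3.20, 4.30, 2.10)       # epitope side-chain pseudo-atom
_LINKER_PARAMS = (0.00, 3.40, 2.70, 2.00)    # staple CH2-like pseudo-atom
_WALL_PARAMS = (0.00, 3.40, 0.25, 1.90)      # uncharged receptor shell sphere
_PROBE_BASE = (-0.20, 3.20, 4.30, 1.80)      # charged probe facing an epitope tip
_COUNTER_BASE = (0.20, 3.40, 0.10, 2.00)     # counter-charge behind the shell
_PATCH_BASE = (0.00, 3.40, 2.00, 1.90)       # hydrophobic patch facing the staple

_EPITOPE_TIP_LENGTH = 3.8   # Å, epitope side chain reach from CA
_SC_LENGTH = 1.8            # Å, ordinary side chain reach
# planted partners sit at ~1.3 σ_pair — inside the attractive well, with a
# wide buffer before the repulsive wall (so positional noise essentially
# never flips the sign of a planted contact) yet within the 4.5 Å
# hydrophobic-contact convention, keeping the planted contacts visible to
# the interface-contact analysis
_PROBE_GAP = 4.32           # Å, epitope tip -> probe distance (1.35 σ)
_PATCH_GAP = 4.45           # Å, staple atom -> patch distance (1.31 σ)
_LINKER_SIZE = 8            # staple pseudo-atoms
_CLASH_LIMIT = 0.8          # Å


def _sequence_for(spec: SyntheticSpec) -> list[str]:
    if spec.n_peptide_residues == len(_DEFAULT_SEQUENCE) and spec.linker_positions == (4, 11):
        return list(_DEFAULT_SEQUENCE)
    seq = ["ALA"] * spec.n_peptide_residues
    for p in spec.linker_positions:
        seq[p - 1] = "XLK"
    return seq


def generate_complex(spec: SyntheticSpec) -> tuple[ComplexSystem, GroundTruth]:
    """Build one synthetic complex with planted hotspot ground truth.

    Peptide chain P: ideal α-helix backbone plus one side-chain
    pseudo-atom per residue (epitope side chains extended toward the
    receptor pocket) plus the 8-atom staple (group ``LINKER``).
    Receptor chain R: concave shell of uncharged LJ spheres around the
    epitope tips, one charged probe per epitope tip, and a hydrophobic
    patch facing the staple. Same spec and seed give bitwise-identical
    coordinates.

    Raises
    ------
    SynthesisError
        If geometry cannot be made clash-free (all interatomic
        distances >= 0.8 Å) within 100 jitter attempts.
    """
    rng = np.random.default_rng(spec.seed)
    for attempt in range(100):
        jitter = 0.0 if attempt == 0 else 0.05 * attempt
        system, truth = _build_complex(spec, rng, jitter)
        coords = system.trajectory.frames[0]
        diff = coords[:, None, :] - coords[None, :, :]
        d = np.sqrt(np.sum(diff * diff, axis=-1))
        np.fill_diagonal(d, np.inf)
        if d.min() >= _CLASH_LIMIT:
            return system, truth
    raise SynthesisError(
        f"geometry clash (< {_CLASH_LIMIT} Å) persisted over 100 attempts"
    )


def _build_complex(spec: SyntheticSpec, rng: np.random.Generator, jitter: float):
    seq = _sequence_for(spec)
    bb = build_ideal_helix(spec.n_peptide_residues)
    center, axis = _helix_axis(bb["CA"])
    att = spec.attenuation

    radial = [_radial_direction(bb["CA"][i], center, axis)
              for i in range(spec.n_peptide_residues)]
    epitope = set(spec.epitope_positions)
    pocket_dir = np.sum([radial[i - 1] for i in sorted(epitope)], axis=0)
    pocket_dir /= np.linalg.norm(pocket_dir)

    atoms: list[AtomRecord] = []
    atom_id = 0

    def add(name, element, res_idx, res_name, chain, pos, params, group=""):
        nonlocal atom_id
        atom_id += 1
        q, s, e, r = params
        atoms.append(AtomRecord(
            atom_id=atom_id, atom_name=name, element=element,
            residue_index=res_idx, residue_name=res_name, chain_id=chain,
            position=np.asarray(pos, float) + (rng.normal(0.0, jitter, 3) if jitter else 0.0),
            partial_charge=q, lj_sigma=s, lj_epsilon=e, intrinsic_radius=r,
            group_label=group,
        ))
        return atoms[-1]

    # ---- peptide chain P ------------------------------------------------
    tips: dict[int, np.ndarray] = {}
    tip_dirs: dict[int, np.ndarray] = {}
    for i in range(spec.n_peptide_residues):
        res_idx, res_name = i + 1, seq[i]
        for name in ("N", "CA", "C", "O"):
            elem = name[0]
            add(name, elem, res_idx, res_name, "P", bb[name][i],
                _BACKBONE_PARAMS[name])
        if res_idx in epitope:
            tip = bb["CA"][i] + _EPITOPE_TIP_LENGTH * radial[i]
            tips[res_idx] = tip
            tip_dirs[res_idx] = radial[i]
            add("SCE", "C", res_idx, res_name, "P", tip, _SCE_PARAMS)
        else:
            add("SC", "C", res_idx, res_name, "P",
                bb["CA"][i] + _SC_LENGTH * radial[i], _SC_PARAMS)

    # ---- staple (LINKER group) -----------------------------------------
    p1, p2 = sorted(spec.linker_positions)
    link_dir_base = _rotate_about(pocket_dir, axis, spec.linker_face_angle_deg)
    linker_positions = []
    for k in range(_LINKER_SIZE):
        t = (k + 0.5) / _LINKER_SIZE
        base_pt = (1 - t) * bb["CA"][p1 - 1] + t * bb["CA"][p2 - 1]
        reach = 2.2 + 1.4 * math.sin(math.pi * t)  # arc bulging off the helix face
        # orient the arc on the staple face, anchored at the X positions
        local_dir = _rotate_about(_radial_direction(base_pt, center, axis),
                                  axis, spec.linker_face_angle_deg)
        direction = link_dir_base if 0.2 < t < 0.8 else (
            0.5 * link_dir_base + 0.5 * local_dir
        )
        direction = direction / np.linalg.norm(direction)
        pos = base_pt + reach * direction
        linker_positions.append((pos, direction))
        add(f"L{k + 1}", "C", spec.n_peptide_residues + 1, "LNK", "P",
            pos, _LINKER_PARAMS, group=LINKER_GROUP)

    # ---- receptor chain R ----------------------------------------------
    probe_params = (_PROBE_BASE[0] * att, _PROBE_BASE[1],
                    _PROBE_BASE[2] * att * att, _PROBE_BASE[3])
    counter_params = (_COUNTER_BASE[0] * att, _COUNTER_BASE[1],
                      _COUNTER_BASE[2], _COUNTER_BASE[3])
    patch_params = (_PATCH_BASE[0], _PATCH_BASE[1],
                    _PATCH_BASE[2] * att * att, _PATCH_BASE[3])

    res_idx = 0
    for k, pos in sorted(tips.items()):
        res_idx += 1
        add("P1", "O", res_idx, "PRB", "R", pos + _PROBE_GAP * tip_dirs[k],
            probe_params)
    # counter-charges behind the shell keep the receptor net-neutral, so the
    # inter-molecular Coulomb energy decays as a dipole term on separation
    for k, pos in sorted(tips.items()):
        res_idx += 1
        add("I1", "N", res_idx, "CIO", "R",
            pos + (_PROBE_GAP + 6.0) * tip_dirs[k], counter_params)
    for k in (1, 3, 4, 6):  # four patch partners along the staple arc
        res_idx += 1
        pos, direction = linker_positions[k]
        add("Q1", "C", res_idx, "PAT", "R", pos + _PATCH_GAP * direction,
            patch_params)

    # concave shell: spherical caps around the tips opening toward the
    # peptide; outer shells are added if the innermost cap cannot hold
    # the requested atom count at the minimum packing distance
    cap_center = np.mean(list(tips.values()), axis=0)
    peptide_coords = np.array([a.position for a in atoms if a.chain_id == "P"])
    receptor_coords = np.array([a.position for a in atoms if a.chain_id == "R"])
    n_cand = max(8 * spec.n_receptor_atoms, 128)
    golden = math.pi * (1.0 + math.sqrt(5.0))
    placed = 0
    wall_slot = 0
    for shell in range(3):
        shell_radius = spec.pocket_depth + 3.0 * shell
        for k in range(n_cand):
            if placed >= spec.n_receptor_atoms:
                break
            z = 1.0 - 2.0 * (k + 0.5) / n_cand
            r = math.sqrt(max(0.0, 1.0 - z * z))
            direction = np.array([r * math.cos(golden * k), r * math.sin(golden * k), z])
            if direction @ pocket_dir < math.cos(math.radians(85.0)):
                continue
            pos = cap_center + shell_radius * direction
            # stay outside LJ-repulsive range of the peptide; pack freely
            # among receptor atoms (intra-receptor energies never enter)
            if np.min(np.linalg.norm(peptide_coords - pos, axis=1)) < 3.9:
                continue
            if np.min(np.linalg.norm(receptor_coords - pos, axis=1)) < 2.2:
                continue
            if wall_slot % 4 == 0:
                res_idx += 1
            wall_slot += 1
            add(f"W{(wall_slot - 1) % 4 + 1}", "C", res_idx, "WAL", "R", pos,
                _WALL_PARAMS)
            receptor_coords = np.vstack([receptor_coords, atoms[-1].position])
            placed += 1
        if placed >= spec.n_receptor_atoms:
            break

    topo = Structure(atoms=atoms, title=f"synthetic complex seed={spec.seed}")
    traj = Trajectory(topo, topo.coordinates[None, :, :], frame_interval_ns=1.0)
    pep_ids = frozenset(a.atom_id for a in atoms if a.chain_id == "P")
    rec_ids = frozenset(a.atom_id for a in atoms if a.chain_id == "R")
    system = ComplexSystem(traj, pep_ids, rec_ids)

    strengths: dict[str, float] = {}
    for a in atoms:
        if a.chain_id != "P":
            continue
        g = a.group_label
        if g in strengths:
            continue
        if a.residue_index in epitope and g != LINKER_GROUP:
            strengths[g] = 1.0 * att
        elif g == LINKER_GROUP:
            strengths[g] = 0.8 * att
        else:
            strengths[g] = 0.05 * att
    ranked = sorted(strengths, key=lambda g: (-strengths[g], g))
    ranks = {g: i + 1 for i, g in enumerate(ranked)}
    return system, GroundTruth(per_group_expected_rank=ranks,
                               planted_interaction_strength=strengths)


def generate_trajectory(
    complex_system: ComplexSystem, spec: SyntheticSpec, replica_seed: int
) -> Trajectory:
    """One replica trajectory: base coordinates + isotropic Gaussian noise.

    Frame k = base + N(0, noise_sigma²) per coordinate, plus an optional
    linear rigid-body drift of the peptide of total amplitude
    ``spec.peptide_drift`` Å along the pocket-exit direction. The frame
    interval is 1 ns. Different replica seeds share the topology.

    Frames whose noise would compress any atom pair below 0.25 Å (an
    unphysical overlap no sampled ensemble would contain, and outside
    the validity of the energy models) have their noise redrawn; the
    redraw is part of the deterministic seed path.
    """
    rng = np.random.default_rng([int(replica_seed), int(spec.seed)])
    base = complex_system.trajectory.frames[0]
    frames = np.repeat(base[None, :, :], spec.n_frames, axis=0)
    if spec.noise_sigma > 0:
        from scipy.spatial.distance import pdist

        for k in range(spec.n_frames):
            for _ in range(100):
                cand = base + rng.normal(0.0, spec.noise_sigma, base.shape)
                if pdist(cand).min() >= 0.25:
                    break
            frames[k] = cand
    if spec.peptide_drift > 0:
        pep = complex_system.peptide_index
        rec = complex_system.receptor_index
        away = base[pep].mean(axis=0) - base[rec].mean(axis=0)
        away /= np.linalg.norm(away)
        for k in range(spec.n_frames):
            frames[k, pep, :] += (k / max(spec.n_frames - 1, 1)) \
                * spec.peptide_drift * away
    return Trajectory(complex_system.topology, frames, frame_interval_ns=1.0)


def generate_destabilized_variant(
    spec: SyntheticSpec, attenuation: float
) -> SyntheticSpec:
    """Spec variant with planted epitope/staple strengths scaled down.

    Emulates staple-position variants that bind more weakly: the
    receptor probe charges scale linearly and the planted pair LJ well
    depths scale linearly with ``attenuation`` (geometry unchanged), so
    smaller attenuation gives a strictly less negative expected Δf.
    """
    if not 0 < attenuation <= 1:
        raise SynthesisError("attenuation must be in (0, 1]")
    if attenuation == 1.0:
        return spec
    return replace(spec, attenuation=spec.attenuation * attenuation)


def parameter_table_for(system: ComplexSystem) -> ParameterTable:
    """Parameter table consistent with a generated complex.

    Entries are keyed by (residue_name, atom_name); residue formal
    charges are declared for every residue type whose instances all
    carry the same net charge.
    """
    entries: dict[tuple[str, str], tuple[float, float, float, float]] = {}
    per_instance: dict[tuple[str, int, str], float] = {}
    for a in system.topology.atoms:
        entries[(a.residue_name, a.atom_name)] = (
            a.partial_charge, a.lj_sigma, a.lj_epsilon, a.intrinsic_radius
        )
        k = (a.chain_id, a.residue_index, a.residue_name)
        per_instance[k] = per_instance.get(k, 0.0) + a.partial_charge
    formal: dict[str, float] = {}
    by_name: dict[str, set[float]] = {}
    for (_, _, res), q in per_instance.items():
        by_name.setdefault(res, set()).add(round(q, 9))
    for res, sums in by_name.items():
        if len(sums) == 1:
            formal[res] = next(iter(sums))
    return ParameterTable(entries=entries, formal_charges=formal)


def linker_atom_ids(system: ComplexSystem) -> list[int]:
    """Atom ids of the staple (group ``LINKER``) atoms."""
    return [a.atom_id for a in system.topology.atoms
            if a.group_label == LINKER_GROUP]


def generate_two_conformer_trajectory(
    n_frames: int = 20,
    separation: float = 8.0,
    spread: float = 0.5,
    majority_fraction: float = 0.7,
    seed: int = 0,
) -> tuple[Trajectory, np.ndarray]:
    """A planted two-conformer trajectory for clustering tests.

    Conformer A is an ideal 12-residue helix (CA trace); conformer B is
    A with its second half hinged until the fitted RMSD between the two
    equals ``separation`` Å. Frames alternate deterministically so that
    ``majority_fraction`` of them come from A, each with isotropic
    Gaussian noise of ``spread``/sqrt(3) per coordinate (≈ ``spread`` Å
    expected displacement scale). Returns the trajectory and the
    planted frame labels (0 = A, 1 = B).
    """
    from .geometry import rmsd_after_fit

    helix = build_ideal_helix(12)
    a_coords = helix["CA"]
    hinge = len(a_coords) // 2
    axis = np.array([0.0, 0.0, 1.0])

    def bent(angle_deg: float) -> np.ndarray:
        out = a_coords.copy()
        pivot = a_coords[hinge]
        for i in range(hinge, len(out)):
            out[i] = pivot + _rotate_about(out[i] - pivot, axis, angle_deg)
        return out

    lo, hi = 0.0, 179.0
    for _ in range(60):  # bisect the hinge angle to the requested separation
        mid = 0.5 * (lo + hi)
        if rmsd_after_fit(bent(mid), a_coords) < separation:
            lo = mid
        else:
            hi = mid
    b_coords = bent(0.5 * (lo + hi))

    rng = np.random.default_rng(seed)
    cycle = max(round(10 * majority_fraction), 1)
    labels = np.array([0 if (k % 10) < cycle else 1 for k in range(n_frames)])
    per_coord = spread / math.sqrt(3.0)
    frames = np.array([
        (a_coords if lab == 0 else b_coords) + rng.normal(0.0, per_coord, a_coords.shape)
        for lab in labels
    ])
    atoms = [
        AtomRecord(atom_id=i + 1, atom_name="CA", element="C", residue_index=i + 1,
                   residue_name="ALA", chain_id="P", position=a_coords[i])
        for i in range(len(a_coords))
    ]
    topo = Structure(atoms=atoms, title="two-conformer fixture")
    return Trajectory(topo, frames, frame_interval_ns=1.0), labels
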
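"""Secondary-structure assignment and peptide–protein interface contacts.

Secondary structure uses the classic backbone hydrogen-bond energy
criterion: with the amide hydrogen built geometrically (heavy-atom
structures carry no H), the electrostatic H-bond energy between a donor
N–H and an acceptor C=O is

    E = 332 · 0.42 · 0.20 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)  kcal/mol

and a bond exists when E < −0.5 kcal/mol. Four classes are assigned with
precedence H > T > B > C:

    H  α-helix: i→i+4 bonds on ≥2 consecutive residues
    T  turn: i→i+3 bond (3-10-like) or an isolated i→i+4 turn
    B  bend: Cα(i−2)–Cα(i)–Cα(i+2) direction change > 70°
    C  coil: none of the above

Contacts are heavy-atom minimum distances between peptide and receptor
residues below a cutoff (default 4.5 Å, the common hydrophobic-contact
convention); a k-d tree accelerates the search but the result equals
the all-pairs scan exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structures import ComplexSystem, Structure, Trajectory

logger = logging.getLogger("stapletherm")

HBOND_PREFACTOR = 332.0 * 0.42 * 0.20  # kcal·Å/mol
HBOND_CUTOFF = -0.5  # kcal/mol
NH_BOND_LENGTH = 1.01  # Å
BEND_ANGLE_DEG = 70.0
DEFAULT_CONTACT_CUTOFF = 4.5  # Å

SS_CLASSES = ("H", "T", "B", "C")


@dataclass
class SecondaryStructureProfile:
    """Per-residue secondary-structure fractions over a trajectory.

    ``per_residue_fractions`` maps each residue key to its fraction of
    frames in each of the four classes (summing to 1); ``helical_content``
    is the mean helix fraction over residues and frames.
    """

    per_residue_fractions: dict[str, dict[str, float]]
    helical_content: float


@dataclass
class ContactList:
    """Peptide/receptor residue pairs in contact on one frame."""

    pairs: list[tuple[str, str, float]]  # (peptide key, receptor key, min dist Å)
    cutoff: float

    def __len__(self) -> int:
        return len(self.pairs)

    def as_dict(self) -> dict[tuple[str, str], float]:
        return {(p, r): d for p, r, d in self.pairs}


# ---------------------------------------------------------------------------
# Secondary structure
# ---------------------------------------------------------------------------

def _backbone_index(structure: Structure) -> list[dict[str, int] | None]:
    """Per chain-residue map of backbone atom positions; None if incomplete.

    Only residues possessing a CA atom participate in the profile (the
    synthetic staple linker group, for instance, has no backbone).
    """
    residues: dict[tuple[str, int], dict[str, int]] = {}
    order: list[tuple[str, int]] = []
    keys: list[str] = []
    for i, a in enumerate(structure.atoms):
        rk = (a.chain_id, a.residue_index)
        if rk not in residues:
            residues[rk] = {}
            order.append(rk)
            keys.append(a.residue_key)
        if a.atom_name in ("N", "CA", "C", "O"):
            residues[rk][a.atom_name] = i
    out = []
    out_keys = []
    for rk, key in zip(order, keys):
        bb = residues[rk]
        if "CA" not in bb:
            continue  # non-peptidic group (e.g. staple pseudo-atoms)
        out.append(bb if all(n in bb for n in ("N", "CA", "C", "O")) else None)
        out_keys.append(key)
    return out, out_keys


def _amide_hydrogens(bb: list, coords: np.ndarray) -> list[np.ndarray | None]:
    """Geometric amide-H positions: along the bisector of C(prev)→N and CA→N."""
    hydrogens: list[np.ndarray | None] = [None] * len(bb)
    for i in range(1, len(bb)):
        if bb[i] is None or bb[i - 1] is None:
            continue
        n = coords[bb[i]["N"]]
        ca = coords[bb[i]["CA"]]
        c_prev = coords[bb[i - 1]["C"]]
        u1 = n - c_prev
        u2 = n - ca
        u1 /= np.linalg.norm(u1)
        u2 /= np.linalg.norm(u2)
        u = u1 + u2
        norm = np.linalg.norm(u)
        if norm < 1e-8:
            continue
        hydrogens[i] = n + NH_BOND_LENGTH * u / norm
    return hydrogens


def _hbond_energy(n, h, c, o) -> float:
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return 0.0  # overlapping backbone: no physical H-bond
    return HBOND_PREFACTOR * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)


def assign_secondary_structure(
    structure: Structure, frame: np.ndarray
) -> dict[str, str]:
    """Assign one of {H, T, B, C} to every peptide residue of one frame.

    Residues lacking any of the N, CA, C, O backbone atoms are labelled
    C with a warning. See the module docstring for the assignment rules.
    """
    frame = np.asarray(frame, dtype=float)
    bb, keys = _backbone_index(structure)
    n_res = len(bb)
    labels = ["C"] * n_res
    if n_res == 0:
        return {}
    incomplete = [keys[i] for i in range(n_res) if bb[i] is None]
    if incomplete:
        logger.warning("missing backbone atoms, labelling C: %s", incomplete)

    hydrogens = _amide_hydrogens(bb, frame)

    def bonded(acceptor: int, donor: int) -> bool:
        """True if donor residue's N-H hydrogen-bonds the acceptor's C=O."""
        if not (0 <= acceptor < n_res and 0 <= donor < n_res):
            return False
        if bb[acceptor] is None or bb[donor] is None or hydrogens[donor] is None:
            return False
        return _hbond_energy(
            frame[bb[donor]["N"]], hydrogens[donor],
            frame[bb[acceptor]["C"]], frame[bb[acceptor]["O"]],
        ) < HBOND_CUTOFF

    turn4 = [bonded(i, i + 4) for i in range(n_res)]
    turn3 = [bonded(i, i + 3) for i in range(n_res)]

    helix = [False] * n_res
    for i in range(n_res - 1):
        if turn4[i] and turn4[i + 1]:
            for j in range(i + 1, min(i + 5, n_res)):
                helix[j] = True

    turn = [False] * n_res
    for i in range(n_res):
        if turn3[i]:
            for j in range(i + 1, min(i + 3, n_res)):
                turn[j] = True
        if turn4[i] and not (turn4[i - 1] if i > 0 else False) and not (
            turn4[i + 1] if i + 1 < n_res else False
        ):
            for j in range(i + 1, min(i + 4, n_res)):
                turn[j] = True

    bend = [False] * n_res
    for i in range(2, n_res - 2):
        if any(bb[j] is None for j in (i - 2, i, i + 2)):
            continue
        v1 = frame[bb[i]["CA"]] - frame[bb[i - 2]["CA"]]
        v2 = frame[bb[i + 2]["CA"]] - frame[bb[i]["CA"]]
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        angle = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
        bend[i] = angle > BEND_ANGLE_DEG

    for i in range(n_res):
        if bb[i] is None:
            labels[i] = "C"
        elif helix[i]:
            labels[i] = "H"
        elif turn[i]:
            labels[i] = "T"
        elif bend[i]:
            labels[i] = "B"
        else:
            labels[i] = "C"
    return dict(zip(keys, labels))


def secondary_structure_profile(trajectory: Trajectory) -> SecondaryStructureProfile:
    """Four-class fractions per residue over all frames, plus helical content."""
    counts: dict[str, dict[str, int]] = {}
    helix_frames = []
    for frame in trajectory.frames:
        labels = assign_secondary_structure(trajectory.topology, frame)
        if not labels:
            continue
        for key, lab in labels.items():
            counts.setdefault(key, {c: 0 for c in SS_CLASSES})[lab] += 1
        helix_frames.append(
            sum(1 for v in labels.values() if v == "H") / len(labels)
        )
    n_frames = trajectory.n_frames
    fractions = {
        key: {c: cnt[c] / n_frames for c in SS_CLASSES} for key, cnt in counts.items()
    }
    content = float(np.mean(helix_frames)) if helix_frames else 0.0
    return SecondaryStructureProfile(
        per_residue_fractions=fractions, helical_content=content
    )


def helical_content(trajectory: Trajectory) -> float:
    """Mean over frames of (number of H residues / number of residues)."""
    return secondary_structure_profile(trajectory).helical_content


# ---------------------------------------------------------------------------
# Interface contacts
# ---------------------------------------------------------------------------

def _heavy(structure: Structure, index: np.ndarray) -> np.ndarray:
    return np.array(
        [i for i in index if structure.atoms[i].element.upper() != "H"], dtype=int
    )


def find_contacts(
    complex_system: ComplexSystem,
    frame: np.ndarray,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> ContactList:
    """All peptide/receptor residue pairs within a heavy-atom cutoff.

    Reports the minimum heavy-atom distance of each residue pair whose
    minimum is <= cutoff. Uses a k-d tree pair search whose result is
    identical to the brute-force all-pairs scan.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    frame = np.asarray(frame, dtype=float)
    topo = complex_system.topology
    pi = _heavy(topo, complex_system.peptide_index)
    ri = _heavy(topo, complex_system.receptor_index)
    if len(pi) == 0 or len(ri) == 0:
        return ContactList(pairs=[], cutoff=cutoff)
    tree_p = cKDTree(frame[pi])
    tree_r = cKDTree(frame[ri])
    best: dict[tuple[str, str], float] = {}
    for ip, neighbours in enumerate(tree_p.query_ball_tree(tree_r, cutoff)):
        if not neighbours:
            continue
        pep_key = topo.atoms[pi[ip]].residue_key
        for ir in neighbours:
            rec_key = topo.atoms[ri[ir]].residue_key
            d = float(np.linalg.norm(frame[pi[ip]] - frame[ri[ir]]))
            pair = (pep_key, rec_key)
            if d <= cutoff and d < best.get(pair, np.inf):
                best[pair] = d
    pairs = sorted((p, r, d) for (p, r), d in best.items())
    return ContactList(pairs=pairs, cutoff=cutoff)


def contact_frequency(
    complex_system: ComplexSystem,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> dict[tuple[str, str], float]:
    """Fraction of frames each residue pair is in contact (sparse: pairs
    never in contact are absent)."""
    n = complex_system.trajectory.n_frames
    counts: dict[tuple[str, str], int] = {}
    for frame in complex_system.trajectory.frames:
        for p, r, _ in find_contacts(complex_system, frame, cutoff).pairs:
            counts[(p, r)] = counts.get((p, r), 0) + 1
    return {pair: c / n for pair, c in counts.items()}
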
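"""Shared fixtures: small synthetic systems and toy structures."""

from dataclasses import replace

import numpy as np
import pytest

from stapletherm import (
    AtomRecord,
    ComplexSystem,
    Structure,
    SyntheticSpec,
    Trajectory,
    generate_complex,
    generate_trajectory,
)


@pytest.fixture(scope="session")
def default_spec() -> SyntheticSpec:
    return SyntheticSpec()


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """Default study conditions with a short trajectory for unit tests."""
    return replace(SyntheticSpec(), n_frames=5, n_replicas=2)


@pytest.fixture(scope="session")
def synthetic_complex(default_spec):
    """Default synthetic complex (single base frame) plus its ground truth."""
    return generate_complex(default_spec)


@pytest.fixture(scope="session")
def small_ensemble(small_spec):
    """(system, truth, replicas) with 2 replicas x 5 noisy frames."""
    system, truth = generate_complex(small_spec)
    replicas = []
    for r in range(small_spec.n_replicas):
        traj = generate_trajectory(system, small_spec, 100 + r)
        replicas.append(
            ComplexSystem(traj, system.peptide_atom_ids, system.receptor_atom_ids)
        )
    return system, truth, replicas


def make_point_structure(coords, charges=None, sigma=3.4, epsilon=0.1,
                         radius=1.5, chain="P", names=None):
    """Bare point-atom structure for toy energy/geometry tests."""
    coords = np.asarray(coords, float)
    n = len(coords)
    charges = np.zeros(n) if charges is None else np.asarray(charges, float)
    atoms = [
        AtomRecord(
            atom_id=i + 1,
            atom_name=(names[i] if names else f"X{i + 1}"),
            element="C",
            residue_index=i + 1,
            residue_name="TOY",
            chain_id=chain,
            position=coords[i],
            partial_charge=float(charges[i]),
            lj_sigma=sigma,
            lj_epsilon=epsilon,
            intrinsic_radius=radius,
        )
        for i in range(n)
    ]
    return Structure(atoms=atoms, title="toy")


def make_two_body_complex(pep_coords, rec_coords, pep_charges, rec_charges,
                          sigma=3.4, epsilon=0.1):
    """Toy ComplexSystem with explicit peptide/receptor point atoms."""
    pep_coords = np.asarray(pep_coords, float)
    rec_coords = np.asarray(rec_coords, float)
    atoms = []
    for i, (pos, q) in enumerate(zip(pep_coords, pep_charges)):
        atoms.append(AtomRecord(i + 1, f"P{i + 1}", "C", i + 1, "TOY", "P",
                                pos, q, sigma, epsilon, 1.5))
    off = len(atoms)
    for i, (pos, q) in enumerate(zip(rec_coords, rec_charges)):
        atoms.append(AtomRecord(off + i + 1, f"R{i + 1}", "C", i + 1, "TOY", "R",
                                pos, q, sigma, epsilon, 1.5))
    topo = Structure(atoms=atoms)
    traj = Trajectory(topo, topo.coordinates[None])
    return ComplexSystem(traj,
                         frozenset(range(1, off + 1)),
                         frozenset(range(off + 1, len(atoms) + 1)))
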
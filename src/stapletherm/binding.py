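"""Effective binding free energy Δf, grouping, and replica statistics.

Per frame of the bound ensemble the end-point score is

    Δf = ΔE_u + ΔG_solv

(direct peptide–receptor interaction energy plus dehydration penalty),
assembled atom-by-atom from the two components, so every level of the
decomposition — atom → residue/linker group → total → replica mean —
is exactly additive. Replica statistics follow the two-level scheme:
frames are averaged within each replica first, then the ensemble mean
and the standard error (sample SD / √n over replica means) are taken
across replicas. The binding free energy bookkeeping

    ΔG_bind = Δf − T(ΔS_config + ΔS_ext)

takes user-supplied entropy terms; no entropy estimator is provided.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .energetics import EnergyDecomposition, direct_interaction_energy
from .solvation import SolvationModelConfig, dehydration_penalty
from .structures import ComplexSystem, Structure

logger = logging.getLogger("stapletherm")


class BindingError(ValueError):
    """Raised for invalid binding-analysis inputs."""


@dataclass
class GroupDecomposition:
    """Residue/linker-level aggregation of an atomic energy decomposition."""

    per_group: dict[str, float]
    total: float
    component: str

    def top(self, k: int) -> list[str]:
        return sorted(self.per_group, key=lambda g: (self.per_group[g], g))[:k]


@dataclass
class BindingEstimate:
    """Ensemble mean Δf ± standard error over independent replicas."""

    mean_delta_f: float
    standard_error: float
    n_replicas: int
    per_group_mean: dict[str, float]
    per_group_se: dict[str, float]
    temperature: float | None = None
    delta_S_config: float | None = None
    delta_S_ext: float | None = None
    delta_G_bind: float | None = None


@dataclass
class ReplicaProfile:
    """Per-frame Δf decompositions for one replica trajectory.

    Stores, for every evaluated frame, the effective total and its
    direct/solvation split, plus the per-group values of all three
    components. Group values of the direct and solvation parts sum to
    the group's Δf exactly (the per-group ΔE_u/ΔG_solv partition).
    """

    frame_indices: list[int]
    totals: list[float]
    direct_totals: list[float]
    solvation_totals: list[float]
    group_effective: list[dict[str, float]]
    group_direct: list[dict[str, float]]
    group_solvation: list[dict[str, float]]

    @property
    def mean_total(self) -> float:
        return float(np.mean(self.totals))

    def group_means(self, component: str = "effective") -> dict[str, float]:
        rows = {"effective": self.group_effective,
                "direct": self.group_direct,
                "solvation": self.group_solvation}[component]
        keys = rows[0].keys()
        return {g: float(np.mean([r[g] for r in rows])) for g in keys}


def effective_binding_energy(
    complex_system: ComplexSystem,
    frame: np.ndarray,
    config: SolvationModelConfig | None = None,
    frame_index: int = 0,
) -> EnergyDecomposition:
    """Δf for one frame: the atom-wise sum of ΔE_u and ΔG_solv."""
    direct = direct_interaction_energy(complex_system, frame, frame_index)
    solv = dehydration_penalty(complex_system, frame, config, frame_index)
    return direct + solv


def group_decomposition(
    decomp: EnergyDecomposition, topology: Structure
) -> GroupDecomposition:
    """Aggregate per-atom contributions by group label.

    Groups are the residue keys ``chain:resindex:resname`` plus the
    literal ``LINKER`` key for staple atoms. The group values sum to
    the decomposition's total exactly.
    """
    label = {a.atom_id: a.group_label for a in topology.atoms}
    per_group: dict[str, float] = {}
    for atom_id, v in decomp.per_atom.items():
        if atom_id not in label:
            raise BindingError(f"atom {atom_id} has no group label in topology")
        per_group[label[atom_id]] = per_group.get(label[atom_id], 0.0) + v
    return GroupDecomposition(
        per_group=per_group,
        total=float(math.fsum(per_group.values())),
        component=decomp.component,
    )


def trajectory_binding_profile(
    complex_system: ComplexSystem,
    config: SolvationModelConfig | None = None,
    frame_stride: int = 1,
) -> ReplicaProfile:
    """Evaluate Δf (and its ΔE_u/ΔG_solv split) on every stride-th frame."""
    traj = complex_system.trajectory
    if frame_stride < 1:
        raise BindingError("frame_stride must be >= 1")
    if frame_stride > traj.n_frames:
        raise BindingError(
            f"frame_stride {frame_stride} exceeds trajectory length {traj.n_frames}"
        )
    topo = complex_system.topology
    profile = ReplicaProfile([], [], [], [], [], [], [])
    for k in range(0, traj.n_frames, frame_stride):
        frame = traj.frames[k]
        direct = direct_interaction_energy(complex_system, frame, k)
        solv = dehydration_penalty(complex_system, frame, config, k)
        eff = direct + solv
        profile.frame_indices.append(k)
        profile.totals.append(eff.total)
        profile.direct_totals.append(direct.total)
        profile.solvation_totals.append(solv.total)
        profile.group_effective.append(group_decomposition(eff, topo).per_group)
        profile.group_direct.append(group_decomposition(direct, topo).per_group)
        profile.group_solvation.append(group_decomposition(solv, topo).per_group)
    return profile


def ensemble_estimate(
    replica_means: Sequence[float],
    per_group_replica_means: Sequence[Mapping[str, float]] | None = None,
) -> BindingEstimate:
    """Mean ± standard error over independent replicas.

    The standard error uses the sample standard deviation (n−1
    denominator) of the replica means divided by √n; a single replica
    yields SE = 0 with a warning. Per-group means/SEs are computed the
    same way when per-replica group means are given.
    """
    if len(replica_means) == 0:
        raise BindingError("need at least one replica mean")
    n = len(replica_means)
    mean = float(np.mean(replica_means))
    if n == 1:
        logger.warning("single replica: standard error reported as 0")
        se = 0.0
    else:
        se = float(np.std(replica_means, ddof=1) / math.sqrt(n))

    per_group_mean: dict[str, float] = {}
    per_group_se: dict[str, float] = {}
    if per_group_replica_means:
        keys = per_group_replica_means[0].keys()
        for g in keys:
            vals = [m[g] for m in per_group_replica_means]
            per_group_mean[g] = float(np.mean(vals))
            per_group_se[g] = (
                0.0 if n == 1 else float(np.std(vals, ddof=1) / math.sqrt(n))
            )
    return BindingEstimate(
        mean_delta_f=mean, standard_error=se, n_replicas=n,
        per_group_mean=per_group_mean, per_group_se=per_group_se,
    )


def binding_free_energy(
    estimate: BindingEstimate,
    temperature: float,
    delta_S_config: float,
    delta_S_ext: float,
) -> float:
    """ΔG_bind = Δf − T(ΔS_config + ΔS_ext), entropies in kcal/(mol·K).

    The entropy terms are inputs, not estimates; they are typically
    negative, making ΔG_bind less favourable than Δf.
    """
    if temperature <= 0:
        raise BindingError("temperature must be > 0")
    value = estimate.mean_delta_f - temperature * (delta_S_config + delta_S_ext)
    estimate.temperature = temperature
    estimate.delta_S_config = delta_S_config
    estimate.delta_S_ext = delta_S_ext
    estimate.delta_G_bind = value
    return value


def rank_groups(
    estimate: BindingEstimate,
    k: int,
    within: Iterable[str] | None = None,
) -> list[str]:
    """Top-k groups by most-negative (most favourable) mean contribution.

    ``within`` optionally restricts the ranking to a subset of group
    keys (e.g. the peptide-side groups when identifying peptide
    hotspots). Ties are broken by group key.
    """
    if k < 1:
        raise BindingError("k must be >= 1")
    pool = estimate.per_group_mean
    if within is not None:
        allowed = set(within)
        pool = {g: v for g, v in pool.items() if g in allowed}
    return sorted(pool, key=lambda g: (pool[g], g))[:k]
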
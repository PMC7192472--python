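"""Rigid-body superposition, RMSD series and conformational clustering.

RMSD between frames is always computed after least-squares optimal
superposition (Kabsch) unless stated otherwise; clustering operates in
this pairwise-fitted RMSD space, grouping frames into conformational
families within a fixed radius.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .structures import Trajectory


class GeometryError(ValueError):
    """Raised for degenerate geometric inputs."""


@dataclass
class SuperpositionResult:
    """Optimal rigid alignment of a mobile onto a reference point set.

    ``rotation`` (3x3, det +1) and ``translation`` map mobile
    coordinates as ``x @ rotation.T + translation``; ``rmsd`` is the
    residual RMSD over the fitted subset in Å.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


@dataclass
class ClusterResult:
    """Radius-capped clustering of trajectory frames.

    Every member frame lies within ``radius`` Å (fitted RMSD) of its
    cluster centroid. ``representative_frame`` is the medoid of the most
    populated cluster.
    """

    assignments: np.ndarray          # frame -> cluster id
    centroids: list[np.ndarray]      # cluster id -> (n_sel, 3) mean coordinates
    radius: float
    representative_frame: int

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)

    def members(self, cluster_id: int) -> np.ndarray:
        return np.nonzero(self.assignments == cluster_id)[0]


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    subset: Sequence[int] | None = None,
) -> SuperpositionResult:
    """Least-squares optimal rigid superposition (Kabsch algorithm).

    Parameters
    ----------
    mobile, reference : (n, 3) arrays
        Coordinate sets of equal length.
    subset : index sequence, optional
        Atoms over which the fit and the reported RMSD are computed
        (all atoms if omitted). Needs >= 3 non-collinear points.

    Returns
    -------
    SuperpositionResult
        Proper rotation (reflections are excluded), translation and the
        post-fit RMSD over the subset.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise GeometryError("mobile and reference must have identical shapes")
    idx = np.arange(len(mobile)) if subset is None else np.asarray(subset, int)
    if len(idx) < 3:
        raise GeometryError("superposition needs at least 3 points")
    x = mobile[idx]
    y = reference[idx]
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    # collinearity check: second singular value of the centered cloud
    if np.linalg.svd(xc, compute_uv=False)[1] < 1e-10:
        raise GeometryError("degenerate (collinear) subset")
    h = xc.T @ yc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = y.mean(axis=0) - x.mean(axis=0) @ rot.T
    fitted = x @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - y) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


def rmsd_after_fit(
    a: np.ndarray, b: np.ndarray, subset: Sequence[int] | None = None
) -> float:
    """RMSD of ``a`` vs ``b`` over ``subset`` after optimal superposition."""
    return superpose(a, b, subset).rmsd


def ca_rmsd_series(
    trajectory: Trajectory,
    reference_frame: int = 0,
    selection: Sequence[int] | None = None,
) -> np.ndarray:
    """Per-frame fitted RMSD (Å) to a reference frame.

    ``selection`` gives the 0-based atom indices to fit over; by default
    all atoms named CA (falling back to all atoms if none are present,
    e.g. for point-cloud fixtures). The value at the reference frame is
    exactly 0.
    """
    if not 0 <= reference_frame < trajectory.n_frames:
        raise GeometryError(f"reference_frame {reference_frame} out of range")
    if selection is None:
        sel = [i for i, a in enumerate(trajectory.topology.atoms) if a.atom_name == "CA"]
        selection = sel if sel else list(range(trajectory.n_atoms))
    selection = np.asarray(selection, int)
    if selection.size == 0:
        raise GeometryError("empty selection")
    ref = trajectory.frames[reference_frame]
    out = np.empty(trajectory.n_frames)
    for k in range(trajectory.n_frames):
        if k == reference_frame:
            out[k] = 0.0
        else:
            out[k] = rmsd_after_fit(trajectory.frames[k], ref, selection)
    return out


def radius_cluster(
    trajectory: Trajectory,
    radius: float,
    selection: Sequence[int] | None = None,
    seed: int = 0,
) -> ClusterResult:
    """Group frames into conformational families within a fixed RMSD radius.

    Leader-style clustering with centroid refinement: frames are visited
    in file order; a frame joins the nearest existing centroid if its
    fitted RMSD is <= ``radius``, else it opens a new cluster. A single
    refinement pass then reassigns every frame to its nearest centroid
    and recomputes centroids as mean coordinates after superposing the
    members onto the running centroid. Frames whose refined nearest
    centroid lies beyond the radius open new clusters, so the radius
    bound holds for every member on output.

    The frame visiting order is deterministic (file order); ``seed`` is
    accepted for interface uniformity but unused.
    """
    del seed
    if radius <= 0:
        raise GeometryError("radius must be > 0")
    if trajectory.n_frames < 1:
        raise GeometryError("need at least one frame")
    if selection is None:
        sel = [i for i, a in enumerate(trajectory.topology.atoms) if a.atom_name == "CA"]
        selection = sel if sel else list(range(trajectory.n_atoms))
    sel = np.asarray(selection, int)
    coords = trajectory.frames[:, sel, :]

    def assign_pass(frames: np.ndarray, centroids: list[np.ndarray]):
        """Assign each frame to nearest centroid within radius, else found one."""
        assignments = np.empty(len(frames), dtype=int)
        for k, frame in enumerate(frames):
            best, best_rmsd = -1, np.inf
            for c, cent in enumerate(centroids):
                r = rmsd_after_fit(frame, cent)
                if r < best_rmsd:
                    best, best_rmsd = c, r
            if best >= 0 and best_rmsd <= radius:
                assignments[k] = best
            else:
                centroids.append(frame.copy())
                assignments[k] = len(centroids) - 1
        return assignments

    def mean_centroids(frames, assignments, centroids):
        """Centroid = mean coordinates of members superposed onto the centroid."""
        out = []
        for c, cent in enumerate(centroids):
            members = np.nonzero(assignments == c)[0]
            if len(members) == 0:
                out.append(None)
                continue
            acc = np.zeros_like(cent)
            for k in members:
                acc += superpose(frames[k], cent).apply(frames[k])
            out.append(acc / len(members))
        return out

    # pass 1: leader clustering (centroid = founding frame), then means
    centroids: list[np.ndarray] = []
    assignments = assign_pass(coords, centroids)
    centroids = [c for c in mean_centroids(coords, assignments, centroids) if c is not None]
    # pass 2: one refinement round against the mean centroids
    assignments = assign_pass(coords, centroids)
    refined = mean_centroids(coords, assignments, centroids)
    centroids = [c if c is not None else centroids[i] for i, c in enumerate(refined)]

    # enforce the radius bound against the final (mean) centroids: any member
    # pushed beyond the radius by centroid drift is split into a singleton
    for k, frame in enumerate(coords):
        if rmsd_after_fit(frame, centroids[assignments[k]]) > radius:
            centroids.append(frame.copy())
            assignments[k] = len(centroids) - 1

    # drop clusters emptied by the refinement, keep ids compact
    used = sorted(set(assignments.tolist()))
    remap = {old: new for new, old in enumerate(used)}
    assignments = np.array([remap[a] for a in assignments], dtype=int)
    centroids = [centroids[old] for old in used]

    rep = _medoid_of_largest(coords, assignments)
    return ClusterResult(
        assignments=assignments, centroids=centroids, radius=radius,
        representative_frame=rep,
    )


def _medoid_of_largest(coords: np.ndarray, assignments: np.ndarray) -> int:
    counts = np.bincount(assignments)
    # most populated cluster; ties broken by lowest cluster id
    target = int(np.argmax(counts))
    members = np.nonzero(assignments == target)[0]
    if len(members) == 1:
        return int(members[0])
    best_frame, best_mean = int(members[0]), np.inf
    for i in members:
        mean_r = np.mean([
            rmsd_after_fit(coords[i], coords[j]) for j in members if j != i
        ])
        if mean_r < best_mean - 1e-12:  # ties -> lowest frame index wins
            best_frame, best_mean = int(i), mean_r
    return best_frame


def representative_frame(cluster_result: ClusterResult, trajectory: Trajectory) -> int:
    """Medoid frame of the most populated cluster (ties -> lowest index)."""
    del trajectory
    return cluster_result.representative_frame
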
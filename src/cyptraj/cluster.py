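"""Kabsch superposition, pairwise RMSD matrices and gromos (Daura) clustering.

The gromos procedure iteratively removes the frame with the most RMSD
neighbours within a cutoff, together with those neighbours, as one cluster;
the removed central frame is the cluster centre. It is the clustering used
to extract representative binding geometries from CYP-ligand trajectories
(default cutoff 0.3 nm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import AtomSelector, SelectionError, Structure, Trajectory, select_atoms

__all__ = [
    "RmsdMatrix",
    "ClusterSet",
    "kabsch_superpose",
    "pairwise_rmsd",
    "gromos_cluster",
    "representative_pose",
]


@dataclass
class RmsdMatrix:
    """Symmetric all-vs-all least-squares RMSD matrix (nm) over frames."""

    frame_indices: np.ndarray  # (n,)
    values: np.ndarray  # (n, n), nm

    def __post_init__(self) -> None:
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.frame_indices)
        if self.values.shape != (n, n):
            raise ValueError("RMSD matrix shape does not match frame count")
        if np.any(self.values < -1e-12):
            raise ValueError("RMSD values must be non-negative")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("RMSD matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-9):
            raise ValueError("RMSD matrix diagonal must be zero")

    @property
    def n_frames(self) -> int:
        return len(self.frame_indices)


@dataclass
class ClusterSet:
    """gromos clustering output: a partition of frames with one centre each.

    Clusters are ordered by extraction (first extracted = most neighbours at
    the time, usually the most populated).
    """

    clusters: list[list[int]]
    centers: list[int]
    cutoff: float
    _all_frames: set = field(init=False, repr=False)

    def __post_init__(self) -> None:
        flat = [f for c in self.clusters for f in c]
        if len(flat) != len(set(flat)):
            raise ValueError("clusters must not share frames")
        if len(self.centers) != len(self.clusters):
            raise ValueError("one centre per cluster required")
        for center, members in zip(self.centers, self.clusters):
            if center not in members:
                raise ValueError(f"centre {center} not a member of its cluster")
        self._all_frames = set(flat)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]

    def membership(self) -> dict[int, int]:
        """frame index -> cluster id."""
        return {f: k for k, members in enumerate(self.clusters) for f in members}


def kabsch_superpose(
    X: np.ndarray, Y: np.ndarray, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal least-squares rigid superposition of point set Y onto X.

    Returns ``(R, t, rmsd)`` such that ``Y @ R.T + t`` best matches ``X``.
    R is a proper rotation (det +1; reflections are corrected). Coordinates
    and the returned RMSD are in nm.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError(f"point counts differ: {X.shape} vs {Y.shape}")
    if X.ndim != 2 or X.shape[1] != 3 or X.shape[0] < 3:
        raise ValueError("need at least 3 points of dimension 3")
    n = X.shape[0]
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()
    cx = w @ X
    cy = w @ Y
    Xc = X - cx
    Yc = Y - cy
    # degenerate geometry: all points (of either set) on one line
    for centered, label in ((Xc, "X"), (Yc, "Y")):
        sv = np.linalg.svd(centered * w[:, None] ** 0.5, compute_uv=False)
        if sv[1] <= 1e-12 * max(sv[0], 1e-300):
            raise ValueError(f"degenerate (collinear) point set {label}")
    H = (Yc * w[:, None]).T @ Xc  # 3x3 covariance, maps Y-frame to X-frame
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cx - R @ cy
    diff = (Y @ R.T + t) - X
    rmsd = float(np.sqrt(np.sum(w * np.einsum("ij,ij->i", diff, diff))))
    return R, t, rmsd


def _selection_indices(traj: Trajectory, selection) -> np.ndarray:
    if isinstance(selection, (AtomSelector, str)):
        idx = select_atoms(traj, selection)
    else:
        idx = np.asarray(selection, dtype=int)
    if len(idx) == 0:
        raise SelectionError("atom selection is empty")
    return idx


def pairwise_rmsd(
    traj: Trajectory,
    selection: AtomSelector | str | np.ndarray,
    fit_selection: AtomSelector | str | np.ndarray | None = None,
    frame_indices: np.ndarray | None = None,
) -> RmsdMatrix:
    """All-vs-all superposed RMSD (nm) on the selected atoms.

    By default each frame pair is superposed on ``selection`` itself. With
    ``fit_selection`` (e.g. the protein backbone) the superposition uses
    those atoms and the RMSD is then measured on ``selection`` (e.g. the
    ligand) without refitting — the usual fit/output split of trajectory
    clustering tools. ``frame_indices`` restricts the matrix to a subset of
    frames (labels in the result keep the original frame numbers).
    """
    idx = _selection_indices(traj, selection)
    frames = (
        np.arange(traj.n_frames)
        if frame_indices is None
        else np.asarray(frame_indices, dtype=int)
    )
    if len(frames) < 2:
        raise ValueError("pairwise RMSD needs at least 2 frames")
    pts = traj.coords[np.ix_(frames, idx)]
    n = len(frames)
    m = np.zeros((n, n))
    if fit_selection is None:
        for i in range(n):
            for j in range(i + 1, n):
                _, _, r = kabsch_superpose(pts[i], pts[j])
                m[i, j] = m[j, i] = r
    else:
        fit_idx = _selection_indices(traj, fit_selection)
        fit_pts = traj.coords[np.ix_(frames, fit_idx)]
        for i in range(n):
            for j in range(i + 1, n):
                R, t, _ = kabsch_superpose(fit_pts[i], fit_pts[j])
                moved = pts[j] @ R.T + t
                diff = moved - pts[i]
                r = float(np.sqrt(np.mean(np.einsum("ij,ij->i", diff, diff))))
                m[i, j] = m[j, i] = r
    return RmsdMatrix(frame_indices=frames, values=m)


def gromos_cluster(m: RmsdMatrix, cutoff: float = 0.3) -> ClusterSet:
    """Daura clustering of an RMSD matrix.

    Repeatedly take the remaining frame with the most remaining neighbours
    within ``cutoff`` (ties broken by lowest frame index; a frame counts as
    its own neighbour), make it a cluster centre together with those
    neighbours, remove them, and iterate. Frames with no neighbours end up
    as singleton clusters.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = m.n_frames
    adjacency = m.values <= cutoff
    remaining = np.ones(n, dtype=bool)
    clusters: list[list[int]] = []
    centers: list[int] = []
    while remaining.any():
        counts = (adjacency & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.nonzero(adjacency[center] & remaining)[0]
        clusters.append([int(m.frame_indices[i]) for i in members])
        centers.append(int(m.frame_indices[center]))
        remaining[members] = False
    return ClusterSet(clusters=clusters, centers=centers, cutoff=cutoff)


def representative_pose(traj: Trajectory, clusters: ClusterSet) -> Structure:
    """Centre frame of the most populated cluster, as a Structure.

    Population ties are broken by the lowest cluster index, i.e. the cluster
    extracted first.
    """
    if clusters.n_clusters < 1:
        raise ValueError("need at least one cluster")
    sizes = clusters.sizes
    best = int(np.argmax(sizes))
    return traj.frame(clusters.centers[best])
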
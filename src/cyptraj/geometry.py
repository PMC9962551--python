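"""Reactive-atom to heme-Fe distance series and reactive-atom spread.

The central observable: the per-frame Euclidean distance (nm) between the
ligand atom undergoing the CYP reaction (the 1'-carbon of safrole or
estragole) and the catalytic iron of the heme cofactor. Its mean over a
trajectory is what the substrate-likeliness threshold is applied to.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cluster import kabsch_superpose
from .io import AtomSelector, SelectionError, Trajectory, resolve_atom, select_atoms

__all__ = [
    "DistanceSeries",
    "DistanceSummary",
    "SpreadMetric",
    "distance_series",
    "summarize",
    "reactive_atom_spread",
]


@dataclass
class DistanceSeries:
    """Per-frame reactive-atom to Fe distances (nm) for one complex.

    ``n_clipped`` is set by the synthetic generator when values had to be
    clipped at its physical lower bound; it is ``None`` for measured series.
    """

    complex_id: str
    values: np.ndarray  # (n_frames,), nm
    n_clipped: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) < 1:
            raise ValueError("distance series must be a non-empty 1-d array")
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError("distances must be finite and positive")

    @property
    def n_frames(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class DistanceSummary:
    """Mean/SD/min/max of a distance series (nm); SD uses the n-1 denominator."""

    mean: float
    sd: float
    n_frames: int
    min: float
    max: float

    def __post_init__(self) -> None:
        eps = 1e-12 * max(1.0, abs(self.mean))  # mean accumulates round-off
        if not (self.min - eps <= self.mean <= self.max + eps):
            raise ValueError("min <= mean <= max violated")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class SpreadMetric:
    """Quantified positional spread of the reactive atom after superposition."""

    rmsf: float  # nm
    radius: float  # nm, max deviation of the position cloud from its mean

    def __post_init__(self) -> None:
        if self.rmsf < 0 or self.radius < 0:
            raise ValueError("spread metrics must be non-negative")


def distance_series(
    traj: Trajectory,
    reactive: AtomSelector | str,
    fe: AtomSelector | str,
    pbc_mode: str = "none",
    complex_id: str = "",
) -> DistanceSeries:
    """Per-frame Euclidean distance between the reactive atom and the Fe.

    ``pbc_mode="minimum_image"`` wraps each coordinate difference into
    [-L/2, L/2] using the per-frame orthorhombic box; the default ``"none"``
    assumes ligand and heme live in the same periodic image (true for
    docking-derived complexes).
    """
    if pbc_mode not in ("none", "minimum_image"):
        raise ValueError(f"unknown pbc_mode {pbc_mode!r}")
    i = resolve_atom(traj, reactive)
    j = resolve_atom(traj, fe)
    diff = traj.coords[:, i, :] - traj.coords[:, j, :]
    if pbc_mode == "minimum_image":
        if traj.box is None:
            raise ValueError("minimum_image requested but trajectory has no box")
        box = traj.box
        diff = diff - box * np.round(diff / box)
    values = np.linalg.norm(diff, axis=1)
    return DistanceSeries(complex_id=complex_id, values=values)


def summarize(series: DistanceSeries) -> DistanceSummary:
    """Arithmetic mean, sample SD (n-1), min and max of a distance series."""
    if series.n_frames < 2:
        raise ValueError("summary requires at least 2 frames")
    v = series.values
    return DistanceSummary(
        mean=float(np.mean(v)),
        sd=float(np.std(v, ddof=1)),
        n_frames=series.n_frames,
        min=float(np.min(v)),
        max=float(np.max(v)),
    )


def reactive_atom_spread(
    traj: Trajectory,
    reactive: AtomSelector | str,
    fit_selection: AtomSelector | str | np.ndarray,
) -> SpreadMetric:
    """Positional spread of the reactive atom in the protein frame.

    Every frame is least-squares superposed (Kabsch) onto frame 0 using
    ``fit_selection`` (>= 3 non-collinear atoms, typically the protein);
    RMSF is the root-mean-square deviation of the reactive atom's
    superposed position from its mean position, and ``radius`` the maximum
    such deviation. Purely descriptive: the substrate call never uses it.
    """
    r = resolve_atom(traj, reactive)
    if isinstance(fit_selection, (AtomSelector, str)):
        fit_idx = select_atoms(traj, fit_selection)
    else:
        fit_idx = np.asarray(fit_selection, dtype=int)
    if len(fit_idx) < 3:
        raise SelectionError("fit selection must contain at least 3 atoms")
    ref = traj.coords[0, fit_idx, :]
    positions = np.empty((traj.n_frames, 3))
    for t in range(traj.n_frames):
        R, trans, _ = kabsch_superpose(ref, traj.coords[t, fit_idx, :])
        positions[t] = R @ traj.coords[t, r, :] + trans
    center = positions.mean(axis=0)
    dev = np.linalg.norm(positions - center, axis=1)
    return SpreadMetric(rmsf=float(np.sqrt(np.mean(dev**2))), radius=float(np.max(dev)))
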
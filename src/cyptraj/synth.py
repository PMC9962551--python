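"""Seed-deterministic synthetic inputs with known ground truth.

The real study conditions — 5000-frame distance series fluctuating around
regime means of ~0.39-0.52 nm (substrate-like) or ~0.63-0.74 nm
(non-substrate-like) — come from solvated 25 ns MD runs that are far beyond
desk scale. This module emulates their *statistical* features instead:

* distance series as a discretised Ornstein-Uhlenbeck (OU) process, the
  simplest stationary mean-reverting Gaussian process with controllable
  mean, SD and correlation time;
* toy 3D complexes whose reactive-atom/Fe distance reproduces a given
  series exactly;
* conformer-mixture trajectories with known cluster labels;
* mutated sequences at a chosen percent identity;
* minimal donor-H-acceptor geometries at exact distance/angle.

Everything is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import DistanceSeries
from .homology import AMINO_ALPHABET, ProteinSequence
from .io import Structure, Trajectory

MIN_DISTANCE_NM = 0.05  # physical lower clip for synthetic distances

__all__ = [
    "OuParameters",
    "ou_distance_series",
    "synth_complex_trajectory",
    "synth_conformer_trajectory",
    "mutate_sequence",
    "synth_hbond_fixture",
]


@dataclass(frozen=True)
class OuParameters:
    """Stationary parameters of the synthetic distance process.

    mu/sigma are the stationary mean/SD in nm; tau the mean-reversion
    correlation time in frames (the lag at which autocorrelation ~ 1/e).
    """

    mu: float
    sigma: float
    tau: float
    n_frames: int
    seed: int

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


def ou_distance_series(p: OuParameters, complex_id: str = "synthetic") -> DistanceSeries:
    """Discretised OU distance series.

    X_0 = mu;  X_{t+1} = X_t + (mu - X_t)/tau + sigma*sqrt(2/tau)*xi_t,
    xi_t ~ N(0,1). For tau >> 1 the stationary SD is ~ sigma (exactly
    sigma/sqrt(1 - 1/(2 tau))). Values are clipped below at 0.05 nm; the
    number of clipped frames is recorded on the returned series so callers
    can require clip-free regimes.
    """
    rng = np.random.default_rng(p.seed)
    noise = p.sigma * np.sqrt(2.0 / p.tau) * rng.standard_normal(p.n_frames - 1)
    x = np.empty(p.n_frames)
    x[0] = p.mu
    a = 1.0 - 1.0 / p.tau
    for t in range(p.n_frames - 1):
        x[t + 1] = a * x[t] + p.mu / p.tau + noise[t]
    n_clipped = int(np.sum(x < MIN_DISTANCE_NM))
    x = np.maximum(x, MIN_DISTANCE_NM)
    return DistanceSeries(complex_id=complex_id, values=x, n_clipped=n_clipped)


def _rotation_to(u: np.ndarray) -> np.ndarray:
    """Proper rotation taking the z axis onto unit vector u (Rodrigues)."""
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(z, u))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    v = np.cross(z, u)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


# rigid 5-atom ligand template: reactive atom at the origin, the rest hanging
# below it along -z so the reactive atom is the moiety closest to the heme
_LIGAND_TEMPLATE = np.array(
    [
        [0.00, 0.00, 0.00],  # C1, the reactive atom
        [0.10, 0.00, 0.10],  # C2
        [-0.10, 0.00, 0.12],  # C3
        [0.00, 0.12, 0.18],  # O1
        [0.00, -0.10, 0.20],  # C4
    ]
)
_LIGAND_NAMES = ["C1", "C2", "C3", "O1", "C4"]
_LIGAND_ELEMENTS = ["C", "C", "C", "O", "C"]

REACTIVE_SELECTOR = "resname=SAF,name=C1"
FE_SELECTOR = "resname=HEM,name=FE"


def _toy_scaffold(seed: int, n_shell: int = 20) -> Structure:
    """Fixed heme (Fe at the origin + 4 planar N) plus a rigid protein shell."""
    rng = np.random.default_rng(seed)
    serial, name, res_name, res_id, chain, element, coords = [], [], [], [], [], [], []

    def add(nm, rn, ri, ch, el, xyz):
        serial.append(len(serial) + 1)
        name.append(nm)
        res_name.append(rn)
        res_id.append(ri)
        chain.append(ch)
        element.append(el)
        coords.append(xyz)

    add("FE", "HEM", 1, "X", "FE", [0.0, 0.0, 0.0])
    for k, (dx, dy) in enumerate(((0.2, 0), (-0.2, 0), (0, 0.2), (0, -0.2)), start=1):
        add(f"N{k}", "HEM", 1, "X", "N", [dx, dy, 0.0])
    # protein shell: CA pseudo-atoms on a hemisphere below the heme plane
    for k in range(n_shell):
        v = rng.standard_normal(3)
        v /= np.linalg.norm(v)
        v[2] = -abs(v[2]) - 0.2
        v /= np.linalg.norm(v)
        add("CA", "ALA", k + 1, "A", "C", (1.5 * v).tolist())
    return Structure(
        serial=serial,
        name=name,
        res_name=res_name,
        res_id=res_id,
        chain=chain,
        element=element,
        coords=np.array(coords),
    )


def synth_complex_trajectory(
    series: DistanceSeries,
    seed: int,
    direction_diffusion: float = 0.05,
) -> Trajectory:
    """Toy CYP-ligand trajectory realising a given distance series exactly.

    The heme (Fe at the origin) and a 20-atom protein shell are rigid; a
    rigid 5-atom ligand is placed each frame so its reactive atom (SAF/C1)
    sits at exactly ``series[t]`` nm from the Fe along a direction that
    performs a slow random walk on the unit sphere
    (``direction_diffusion`` rad/frame; 0 freezes the direction).
    """
    rng = np.random.default_rng(seed)
    scaffold = _toy_scaffold(seed)
    n_scaffold = scaffold.n_atoms
    n_frames = series.n_frames

    lig_serial = np.arange(n_scaffold + 1, n_scaffold + 1 + len(_LIGAND_NAMES))
    atoms = Structure(
        serial=np.concatenate([scaffold.serial, lig_serial]),
        name=np.concatenate([scaffold.name, _LIGAND_NAMES]),
        res_name=np.concatenate([scaffold.res_name, ["SAF"] * 5]),
        res_id=np.concatenate([scaffold.res_id, [1] * 5]),
        chain=np.concatenate([scaffold.chain, ["L"] * 5]),
        element=np.concatenate([scaffold.element, _LIGAND_ELEMENTS]),
        coords=np.vstack([scaffold.coords, np.zeros((5, 3))]),
    )

    coords = np.empty((n_frames, atoms.n_atoms, 3))
    coords[:, :n_scaffold, :] = scaffold.coords[None, :, :]
    u = np.array([0.0, 0.0, 1.0])
    for t in range(n_frames):
        if t > 0 and direction_diffusion > 0:
            step = direction_diffusion * rng.standard_normal(3)
            u = u + step - u * np.dot(u, step)
            u /= np.linalg.norm(u)
        rot = _rotation_to(u)
        anchor = series.values[t] * u
        coords[t, n_scaffold:, :] = anchor + _LIGAND_TEMPLATE @ rot.T
    atoms = atoms.with_coords(coords[0])
    return Trajectory(atoms=atoms, coords=coords)


def synth_conformer_trajectory(
    centers: list[Structure],
    weights: list[float],
    noise_sd: float,
    n_frames: int,
    seed: int,
) -> tuple[Trajectory, np.ndarray]:
    """Frames drawn from K conformer centres with Gaussian coordinate noise.

    Returns the trajectory together with the ground-truth centre label of
    every frame. Weights must sum to 1.
    """
    if not centers:
        raise ValueError("need at least one centre structure")
    w = np.asarray(weights, dtype=float)
    if len(w) != len(centers) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be non-negative and sum to 1")
    n_atoms = centers[0].n_atoms
    for c in centers[1:]:
        if c.n_atoms != n_atoms:
            raise ValueError("all centres must have the same atom count")
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(centers), size=n_frames, p=w)
    coords = np.empty((n_frames, n_atoms, 3))
    for t, lab in enumerate(labels):
        coords[t] = centers[lab].coords + noise_sd * rng.standard_normal((n_atoms, 3))
    return Trajectory(atoms=centers[0].with_coords(coords[0]), coords=coords), labels


def mutate_sequence(reference: ProteinSequence, target_identity: float, seed: int) -> ProteinSequence:
    """Substitute residues (no indels) to a chosen percent identity.

    round(n * (1 - target/100)) uniformly chosen positions are replaced by
    a uniformly chosen *different* residue, so the realised identity of the
    unaligned strings equals the target up to the rounding of the position
    count.
    """
    if not 0 < target_identity <= 100:
        raise ValueError("target identity must be in (0, 100]")
    n = len(reference)
    n_sub = round(n * (1.0 - target_identity / 100.0))
    if n_sub == 0:
        return ProteinSequence(
            id=f"{reference.id}_mut{target_identity:g}", residues=reference.residues
        )
    rng = np.random.default_rng(seed)
    positions = rng.choice(n, size=n_sub, replace=False)
    alphabet = sorted(AMINO_ALPHABET - {"X"})
    residues = list(reference.residues)
    for pos in positions:
        choices = [a for a in alphabet if a != residues[pos]]
        residues[pos] = choices[rng.integers(len(choices))]
    return ProteinSequence(
        id=f"{reference.id}_mut{target_identity:g}", residues="".join(residues)
    )


def synth_hbond_fixture(distance: float, angle: float) -> Structure:
    """Minimal donor-H-acceptor geometry at an exact distance and angle.

    A serine-like donor oxygen at the origin with its hydrogen 0.10 nm
    along +x, and a ligand acceptor oxygen placed so the donor-acceptor
    distance is ``distance`` nm and the D-H...A angle (at the hydrogen) is
    ``angle`` degrees.
    """
    if distance <= 0.1:
        raise ValueError("donor-acceptor distance must exceed the O-H bond length")
    phi = np.radians(180.0 - angle)
    cphi, sphi = np.cos(phi), np.sin(phi)
    # acceptor = H + L*(cos phi, sin phi, 0); solve |acceptor - donor| = distance
    ell = -0.1 * cphi + np.sqrt(0.01 * cphi**2 + distance**2 - 0.01)
    acceptor = np.array([0.1 + ell * cphi, ell * sphi, 0.0])
    return Structure(
        serial=[1, 2, 3],
        name=["OG", "HG", "O1"],
        res_name=["SER", "SER", "LIG"],
        res_id=[10, 10, 1],
        chain=["A", "A", "L"],
        element=["O", "H", "O"],
        coords=np.array([[0.0, 0.0, 0.0], [0.1, 0.0, 0.0], acceptor]),
    )
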
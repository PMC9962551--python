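import numpy as np
import pytest

from cyptraj.io import Structure, Trajectory


def make_structure(coords, elements=None, names=None, res_names=None, res_ids=None,
                   chains=None, serials=None, box=None) -> Structure:
    """Compact Structure builder for geometric fixtures."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = len(coords)
    return Structure(
        serial=serials if serials is not None else np.arange(1, n + 1),
        name=names if names is not None else [f"A{i}" for i in range(n)],
        res_name=res_names if res_names is not None else ["RES"] * n,
        res_id=res_ids if res_ids is not None else [1] * n,
        chain=chains if chains is not None else ["A"] * n,
        element=elements if elements is not None else ["C"] * n,
        coords=coords,
        box=box,
    )


def make_trajectory(frames, box=None, **kwargs) -> Trajectory:
    frames = np.asarray(frames, dtype=float)
    atoms = make_structure(frames[0], **kwargs)
    return Trajectory(atoms=atoms, coords=frames, box=box)


@pytest.fixture
def rng():
    return np.random.default_rng(20230094)


@pytest.fixture
def toy_pdb(tmp_path):
    """Three-atom PDB with a heme-iron HETATM; coordinates in Angstrom."""
    text = (
        "ATOM      1  CA  ALA A   1      10.000   0.000   0.000  1.00  0.00           C\n"
        "ATOM      2  CB  ALA A   1      11.000   1.000   0.000  1.00  0.00           C\n"
        "HETATM    3 FE   HEM A   2       0.000   0.000   0.000  1.00  0.00          FE\n"
        "END\n"
    )
    path = tmp_path / "toy.pdb"
    path.write_text(text)
    return path


def random_rotation(rng) -> np.ndarray:
    """Uniform-ish proper rotation via QR decomposition."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
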
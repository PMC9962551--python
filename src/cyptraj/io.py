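"""Structure and trajectory I/O with a consistent nanometre coordinate convention.

PDB files store Ångström; everything inside this package is nanometres.
Conversion happens here, at the I/O boundary, and nowhere else. Atom order
(not atom serial) is the frame-matching key across models of a trajectory.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from biotite.structure import AtomArray
from biotite.structure.io.pdb import PDBFile

ANGSTROM_PER_NM = 10.0

__all__ = [
    "AtomRecord",
    "Structure",
    "Trajectory",
    "AtomSelector",
    "ParseError",
    "SelectionError",
    "read_pdb",
    "write_pdb",
    "read_multimodel_pdb",
    "read_frame_table",
    "write_frame_table",
    "resolve_atom",
    "select_atoms",
]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


class SelectionError(ValueError):
    """Raised when an atom selection resolves to zero or several atoms."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity metadata plus coordinates in nm."""

    serial: int
    name: str
    res_name: str
    res_id: int
    chain: str
    element: str
    coord: np.ndarray  # shape (3,), nm

    def __post_init__(self) -> None:
        coord = np.asarray(self.coord, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise ValueError(f"atom {self.serial}: coordinates must be 3 finite numbers")
        object.__setattr__(self, "coord", coord)


@dataclass
class Structure:
    """An ordered set of atoms with coordinates in nm and an optional box.

    Metadata is stored as parallel numpy arrays so geometric operations can
    work on whole selections without per-atom Python objects.
    """

    serial: np.ndarray  # (n,) int
    name: np.ndarray  # (n,) str
    res_name: np.ndarray  # (n,) str
    res_id: np.ndarray  # (n,) int
    chain: np.ndarray  # (n,) str
    element: np.ndarray  # (n,) str
    coords: np.ndarray  # (n, 3) float, nm
    box: np.ndarray | None = None  # (3,) orthorhombic box lengths, nm

    def __post_init__(self) -> None:
        self.serial = np.asarray(self.serial, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.serial)
        for attr in ("name", "res_name", "chain", "element"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype="U6"))
        self.res_id = np.asarray(self.res_id, dtype=int)
        if self.coords.shape != (n, 3):
            raise ValueError("coords must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        uniq, counts = np.unique(self.serial, return_counts=True)
        if np.any(counts > 1):
            dupes = uniq[counts > 1].tolist()
            raise ParseError(f"duplicate atom serials: {dupes}")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,):
                raise ValueError("box must be 3 orthorhombic edge lengths (nm)")

    @property
    def n_atoms(self) -> int:
        return len(self.serial)

    def atom(self, i: int) -> AtomRecord:
        return AtomRecord(
            serial=int(self.serial[i]),
            name=str(self.name[i]),
            res_name=str(self.res_name[i]),
            res_id=int(self.res_id[i]),
            chain=str(self.chain[i]),
            element=str(self.element[i]),
            coord=self.coords[i].copy(),
        )

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return replace(self, coords=np.asarray(coords, dtype=float))

    @classmethod
    def from_records(cls, records: list[AtomRecord], box: np.ndarray | None = None) -> "Structure":
        return cls(
            serial=[r.serial for r in records],
            name=[r.name for r in records],
            res_name=[r.res_name for r in records],
            res_id=[r.res_id for r in records],
            chain=[r.chain for r in records],
            element=[r.element for r in records],
            coords=np.array([r.coord for r in records], dtype=float).reshape(-1, 3),
            box=box,
        )


@dataclass
class Trajectory:
    """Frames x atoms x 3 coordinates (nm) sharing one atom-metadata table."""

    atoms: Structure
    coords: np.ndarray  # (n_frames, n_atoms, 3), nm
    box: np.ndarray | None = None  # (n_frames, 3), nm

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame of (n_atoms, 3) coordinates")
        if self.coords.shape[1] != self.atoms.n_atoms or self.coords.shape[2] != 3:
            raise ValueError(
                f"frame shape {self.coords.shape[1:]} does not match "
                f"{self.atoms.n_atoms} metadata atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("trajectory coordinates must be finite")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (self.n_frames, 3):
                raise ValueError("box must have shape (n_frames, 3)")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, t: int) -> Structure:
        box = None if self.box is None else self.box[t]
        return replace(self.atoms, coords=self.coords[t].copy(), box=box)


@dataclass(frozen=True)
class AtomSelector:
    """Selects atoms either by explicit index or by metadata fields.

    Unset fields are wildcards. String form (used in configs, manifests and
    the CLI): comma-separated ``key=value`` pairs, e.g.
    ``"resname=HEM,name=FE"`` or ``"index=12"``.
    """

    index: int | None = None
    chain: str | None = None
    res_name: str | None = None
    res_id: int | None = None
    name: str | None = None

    _KEYS = {"index", "chain", "resname", "resid", "name"}

    @classmethod
    def from_string(cls, text: str) -> "AtomSelector":
        kwargs: dict = {}
        for part in text.split(","):
            part = part.strip()
            if not part:
                continue
            if "=" not in part:
                raise SelectionError(f"bad selector token {part!r}: expected key=value")
            key, value = (s.strip() for s in part.split("=", 1))
            if key not in cls._KEYS:
                raise SelectionError(f"unknown selector key {key!r}; allowed: {sorted(cls._KEYS)}")
            if key == "index":
                kwargs["index"] = int(value)
            elif key == "resid":
                kwargs["res_id"] = int(value)
            elif key == "resname":
                kwargs["res_name"] = value
            else:
                kwargs[key] = value
        if not kwargs:
            raise SelectionError(f"empty selector string {text!r}")
        return cls(**kwargs)

    def __str__(self) -> str:
        parts = []
        if self.index is not None:
            parts.append(f"index={self.index}")
        if self.chain is not None:
            parts.append(f"chain={self.chain}")
        if self.res_name is not None:
            parts.append(f"resname={self.res_name}")
        if self.res_id is not None:
            parts.append(f"resid={self.res_id}")
        if self.name is not None:
            parts.append(f"name={self.name}")
        return ",".join(parts)

    def matches(self, s: Structure) -> np.ndarray:
        """Indices of all atoms matched in ``s`` (ascending)."""
        if self.index is not None:
            if not 0 <= self.index < s.n_atoms:
                raise SelectionError(
                    f"index {self.index} out of range for {s.n_atoms} atoms"
                )
            return np.array([self.index], dtype=int)
        mask = np.ones(s.n_atoms, dtype=bool)
        if self.chain is not None:
            mask &= s.chain == self.chain
        if self.res_name is not None:
            mask &= s.res_name == self.res_name
        if self.res_id is not None:
            mask &= s.res_id == self.res_id
        if self.name is not None:
            mask &= s.name == self.name
        return np.nonzero(mask)[0]


def _as_structure(obj: Structure | Trajectory) -> Structure:
    return obj.atoms if isinstance(obj, Trajectory) else obj


def select_atoms(obj: Structure | Trajectory, sel: AtomSelector | str) -> np.ndarray:
    """All atom indices matching ``sel``; may be empty."""
    if isinstance(sel, str):
        sel = AtomSelector.from_string(sel)
    return sel.matches(_as_structure(obj))


def resolve_atom(obj: Structure | Trajectory, sel: AtomSelector | str) -> int:
    """Resolve ``sel`` to exactly one atom index, or raise ``SelectionError``."""
    if isinstance(sel, str):
        sel = AtomSelector.from_string(sel)
    s = _as_structure(obj)
    hits = sel.matches(s)
    if len(hits) == 0:
        raise SelectionError(f"selector {sel} matched no atoms")
    if len(hits) > 1:
        listing = ", ".join(
            f"#{i}({s.res_name[i]}{s.res_id[i]}/{s.name[i]})" for i in hits
        )
        raise SelectionError(f"selector {sel} matched {len(hits)} atoms: {listing}")
    return int(hits[0])


# ---------------------------------------------------------------------------
# PDB reading/writing (biotite underneath; nm at this surface)
# ---------------------------------------------------------------------------


def _prescan_pdb_lines(lines: list[str]) -> None:
    """Cheap fixed-width sanity check so format errors carry a line number."""
    for lineno, line in enumerate(lines, start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        if len(line.rstrip("\n")) < 54:
            raise ParseError(f"line {lineno}: coordinate record shorter than 54 columns")
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            try:
                float(line[lo:hi])
            except ValueError:
                raise ParseError(
                    f"line {lineno}: malformed {what} coordinate field {line[lo:hi]!r}"
                ) from None


def _atom_array_to_structure(arr: AtomArray) -> Structure:
    box = None
    if arr.box is not None:
        diag = np.diagonal(np.asarray(arr.box, dtype=float))
        if np.any(diag > 0):
            box = diag / ANGSTROM_PER_NM
    return Structure(
        serial=arr.get_annotation("atom_id"),
        name=arr.atom_name,
        res_name=arr.res_name,
        res_id=arr.res_id,
        chain=arr.chain_id,
        element=arr.element,
        coords=np.asarray(arr.coord, dtype=float) / ANGSTROM_PER_NM,
        box=box,
    )


def _model_atom_counts(lines: list[str]) -> list[int]:
    """ATOM/HETATM count per MODEL block (single implicit model if none)."""
    counts: list[int] = []
    current = 0
    in_model = False
    saw_model = False
    for line in lines:
        if line.startswith("MODEL"):
            saw_model = True
            in_model = True
            current = 0
        elif line.startswith("ENDMDL"):
            counts.append(current)
            in_model = False
        elif line.startswith(("ATOM  ", "HETATM")):
            current += 1
    if not saw_model:
        return [current]
    if in_model:  # MODEL without ENDMDL
        counts.append(current)
    return counts


def read_pdb(path, model: int = 1) -> Structure:
    """Read one model of a PDB file; HETATM records (heme, ligand) are kept."""
    with open(path) as fh:
        lines = fh.readlines()
    _prescan_pdb_lines(lines)
    pdb = PDBFile.read(_stdio.StringIO("".join(lines)))
    try:
        arr = pdb.get_structure(model=model, extra_fields=["atom_id"])
    except Exception as exc:  # biotite error types vary by failure mode
        raise ParseError(f"{path}: {exc}") from exc
    return _atom_array_to_structure(arr)


def read_multimodel_pdb(path) -> Trajectory:
    """Read MODEL/ENDMDL blocks as trajectory frames (one frame if no MODEL)."""
    with open(path) as fh:
        lines = fh.readlines()
    _prescan_pdb_lines(lines)
    counts = _model_atom_counts(lines)
    if len(set(counts)) > 1:
        offender = next(i for i, c in enumerate(counts, start=1) if c != counts[0])
        raise ParseError(
            f"{path}: model {offender} has {counts[offender - 1]} atoms, "
            f"model 1 has {counts[0]}"
        )
    pdb = PDBFile.read(_stdio.StringIO("".join(lines)))
    first = _atom_array_to_structure(pdb.get_structure(model=1, extra_fields=["atom_id"]))
    n_models = pdb.get_model_count()
    frames = np.empty((n_models, first.n_atoms, 3), dtype=float)
    for m in range(1, n_models + 1):
        frames[m - 1] = np.asarray(
            pdb.get_coord(model=m), dtype=float
        ) / ANGSTROM_PER_NM
    box = None
    if first.box is not None:
        box = np.tile(first.box, (n_models, 1))
    return Trajectory(atoms=first, coords=frames, box=box)


def write_pdb(path, structure: Structure) -> None:
    """Write a Structure as PDB (nm converted back to Å)."""
    n = structure.n_atoms
    arr = AtomArray(n)
    arr.coord = structure.coords * ANGSTROM_PER_NM
    arr.atom_name = structure.name
    arr.res_name = structure.res_name
    arr.res_id = structure.res_id
    arr.chain_id = structure.chain
    arr.element = structure.element
    arr.set_annotation("atom_id", structure.serial)
    arr.hetero = np.isin(structure.res_name, _HET_RESNAMES_GUESS(structure))
    if structure.box is not None:
        box_a = structure.box * ANGSTROM_PER_NM
        arr.box = np.diag(box_a)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


_STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def _HET_RESNAMES_GUESS(structure: Structure) -> list[str]:
    return sorted(set(structure.res_name.tolist()) - _STANDARD_AA)


# ---------------------------------------------------------------------------
# Frame-table dialect
#
# Trajectory frames: TSV with header columns  frame  atom_id  x  y  z
# (coordinates in nm; frame numbers monotone, need not be contiguous).
# Atom metadata sidecar: TSV with header
# serial  name  res_name  res_id  chain  element
# row order defines atom order; atom_id in the frame table refers to serial.
# ---------------------------------------------------------------------------

FRAME_TABLE_COLUMNS = ["frame", "atom_id", "x", "y", "z"]
ATOM_TABLE_COLUMNS = ["serial", "name", "res_name", "res_id", "chain", "element"]


def read_frame_table(frames_path, atoms_path) -> Trajectory:
    """Assemble a Trajectory from the frame-table TSV dialect."""
    atoms_df = pd.read_csv(atoms_path, sep="\t", dtype={"chain": str})
    missing = [c for c in ATOM_TABLE_COLUMNS if c not in atoms_df.columns]
    if missing:
        raise ParseError(f"{atoms_path}: missing atom-table columns {missing}")
    atoms = Structure(
        serial=atoms_df["serial"].to_numpy(),
        name=atoms_df["name"].to_numpy(dtype="U6"),
        res_name=atoms_df["res_name"].to_numpy(dtype="U6"),
        res_id=atoms_df["res_id"].to_numpy(),
        chain=atoms_df["chain"].to_numpy(dtype="U6"),
        element=atoms_df["element"].to_numpy(dtype="U6"),
        coords=np.zeros((len(atoms_df), 3)),
    )
    df = pd.read_csv(frames_path, sep="\t")
    missing = [c for c in FRAME_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{frames_path}: missing frame-table columns {missing}")
    frame_ids = np.sort(df["frame"].unique())
    serial_order = {s: i for i, s in enumerate(atoms.serial.tolist())}
    coords = np.full((len(frame_ids), atoms.n_atoms, 3), np.nan)
    frame_pos = {f: t for t, f in enumerate(frame_ids.tolist())}
    rows_t = df["frame"].map(frame_pos).to_numpy()
    try:
        rows_a = df["atom_id"].map(serial_order).to_numpy(dtype=int)
    except (ValueError, TypeError):
        unknown = sorted(set(df["atom_id"]) - set(serial_order))
        raise ParseError(f"{frames_path}: atom_id values not in atom table: {unknown}") from None
    coords[rows_t, rows_a, 0] = df["x"].to_numpy(dtype=float)
    coords[rows_t, rows_a, 1] = df["y"].to_numpy(dtype=float)
    coords[rows_t, rows_a, 2] = df["z"].to_numpy(dtype=float)
    bad = np.nonzero(np.isnan(coords).any(axis=(1, 2)))[0]
    if len(bad):
        missing_atoms = np.nonzero(np.isnan(coords[bad[0], :, 0]))[0]
        raise ParseError(
            f"{frames_path}: frame {frame_ids[bad[0]]} is missing atoms "
            f"{atoms.serial[missing_atoms].tolist()}"
        )
    atoms = atoms.with_coords(coords[0])
    return Trajectory(atoms=atoms, coords=coords)


def write_frame_table(frames_path, atoms_path, traj: Trajectory) -> None:
    """Write a Trajectory in the frame-table TSV dialect (nm, full precision)."""
    a = traj.atoms
    pd.DataFrame(
        {
            "serial": a.serial,
            "name": a.name,
            "res_name": a.res_name,
            "res_id": a.res_id,
            "chain": a.chain,
            "element": a.element,
        }
    ).to_csv(atoms_path, sep="\t", index=False)
    n_f, n_a = traj.n_frames, traj.n_atoms
    frame_col = np.repeat(np.arange(n_f), n_a)
    atom_col = np.tile(a.serial, n_f)
    flat = traj.coords.reshape(n_f * n_a, 3)
    pd.DataFrame(
        {
            "frame": frame_col,
            "atom_id": atom_col,
            "x": flat[:, 0],
            "y": flat[:, 1],
            "z": flat[:, 2],
        }
    ).to_csv(frames_path, sep="\t", index=False, float_format="%.9f")
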
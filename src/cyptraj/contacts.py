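"""Geometric protein-ligand contact detection and a pluggable affinity model.

Hydrogen bonds: donor/acceptor heavy atoms are N or O; a bond needs
donor-acceptor distance <= 0.35 nm and a D-H...A angle (at the hydrogen)
>= 120 degrees. Structures without explicit hydrogens fall back to the
distance-only heavy-atom criterion, and such contacts are flagged.

Hydrophobic contacts: pairs of apolar carbons (carbons not covalently
bonded to N or O; bonds inferred from inter-heavy-atom distance < 0.17 nm)
within 0.40 nm across the protein-ligand interface.

The affinity estimate is a transparent linear model over contact-class
counts with user-supplied coefficients (negative = favourable, kcal/mol).
Its output is model-dependent: it gives a PRODIGY-style interface without
shipping any fitted coefficient set.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .io import AtomSelector, SelectionError, Structure, select_atoms

BOND_CUTOFF_NM = 0.17  # heavy-heavy covalent bond inference
H_BOND_LENGTH_NM = 0.125  # X-H covalent attachment inference

__all__ = [
    "Contact",
    "InteractionReport",
    "detect_hbonds",
    "detect_hydrophobic",
    "build_interaction_report",
    "affinity_estimate",
]


@dataclass(frozen=True)
class Contact:
    kind: str  # "hbond" | "hydrophobic"
    protein_index: int
    protein_atom: str
    protein_residue: str  # e.g. "THR124"
    ligand_index: int
    ligand_atom: str
    distance: float  # nm, heavy-atom distance
    angle: float | None = None  # degrees, hbond only
    heavy_atom_fallback: bool = False  # hbond detected without explicit H

    def __post_init__(self) -> None:
        if self.kind not in ("hbond", "hydrophobic"):
            raise ValueError(f"unknown contact kind {self.kind!r}")
        if self.distance <= 0:
            raise ValueError("contact distance must be positive")


@dataclass
class InteractionReport:
    complex_id: str
    contacts: list[Contact]
    per_residue_counts: dict[str, int] = field(init=False)
    predominant_kind: str = field(init=False)
    affinity_kcal_mol: float | None = None

    def __post_init__(self) -> None:
        residue_counter: Counter = Counter(c.protein_residue for c in self.contacts)
        self.per_residue_counts = dict(sorted(residue_counter.items()))
        kinds = Counter(c.kind for c in self.contacts)
        n_hb, n_hp = kinds.get("hbond", 0), kinds.get("hydrophobic", 0)
        if n_hb == n_hp:
            self.predominant_kind = "mixed"
        else:
            self.predominant_kind = "hbond" if n_hb > n_hp else "hydrophobic"


def _partition(s: Structure, ligand: AtomSelector | str) -> tuple[np.ndarray, np.ndarray]:
    lig = select_atoms(s, ligand)
    if len(lig) == 0:
        raise SelectionError("ligand selection matched no atoms")
    mask = np.zeros(s.n_atoms, dtype=bool)
    mask[lig] = True
    return np.nonzero(~mask)[0], lig


def _bond_adjacency(s: Structure) -> np.ndarray:
    """Covalent bonds inferred by distance; hydrogens use a shorter cutoff."""
    d = cdist(s.coords, s.coords)
    is_h = s.element == "H"
    cutoff = np.where(is_h[:, None] | is_h[None, :], H_BOND_LENGTH_NM, BOND_CUTOFF_NM)
    adj = (d < cutoff) & (d > 1e-9)
    return adj


def _residue_label(s: Structure, i: int) -> str:
    return f"{s.res_name[i]}{s.res_id[i]}"


def detect_hbonds(
    s: Structure,
    ligand: AtomSelector | str,
    d_max: float = 0.35,
    angle_min: float = 120.0,
) -> list[Contact]:
    """Hydrogen bonds across the protein-ligand interface, both directions."""
    protein_idx, ligand_idx = _partition(s, ligand)
    adj = _bond_adjacency(s)
    polar = np.isin(s.element, ("N", "O"))
    is_h = s.element == "H"
    # heavy-atom-only fallback applies only to structures with no explicit
    # hydrogens at all; if hydrogens are present, an N/O without one is
    # simply not a donor (prevents double counting donor<->acceptor roles)
    structure_has_h = bool(np.any(is_h))
    contacts: list[Contact] = []
    for donors_side, acceptors_side, donor_is_protein in (
        (protein_idx, ligand_idx, True),
        (ligand_idx, protein_idx, False),
    ):
        donors = [i for i in donors_side if polar[i]]
        acceptors = [j for j in acceptors_side if polar[j]]
        for d_i in donors:
            attached_h = np.nonzero(adj[d_i] & is_h)[0]
            if len(attached_h) == 0 and structure_has_h:
                continue  # not a donor in a protonated structure
            for a_i in acceptors:
                dist = float(np.linalg.norm(s.coords[d_i] - s.coords[a_i]))
                if dist > d_max:
                    continue
                if len(attached_h) > 0:
                    best = _best_dha_angle(s, d_i, attached_h, a_i)
                    if best < angle_min:
                        continue
                    angle, fallback = best, False
                else:
                    angle, fallback = None, True
                p_i, l_i = (d_i, a_i) if donor_is_protein else (a_i, d_i)
                contacts.append(
                    Contact(
                        kind="hbond",
                        protein_index=int(p_i),
                        protein_atom=str(s.name[p_i]),
                        protein_residue=_residue_label(s, p_i),
                        ligand_index=int(l_i),
                        ligand_atom=str(s.name[l_i]),
                        distance=dist,
                        angle=angle,
                        heavy_atom_fallback=fallback,
                    )
                )
    return contacts


def _best_dha_angle(s: Structure, donor: int, hydrogens: np.ndarray, acceptor: int) -> float:
    """Largest D-H...A angle (degrees, at H) over the donor's hydrogens."""
    best = 0.0
    for h in hydrogens:
        v1 = s.coords[donor] - s.coords[h]
        v2 = s.coords[acceptor] - s.coords[h]
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        best = max(best, float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))))
    return best


def apolar_carbons(s: Structure) -> np.ndarray:
    """Indices of carbons not covalently bonded to N or O."""
    adj = _bond_adjacency(s)
    polar = np.isin(s.element, ("N", "O"))
    carbons = np.nonzero(s.element == "C")[0]
    return np.array([i for i in carbons if not np.any(adj[i] & polar)], dtype=int)


def detect_hydrophobic(
    s: Structure, ligand: AtomSelector | str, d_max: float = 0.40
) -> list[Contact]:
    """Apolar-carbon pairs across the protein-ligand interface within d_max."""
    protein_idx, ligand_idx = _partition(s, ligand)
    apolar = set(apolar_carbons(s).tolist())
    p_c = [i for i in protein_idx if i in apolar]
    l_c = [i for i in ligand_idx if i in apolar]
    contacts: list[Contact] = []
    for p_i in p_c:
        for l_i in l_c:
            dist = float(np.linalg.norm(s.coords[p_i] - s.coords[l_i]))
            if dist <= d_max:
                contacts.append(
                    Contact(
                        kind="hydrophobic",
                        protein_index=int(p_i),
                        protein_atom=str(s.name[p_i]),
                        protein_residue=_residue_label(s, p_i),
                        ligand_index=int(l_i),
                        ligand_atom=str(s.name[l_i]),
                        distance=dist,
                    )
                )
    return contacts


def build_interaction_report(
    complex_id: str,
    s: Structure,
    ligand: AtomSelector | str,
    hbond_d_max: float = 0.35,
    hbond_angle_min: float = 120.0,
    hydrophobic_d_max: float = 0.40,
    coefficients: dict | None = None,
) -> InteractionReport:
    """Run both detectors and assemble the per-complex interaction report."""
    contacts = detect_hbonds(s, ligand, d_max=hbond_d_max, angle_min=hbond_angle_min)
    contacts += detect_hydrophobic(s, ligand, d_max=hydrophobic_d_max)
    report = InteractionReport(complex_id=complex_id, contacts=contacts)
    if coefficients is not None:
        report.affinity_kcal_mol = affinity_estimate(report, coefficients)
    return report


def contact_class_counts(report: InteractionReport, s: Structure | None = None) -> dict[str, int]:
    """Counts by contact kind ("hbond"/"hydrophobic"); the class vocabulary
    of the linear affinity model."""
    return dict(Counter(c.kind for c in report.contacts))


def affinity_estimate(report: InteractionReport, coefficients: dict) -> float:
    """Linear contact-count binding-affinity estimate (kcal/mol).

    ``coefficients`` maps contact-class names ("hbond", "hydrophobic") to
    weights, plus an "intercept" entry. Negative output = favourable.
    Unknown class names are an error; classes with zero contacts simply
    contribute nothing.
    """
    allowed = {"intercept", "hbond", "hydrophobic"}
    unknown = set(coefficients) - allowed
    if unknown:
        raise ValueError(f"unknown contact classes in coefficients: {sorted(unknown)}")
    counts = contact_class_counts(report)
    dg = float(coefficients.get("intercept", 0.0))
    for klass, weight in coefficients.items():
        if klass == "intercept":
            continue
        dg += float(weight) * counts.get(klass, 0)
    return dg
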
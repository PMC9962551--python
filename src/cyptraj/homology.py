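"""Proximate-homolog mining by percent identity, with conservation profiles.

For each species, the CYP most likely to carry the reaction is taken to be
the one with the highest percent sequence identity to the human reference
(its "proximate homolog"). Candidates below a usability floor (50% identity
by default) are excluded as too divergent to preserve the function — this
is how chicken drops out of the CYP2A6 analysis — and equal-identity ties
are all retained, which is how rabbit contributes both CYP2A10 and CYP2A11.

Percent identity convention: identical columns divided by columns where
neither sequence is gapped, x100. Alignments are affine-gap global
(Needleman-Wunsch) alignments, BLOSUM62 with gap open 10 / extend 0.5 by
default, computed with Biopython's PairwiseAligner. Conservation profiles
are reference-anchored: each homolog is aligned pairwise to the reference
and per-reference-position matches are counted, rather than building a
progressive MSA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

AMINO_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

__all__ = [
    "ProteinSequence",
    "PairwiseAlignment",
    "IdentityMatrix",
    "HomologSelection",
    "read_fasta",
    "write_fasta",
    "global_align",
    "percent_identity",
    "build_identity_matrix",
    "select_proximate_homolog",
    "conservation_profile",
]


@dataclass(frozen=True)
class ProteinSequence:
    id: str
    residues: str
    species: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - AMINO_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains illegal residue characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PairwiseAlignment:
    id_a: str
    id_b: str
    gapped_a: str
    gapped_b: str
    score: float
    n_identical: int
    n_aligned_columns: int  # columns where neither row is a gap

    def __post_init__(self) -> None:
        if len(self.gapped_a) != len(self.gapped_b):
            raise ValueError("gapped strings must have equal length")
        if self.n_identical > self.n_aligned_columns:
            raise ValueError("n_identical cannot exceed n_aligned_columns")


@dataclass
class IdentityMatrix:
    ids: list[str]
    values: np.ndarray  # (n, n) percent identities

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(np.diag(self.values), 100.0, atol=1e-9):
            raise ValueError("diagonal must be 100")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class HomologSelection:
    """Outcome of proximate-homolog mining against one reference."""

    reference_id: str
    ranked: list[tuple[str, float]]  # (candidate id, percent identity), best first
    selected: list[str]  # all ties at the maximal identity
    excluded: dict[str, str]  # candidate id -> reason
    all_excluded: bool  # no usable homolog in this species (chicken case)


def read_fasta(path) -> list[ProteinSequence]:
    """Read protein sequences; uppercased, whitespace stripped, validated."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        residues = "".join(str(rec.seq).split()).upper()
        try:
            out.append(ProteinSequence(id=rec.id, residues=residues))
        except ValueError as exc:
            raise ValueError(f"{path}: record {rec.id!r}: {exc}") from exc
    return out


def write_fasta(path, seqs: list[ProteinSequence], width: int = 60) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for k in range(0, len(s.residues), width):
                fh.write(s.residues[k : k + width] + "\n")


def _aligner(matrix: str, gap_open: float, gap_extend: float) -> PairwiseAligner:
    try:
        sub = substitution_matrices.load(matrix)
    except FileNotFoundError:
        raise ValueError(f"unknown substitution matrix {matrix!r}") from None
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = sub
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    return aligner


def global_align(
    a: ProteinSequence,
    b: ProteinSequence,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> PairwiseAlignment:
    """Optimal affine-gap global alignment; deterministic (first co-optimal
    traceback in Biopython's canonical enumeration order)."""
    aligner = _aligner(matrix, gap_open, gap_extend)
    aln = aligner.align(a.residues, b.residues)[0]
    gapped_a, gapped_b = str(aln[0]), str(aln[1])
    n_id = sum(
        1 for x, y in zip(gapped_a, gapped_b) if x == y and x != "-"
    )
    n_cols = sum(1 for x, y in zip(gapped_a, gapped_b) if x != "-" and y != "-")
    return PairwiseAlignment(
        id_a=a.id,
        id_b=b.id,
        gapped_a=gapped_a,
        gapped_b=gapped_b,
        score=float(aln.score),
        n_identical=n_id,
        n_aligned_columns=n_cols,
    )


def percent_identity(aln: PairwiseAlignment) -> float:
    """100 x identical columns / columns where neither sequence is gapped."""
    if aln.n_aligned_columns == 0:
        raise ValueError(
            f"alignment {aln.id_a}/{aln.id_b} has no aligned columns; identity undefined"
        )
    return 100.0 * aln.n_identical / aln.n_aligned_columns


def build_identity_matrix(
    seqs: list[ProteinSequence],
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> IdentityMatrix:
    """Percent-identity matrix over all sequence pairs."""
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    n = len(seqs)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pid = percent_identity(
                global_align(seqs[i], seqs[j], matrix=matrix, gap_open=gap_open, gap_extend=gap_extend)
            )
            values[i, j] = values[j, i] = pid
    return IdentityMatrix(ids=ids, values=values)


def select_proximate_homolog(
    reference: ProteinSequence,
    candidates: list[ProteinSequence],
    min_identity: float = 50.0,
    **align_kwargs,
) -> HomologSelection:
    """Rank candidates by identity to the reference and pick the best.

    All candidates tied (within 1e-9) at the maximal identity are selected;
    candidates below ``min_identity`` are excluded with reason
    "below_min_identity". If every candidate is excluded the selection is
    empty and flagged.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    scored = [
        (c.id, percent_identity(global_align(reference, c, **align_kwargs)))
        for c in candidates
    ]
    ranked = sorted(scored, key=lambda t: (-t[1], t[0]))
    excluded = {cid: "below_min_identity" for cid, pid in ranked if pid < min_identity}
    usable = [(cid, pid) for cid, pid in ranked if cid not in excluded]
    if not usable:
        return HomologSelection(
            reference_id=reference.id,
            ranked=ranked,
            selected=[],
            excluded=excluded,
            all_excluded=True,
        )
    best = usable[0][1]
    selected = [cid for cid, pid in usable if abs(pid - best) <= 1e-9]
    return HomologSelection(
        reference_id=reference.id,
        ranked=ranked,
        selected=selected,
        excluded=excluded,
        all_excluded=False,
    )


def conservation_profile(
    reference: ProteinSequence,
    homologs: list[ProteinSequence],
    site_residues: list[int] | None = None,
    **align_kwargs,
) -> pd.DataFrame:
    """Per-reference-position conservation across homologs.

    For each 1-based reference position, the percentage of homologs whose
    residue aligned to that position (via pairwise global alignment to the
    reference) matches the reference residue; a gap counts as a mismatch.
    ``site_residues`` marks positions of interest (e.g. ligand-contacting
    residues) in the ``is_site_residue`` column.
    """
    if not homologs:
        raise ValueError("need at least one homolog")
    n = len(reference)
    sites = set(site_residues or [])
    bad = [p for p in sites if not 1 <= p <= n]
    if bad:
        raise ValueError(f"site residues outside reference length {n}: {sorted(bad)}")
    matches = np.zeros(n, dtype=int)
    for hom in homologs:
        aln = global_align(reference, hom, **align_kwargs)
        ref_pos = 0
        for x, y in zip(aln.gapped_a, aln.gapped_b):
            if x == "-":
                continue
            if y == x:
                matches[ref_pos] += 1
            ref_pos += 1
    pct = 100.0 * matches / len(homologs)
    return pd.DataFrame(
        {
            "pos": np.arange(1, n + 1),
            "ref_residue": list(reference.residues),
            "conservation_pct": pct,
            "is_site_residue": [p in sites for p in range(1, n + 1)],
        }
    )
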
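import numpy as np
import pytest

from cyptraj.homology import (
    ProteinSequence,
    build_identity_matrix,
    conservation_profile,
    global_align,
    percent_identity,
    read_fasta,
    select_proximate_homolog,
    write_fasta,
)
from cyptraj.synth import mutate_sequence

# a 360-residue pseudo-protein; long enough that identity targets are tight
REF = ProteinSequence(
    "ref",
    (
        "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVK"
        "ALPDAQFEVVHSLAKWKRQTLGQHDFSAGEGLYTHMKALRPDEDRLSPLHSVYVDQWDWE"
        "RVMGDGERQFSTLKSTVEAIWAGIKATEAAVSEEFGLAPFLPDQIHFVHSQELLSRYPDL"
        "DAKGRERAIAKDLGAVFLVGIGGKLSDGHRHDVRAPDYDDWSTPSELGHAGLNGDILVWN"
        "PVLEDAFELSSMGIRVDADTLKHQLALTGDEDRLELEWHQALLRGEMPQTIGGGIGQSRL"
        "TMLLLQLPHIGQVQAGVWPAAVRESVPSLLQVKDQLRAMGAEVKVTSDPRHAADLHRSGN"
    ),
)


def brute_force_identity(gapped_a: str, gapped_b: str) -> float:
    """Independent column recount over the alignment strings."""
    ident = cols = 0
    for x, y in zip(gapped_a, gapped_b):
        if x != "-" and y != "-":
            cols += 1
            if x == y:
                ident += 1
    return 100.0 * ident / cols


class TestReadFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nMKT\n")
        seqs = read_fasta(p)
        assert len(seqs) == 1
        assert seqs[0].id == "a" and seqs[0].residues == "MKT"

    def test_two_records_preserve_order(self, tmp_path):
        p = tmp_path / "ab.fasta"
        p.write_text(">a\nMKT\n>b\nMTT\n")
        assert [s.id for s in read_fasta(p)] == ["a", "b"]

    def test_lowercase_and_wrapped_lines_normalised(self, tmp_path):
        p = tmp_path / "w.fasta"
        p.write_text(">a\nmkt\nay\n")
        assert read_fasta(p)[0].residues == "MKTAY"

    def test_illegal_residue_names_record(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">a\nMK7\n")
        with pytest.raises(ValueError, match="'a'"):
            read_fasta(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(ValueError, match="no FASTA records"):
            read_fasta(p)

    def test_write_read_roundtrip(self, tmp_path):
        p = tmp_path / "rt.fasta"
        write_fasta(p, [REF])
        assert read_fasta(p)[0].residues == REF.residues


class TestGlobalAlign:
    def test_identical_sequences(self):
        a = ProteinSequence("a", "MKT")
        aln = global_align(a, ProteinSequence("b", "MKT"))
        assert aln.n_identical == 3
        assert aln.n_aligned_columns == 3
        assert "-" not in aln.gapped_a + aln.gapped_b

    def test_deletion_gives_exactly_one_gap_column(self):
        aln = global_align(ProteinSequence("a", "MKT"), ProteinSequence("b", "MT"))
        gap_cols = sum(1 for x, y in zip(aln.gapped_a, aln.gapped_b) if "-" in (x, y))
        assert gap_cols == 1
        assert aln.gapped_a.replace("-", "") == "MKT"
        assert aln.gapped_b.replace("-", "") == "MT"

    def test_score_symmetric(self):
        a, b = REF, mutate_sequence(REF, 70, seed=11)
        assert global_align(a, b).score == pytest.approx(global_align(b, a).score)

    def test_unknown_matrix_rejected(self):
        with pytest.raises(ValueError, match="unknown substitution matrix"):
            global_align(REF, REF, matrix="NOSUCH99")


class TestPercentIdentity:
    def test_identical_is_100(self):
        assert percent_identity(global_align(REF, REF)) == pytest.approx(100.0)

    def test_three_of_four(self):
        aln = global_align(ProteinSequence("a", "AAAA"), ProteinSequence("b", "AAAT"))
        assert percent_identity(aln) == pytest.approx(75.0)

    @pytest.mark.parametrize("target,seed", [(90, 1), (75, 2), (55, 3)])
    def test_matches_brute_force_recount(self, target, seed):
        aln = global_align(REF, mutate_sequence(REF, target, seed=seed))
        assert percent_identity(aln) == pytest.approx(
            brute_force_identity(aln.gapped_a, aln.gapped_b)
        )


class TestIdentityMatrix:
    def test_two_identical_sequences(self):
        m = build_identity_matrix([REF, ProteinSequence("copy", REF.residues)])
        np.testing.assert_allclose(m.values, 100.0)

    def test_three_by_three_symmetric(self):
        seqs = [REF, mutate_sequence(REF, 85, seed=5), mutate_sequence(REF, 60, seed=6)]
        m = build_identity_matrix(seqs)
        assert m.values.shape == (3, 3)
        np.testing.assert_allclose(m.values, m.values.T, atol=1e-9)
        np.testing.assert_allclose(np.diag(m.values), 100.0)

    def test_known_mutation_level_recovered(self):
        m = build_identity_matrix([REF, mutate_sequence(REF, 90, seed=7)])
        assert m.values[0, 1] == pytest.approx(90.0, abs=2.0)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_identity_matrix([REF, REF])


class TestProximateHomolog:
    def test_selects_highest_identity_only(self):
        cands = [mutate_sequence(REF, 85, seed=21), mutate_sequence(REF, 60, seed=22)]
        sel = select_proximate_homolog(REF, cands)
        assert sel.selected == [cands[0].id]
        assert not sel.all_excluded

    def test_equal_identity_tie_selects_both(self):
        # the rabbit situation: two homologs at the same identity
        a = mutate_sequence(REF, 84, seed=31)
        b = ProteinSequence("other84", a.residues)
        sel = select_proximate_homolog(REF, [a, b])
        assert set(sel.selected) == {a.id, "other84"}

    def test_all_below_floor_flagged_empty(self):
        # the chicken situation: best candidate under 50% -> unusable
        lone = mutate_sequence(REF, 45, seed=41)
        sel = select_proximate_homolog(REF, [lone], min_identity=50.0)
        assert sel.selected == []
        assert sel.all_excluded
        assert sel.excluded == {lone.id: "below_min_identity"}

    def test_partition_has_no_overlap(self):
        cands = [mutate_sequence(REF, t, seed=50 + t) for t in (88, 70, 45)]
        sel = select_proximate_homolog(REF, cands)
        ranked_ids = {cid for cid, _ in sel.ranked}
        assert set(sel.selected) <= ranked_ids
        assert set(sel.excluded) <= ranked_ids
        assert not set(sel.selected) & set(sel.excluded)

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_proximate_homolog(REF, [])


class TestConservationProfile:
    def test_identical_homologs_fully_conserved(self):
        prof = conservation_profile(REF, [ProteinSequence("h1", REF.residues)])
        assert (prof["conservation_pct"] == 100.0).all()

    def test_single_mutation_in_one_of_two_homologs(self):
        k = 100  # 1-based position
        residues = list(REF.residues)
        residues[k - 1] = "W" if residues[k - 1] != "W" else "Y"
        mutant = ProteinSequence("mut", "".join(residues))
        prof = conservation_profile(REF, [ProteinSequence("h1", REF.residues), mutant])
        assert prof.loc[prof["pos"] == k, "conservation_pct"].iloc[0] == pytest.approx(50.0)
        others = prof.loc[prof["pos"] != k, "conservation_pct"]
        assert (others == 100.0).all()

    def test_site_residue_flag(self):
        prof = conservation_profile(REF, [REF], site_residues=[5, 10])
        assert prof.loc[prof["pos"].isin([5, 10]), "is_site_residue"].all()
        assert prof["is_site_residue"].sum() == 2

    def test_site_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside reference length"):
            conservation_profile(REF, [REF], site_residues=[99999])

    def test_matches_brute_force_column_recount(self):
        homs = [mutate_sequence(REF, 80, seed=61), mutate_sequence(REF, 90, seed=62)]
        prof = conservation_profile(REF, homs)
        # independent recount via the alignment strings
        n = len(REF)
        matches = np.zeros(n)
        for h in homs:
            aln = global_align(REF, h)
            pos = 0
            for x, y in zip(aln.gapped_a, aln.gapped_b):
                if x != "-":
                    if x == y:
                        matches[pos] += 1
                    pos += 1
        np.testing.assert_allclose(prof["conservation_pct"], 100.0 * matches / 2)


class TestMutateSequence:
    def test_target_100_unchanged(self):
        assert mutate_sequence(REF, 100, seed=1).residues == REF.residues

    @pytest.mark.parametrize("target", [95, 80, 55])
    def test_measured_identity_within_three_points(self, target):
        mut = mutate_sequence(REF, target, seed=target)
        pid = percent_identity(global_align(REF, mut))
        assert abs(pid - target) <= 3.0

    def test_target_outside_range_rejected(self):
        with pytest.raises(ValueError):
            mutate_sequence(REF, 0, seed=1)
        with pytest.raises(ValueError):
            mutate_sequence(REF, 101, seed=1)

    def test_determinism(self):
        a = mutate_sequence(REF, 80, seed=9)
        b = mutate_sequence(REF, 80, seed=9)
        c = mutate_sequence(REF, 80, seed=10)
        assert a.residues == b.residues
        assert a.residues != c.residues
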
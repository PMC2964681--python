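import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import enum_local, slow_local
from ryhbkit._align import local_align_codes
from ryhbkit.genome_model import GeneFeature
from ryhbkit.orthology import (
    best_hits,
    global_identity,
    local_align,
    reciprocal_best_hits,
)
from ryhbkit.synthetic_data import GenomeSimParams, simulate_genome_pair

AA = "ARNDCQEGHILKMFPSTWYV"


def _feat(tag, protein):
    return GeneFeature(tag, "c", 0, 3 * (len(protein) + 1), "+", translation=protein)


class TestLocalAlignKernel:
    """The Gotoh kernel must agree with independent slow oracles."""

    def test_enumeration_validates_cubic_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            a = rng.integers(0, 4, size=rng.integers(1, 5))
            b = rng.integers(0, 4, size=rng.integers(1, 5))
            sub = rng.integers(-4, 5, size=(4, 4)).astype(float)
            go, ge = -float(rng.integers(0, 6)), -float(rng.integers(1, 3))
            assert slow_local(a, b, sub, go, ge) == pytest.approx(
                enum_local(a, b, sub, go, ge)
            )

    def test_kernel_matches_bruteforce_on_short_strings(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            a = rng.integers(0, 4, size=rng.integers(1, 9))
            b = rng.integers(0, 4, size=rng.integers(1, 9))
            sub = rng.integers(-4, 5, size=(4, 4)).astype(float)
            go, ge = -float(rng.integers(0, 8)), -float(rng.integers(1, 4))
            score, *_ = local_align_codes(a, b, sub, go, ge)
            assert score == pytest.approx(slow_local(a, b, sub, go, ge))

    def test_score_matches_reference_aligner_on_random_proteins(self):
        from Bio import Align
        from Bio.Align import substitution_matrices

        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -12  # first gap residue: open + extend
        aligner.extend_gap_score = -1
        rng = np.random.default_rng(2)
        for _ in range(25):
            a = "".join(rng.choice(list(AA), rng.integers(15, 60)))
            b = "".join(rng.choice(list(AA), rng.integers(15, 60)))
            assert local_align(a, b).score == pytest.approx(aligner.score(a, b))


class TestLocalAlign:
    def test_self_alignment_has_full_identity_and_diagonal_score(self):
        from Bio.Align import substitution_matrices

        seq = "MKVLATTLGAARW"
        blosum = substitution_matrices.load("BLOSUM62")
        r = local_align(seq, seq)
        assert r.identity == 1.0
        assert r.score == pytest.approx(sum(blosum[c, c] for c in seq))
        assert r.query_interval == (0, len(seq)) == r.subject_interval

    def test_no_positive_pair_gives_empty_alignment(self):
        # L vs P scores -3 in BLOSUM62; no positive cell anywhere
        r = local_align("LLLL", "PPPP")
        assert r.score == 0.0
        assert r.aligned_query == "" and r.query_interval == (0, 0)

    def test_unknown_residue_named_in_error(self):
        with pytest.raises(ValueError, match="'J'"):
            local_align("MKJ", "MKV")

    def test_ungapping_reproduces_interval_slices(self):
        a, b = "MKVATLWRRA", "HHMKVATGWRR"
        r = local_align(a, b)
        qs, qe = r.query_interval
        ss, se = r.subject_interval
        assert r.aligned_query.replace("-", "") == a[qs:qe]
        assert r.aligned_subject.replace("-", "") == b[ss:se]

    @given(data=st.data())
    @settings(max_examples=25)
    def test_score_invariant_under_joint_reversal(self, data):
        a = data.draw(st.text(alphabet=AA, min_size=1, max_size=30))
        b = data.draw(st.text(alphabet=AA, min_size=1, max_size=30))
        assert local_align(a, b).score == local_align(a[::-1], b[::-1]).score


class TestGlobalIdentity:
    def test_identical_sequences(self):
        assert global_identity("MKVLAT", "MKVLAT") == 1.0

    def test_single_substitution(self):
        # 1 mismatch over 10 aligned columns
        assert global_identity("MKVLATWRRA", "MKVLATWRRG") == pytest.approx(0.9)


class TestBestHits:
    def test_single_pair(self):
        hits = best_hits([_feat("A1", "MKVLAT")], [_feat("B1", "MKVLAT")])
        assert hits["A1"][0] == "B1"

    def test_duplicate_subjects_resolve_to_lexicographically_smaller_tag(self):
        subs = [_feat("B2", "MKVLATWR"), _feat("B1", "MKVLATWR")]
        hits = best_hits([_feat("A1", "MKVLATWR")], subs)
        assert hits["A1"][0] == "B1"

    def test_empty_proteome_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            best_hits([], [_feat("B1", "MKV")])

    def test_missing_translation_rejected(self):
        bare = GeneFeature("A1", "c", 0, 30, "+")
        with pytest.raises(ValueError, match="translation"):
            best_hits([bare], [_feat("B1", "MKVLAT")])


class TestReciprocalBestHits:
    def test_self_comparison_pairs_every_protein_with_itself(self):
        prots = [_feat(f"P{i}", p) for i, p in enumerate(
            ["MKVLATWRRA", "MDDEEKKRLL", "MWWYYFFHHG"])]
        pairs = reciprocal_best_hits(prots, prots)
        assert [(p.query_locus, p.subject_locus) for p in pairs] == [
            ("P0", "P0"), ("P1", "P1"), ("P2", "P2")]

    def test_asymmetric_best_hit_excluded(self):
        # both A1 and A2 hit B1 best, but B1 reciprocates only with its
        # own best (the identical A1), so A2 forms no pair
        a = [_feat("A1", "MKVLATWRRA"), _feat("A2", "MKVLATWRRG")]
        b = [_feat("B1", "MKVLATWRRA")]
        pairs = reciprocal_best_hits(a, b)
        assert [(p.query_locus, p.subject_locus) for p in pairs] == [("A1", "B1")]

    def test_role_swap_symmetry(self):
        params = GenomeSimParams(seed=5, n_genes=10, genome_length=20000, anchor_index=4)
        ref, qry, _ = simulate_genome_pair(params)
        ab = reciprocal_best_hits(qry.proteome(), ref.proteome())
        ba = reciprocal_best_hits(ref.proteome(), qry.proteome())
        assert {(p.query_locus, p.subject_locus) for p in ab} == {
            (p.subject_locus, p.query_locus) for p in ba}

    def test_planted_ortholog_found_among_decoys(self):
        params = GenomeSimParams(seed=7, n_genes=12, genome_length=22000,
                                 anchor_index=6, anchor_divergence=0.3)
        ref, qry, truth = simulate_genome_pair(params)
        pairs = reciprocal_best_hits(qry.proteome(), ref.proteome(), prefilter=True)
        assert (truth.anchor_pair[0], truth.anchor_pair[1]) in {
            (p.query_locus, p.subject_locus) for p in pairs}
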
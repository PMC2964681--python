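import numpy as np
import pytest

from ryhbkit.genome_model import GeneFeature, GenomeRecord, Interval, reverse_complement
from ryhbkit.srna_discovery import (
    CoreModel,
    default_core_sequence,
    discover_srna,
    downstream_intergenic,
    find_all_core_homologs,
    find_core_homolog,
)
from ryhbkit.synthetic_data import GenomeSimParams, random_sequence, simulate_genome_pair


def _genome_with(features, length=2000):
    return GenomeRecord("c", "A" * length, features=features)


class TestDownstreamIntergenic:
    def test_truncated_by_next_feature(self):
        anchor = GeneFeature("a", "c", 100, 400, "+")
        nxt = GeneFeature("b", "c", 700, 900, "+")
        g = _genome_with([anchor, nxt])
        iv = downstream_intergenic(g, anchor, max_len=1000)
        assert (iv.start, iv.end, iv.strand) == (400, 700, "+")

    def test_truncated_by_max_len(self):
        anchor = GeneFeature("a", "c", 100, 400, "+")
        g = _genome_with([anchor])
        iv = downstream_intergenic(g, anchor, max_len=300)
        assert (iv.start, iv.end) == (400, 700)

    def test_minus_strand_mirrors_upstream_in_plus_coordinates(self):
        prev = GeneFeature("b", "c", 100, 300, "+")
        anchor = GeneFeature("a", "c", 800, 1100, "-")
        g = _genome_with([prev, anchor])
        iv = downstream_intergenic(g, anchor, max_len=1000)
        assert (iv.start, iv.end, iv.strand) == (300, 800, "-")

    def test_anchor_at_contig_edge_rejected(self):
        anchor = GeneFeature("a", "c", 100, 2000, "+")
        g = _genome_with([anchor])
        with pytest.raises(ValueError, match="downstream"):
            downstream_intergenic(g, anchor, max_len=500)

    def test_foreign_anchor_rejected(self):
        g = _genome_with([GeneFeature("a", "c", 100, 400, "+")])
        with pytest.raises(ValueError, match="belong"):
            downstream_intergenic(g, GeneFeature("x", "c", 0, 30, "+"), 500)

    def test_contains_planted_locus_across_seeds(self, default_core):
        contained = 0
        for seed in range(50):
            ref, qry, truth = simulate_genome_pair(GenomeSimParams(seed=seed))
            anchor = qry.feature_by_tag(truth.anchor_pair[0])
            iv = downstream_intergenic(qry, anchor, max_len=1000)
            if iv.start <= truth.srna_interval.start and truth.srna_interval.end <= iv.end:
                contained += 1
        assert contained == 50


class TestFindCoreHomolog:
    IV = Interval("c", 1000, 1500, "+")

    def test_exact_planting_recovered_at_full_score(self, default_core, rng):
        region = random_sequence(rng, 500, 0.46)
        k = 137
        region = region[:k] + default_core + region[k + len(default_core):]
        core = CoreModel(core_sequence=default_core)
        cand = find_core_homolog(region, self.IV, core)
        assert cand is not None
        assert (cand.locus.start, cand.locus.end) == (1000 + k, 1000 + k + len(default_core))
        assert cand.core_alignment.score == pytest.approx(core.match * len(default_core))
        assert cand.locus.strand == "+"

    def test_opposite_strand_hit_flips_candidate_strand(self, default_core, rng):
        region = random_sequence(rng, 500, 0.46)
        k = 200
        planted = reverse_complement(default_core)
        region = region[:k] + planted + region[k + len(planted):]
        cand = find_core_homolog(region, self.IV, CoreModel(core_sequence=default_core))
        assert cand is not None
        assert cand.locus.strand == "-"
        assert (cand.locus.start, cand.locus.end) == (1200, 1200 + len(default_core))

    def test_random_region_stays_below_threshold(self, default_core):
        rng = np.random.default_rng(99)
        core = CoreModel(core_sequence=default_core)
        hits = sum(
            find_core_homolog(random_sequence(rng, 500, 0.46), self.IV, core) is not None
            for _ in range(200)
        )
        assert hits == 0

    def test_too_short_region_rejected(self, default_core):
        with pytest.raises(ValueError, match="region"):
            find_core_homolog("ACGT", Interval("c", 0, 4), CoreModel(core_sequence=default_core))

    def test_lowering_min_score_never_removes_a_candidate(self, default_core, rng):
        region = random_sequence(rng, 400, 0.46)
        region = region[:50] + default_core + region[50 + len(default_core):]
        strict = CoreModel(core_sequence=default_core, min_score=150.0)
        lax = CoreModel(core_sequence=default_core, min_score=40.0)
        c_strict = find_core_homolog(region, self.IV, strict)
        c_lax = find_core_homolog(region, self.IV, lax)
        assert c_strict is not None and c_lax is not None
        assert c_strict.locus == c_lax.locus


class TestDiscoverSrna:
    def test_zero_divergence_recovers_planted_coordinates_exactly(self, default_core):
        ref, qry, truth = simulate_genome_pair(GenomeSimParams(seed=11))
        cand = discover_srna(qry, truth.anchor_pair[0], CoreModel(core_sequence=default_core))
        assert cand is not None
        assert (cand.locus.start, cand.locus.end, cand.locus.strand) == (
            truth.srna_interval.start, truth.srna_interval.end, truth.srna_interval.strand)
        assert len(cand.upstream_flank) == 100

    def test_minus_strand_anchor_recovered(self, default_core):
        ref, qry, truth = simulate_genome_pair(
            GenomeSimParams(seed=12, anchor_strand="-"))
        cand = discover_srna(qry, truth.anchor_pair[0], CoreModel(core_sequence=default_core))
        assert cand is not None
        assert (cand.locus.start, cand.locus.end, cand.locus.strand) == (
            truth.srna_interval.start, truth.srna_interval.end, "-")

    def test_no_planted_core_yields_none(self, default_core, rng):
        # a genome whose downstream region is random sequence
        anchor = GeneFeature("a", "c", 100, 400, "+")
        g = GenomeRecord("c", random_sequence(rng, 2000, 0.46), features=[anchor])
        cand = discover_srna(g, "a", CoreModel(core_sequence=default_core))
        assert cand is None

    def test_missing_anchor_raises(self, default_core):
        g = _genome_with([GeneFeature("a", "c", 100, 400, "+")])
        with pytest.raises(KeyError, match="nope"):
            discover_srna(g, "nope", CoreModel(core_sequence=default_core))

    def test_discovery_is_deterministic(self, default_core):
        ref, qry, truth = simulate_genome_pair(GenomeSimParams(seed=13, core_divergence=0.1))
        core = CoreModel(core_sequence=default_core)
        c1 = discover_srna(qry, truth.anchor_pair[0], core)
        c2 = discover_srna(qry, truth.anchor_pair[0], core)
        assert c1.locus == c2.locus
        assert c1.core_alignment.aligned_subject == c2.core_alignment.aligned_subject

    def test_candidate_coordinates_consistent_with_1based_report(self, default_core):
        ref, qry, truth = simulate_genome_pair(GenomeSimParams(seed=14))
        cand = discover_srna(qry, truth.anchor_pair[0], CoreModel(core_sequence=default_core))
        s1, e1 = cand.locus.to_1based()
        assert s1 == cand.locus.start + 1
        assert e1 == cand.locus.end
        assert e1 - s1 + 1 == len(cand.locus)


class TestTandemCopies:
    def test_two_planted_copies_both_reported(self, default_core, rng):
        region = random_sequence(rng, 700, 0.46)
        region = region[:50] + default_core + region[50 + len(default_core):]
        region = region[:400] + default_core + region[400 + len(default_core):]
        iv = Interval("c", 0, 700, "+")
        hits = find_all_core_homologs(region, iv, CoreModel(core_sequence=default_core))
        starts = sorted(h.locus.start for h in hits)
        assert starts == [50, 400]
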
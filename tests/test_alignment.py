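import numpy as np
import pytest

from fragpan._sw import encode
from fragpan.alignment import (
    AlignmentHit,
    HitSet,
    ScoringScheme,
    align_gene_to_genome,
    best_hit_statistics,
    write_hits_tsv,
)
from fragpan.genome_io import reverse_complement

from conftest import make_gene, make_genome, mutate, random_seq
from oracles import sw_full


def top_hit(hitset):
    assert hitset.hits, "expected at least one hit"
    return max(hitset.hits, key=lambda h: h.score)


class TestAlignGeneToGenome:
    def test_exact_substring_single_perfect_hit(self, rng):
        contig = random_seq(rng, 2000)
        gene = make_gene(contig[600:1000], "g", "A")
        genome = make_genome("B", {"c1": contig})
        hitset = align_gene_to_genome(gene, genome)
        hit = top_hit(hitset)
        assert hit.identity == 1.0
        assert (hit.q_start, hit.q_end) == (0, 400)
        assert (hit.s_start, hit.s_end) == (600, 1000)
        assert hit.strand == "+"

    def test_split_gene_two_hits_cover_query(self, rng):
        gene_seq = random_seq(rng, 400)
        contig_a = random_seq(rng, 800) + gene_seq[:200]
        contig_b = gene_seq[200:] + random_seq(rng, 800)
        gene = make_gene(gene_seq, "g", "A")
        genome = make_genome("B", {"cA": contig_a, "cB": contig_b})
        hitset = align_gene_to_genome(gene, genome)
        by_contig = {h.contig_id: h for h in hitset.hits if h.score > 150}
        assert set(by_contig) == {"cA", "cB"}
        ha, hb = by_contig["cA"], by_contig["cB"]
        assert (ha.q_start, ha.q_end) == (0, 200)
        assert (hb.q_start, hb.q_end) == (200, 400)

    def test_minus_strand_hit(self, rng):
        gene_seq = random_seq(rng, 300)
        contig = random_seq(rng, 500) + reverse_complement(gene_seq) + random_seq(rng, 500)
        gene = make_gene(gene_seq, "g", "A")
        genome = make_genome("B", {"c": contig})
        hit = top_hit(align_gene_to_genome(gene, genome))
        assert hit.strand == "-"
        assert hit.identity == 1.0
        assert (hit.q_start, hit.q_end) == (0, 300)
        assert (hit.s_start, hit.s_end) == (500, 800)

    def test_no_homology_empty_hitset(self, rng):
        gene = make_gene(random_seq(rng, 100), "g", "A")
        genome = make_genome("B", {"c": random_seq(rng, 1000)})
        hitset = align_gene_to_genome(gene, genome)
        for h in hitset.hits:
            assert h.score >= ScoringScheme().min_hit_score

    def test_empty_gene_rejected(self, rng):
        gene = make_gene("ACGT", "g", "A")
        object.__setattr__(gene, "sequence", "")
        genome = make_genome("B", {"c": random_seq(rng, 100)})
        with pytest.raises(ValueError):
            align_gene_to_genome(gene, genome)


class TestDPOracle:
    @pytest.mark.parametrize("seed", range(20))
    def test_top_score_equals_full_dp_optimum(self, seed):
        """Planted, mutated homology: the heuristic's best score must equal
        the full Smith-Waterman optimum."""
        rng = np.random.default_rng(1000 + seed)
        scoring = ScoringScheme()
        qlen = int(rng.integers(100, 301))
        slen = int(rng.integers(1000, 2001))
        query = random_seq(rng, qlen)
        # plant a mutated copy of a random query segment inside the subject
        seg_lo = int(rng.integers(0, qlen // 3))
        seg_hi = int(rng.integers(2 * qlen // 3, qlen + 1))
        planted = mutate(rng, query[seg_lo:seg_hi], float(rng.uniform(0.0, 0.05)))
        pos = int(rng.integers(0, slen - len(planted)))
        subject = random_seq(rng, pos) + planted + random_seq(rng, slen - pos - len(planted))

        gene = make_gene(query, "g", "A")
        genome = make_genome("B", {"c": subject})
        hitset = align_gene_to_genome(gene, genome, scoring)

        best_fwd = sw_full(
            encode(query), encode(subject),
            scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend,
        )[0]
        best_rev = sw_full(
            encode(reverse_complement(query)), encode(subject),
            scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend,
        )[0]
        optimum = max(best_fwd, best_rev)
        if optimum >= scoring.min_hit_score:
            assert top_hit(hitset).score == optimum
        else:
            assert not hitset.hits

    def test_reverse_complement_symmetry(self, rng):
        gene_seq = mutate(rng, random_seq(rng, 250), 0.02)
        contig = random_seq(rng, 300) + gene_seq + random_seq(rng, 300)
        genome = make_genome("B", {"c": contig})
        fwd = align_gene_to_genome(make_gene(gene_seq, "g", "A"), genome)
        rev = align_gene_to_genome(
            make_gene(reverse_complement(gene_seq), "g", "A"), genome
        )
        fwd_keys = sorted(
            (h.score, h.identity, h.s_start, h.s_end, h.q_end - h.q_start)
            for h in fwd.hits
        )
        rev_keys = sorted(
            (h.score, h.identity, h.s_start, h.s_end, h.q_end - h.q_start)
            for h in rev.hits
        )
        assert fwd_keys == rev_keys
        assert {h.strand for h in fwd.hits} == {"+"}
        assert {h.strand for h in rev.hits} == {"-"}


class TestIdentitySemantics:
    def test_identity_bounds_and_perfect_iff_clean(self, rng):
        contig = random_seq(rng, 1200)
        clean = make_gene(contig[100:400], "clean", "A")
        noisy_seq = mutate(rng, contig[600:900], 0.05)
        noisy = make_gene(noisy_seq, "noisy", "A")
        genome = make_genome("B", {"c": contig})
        for gene, expect_perfect in ((clean, True), (noisy, False)):
            hit = top_hit(align_gene_to_genome(gene, genome))
            assert 0.0 <= hit.identity <= 1.0
            if expect_perfect:
                assert hit.identity == 1.0
            else:
                assert hit.identity < 1.0

    def test_n_bases_never_match(self):
        gene = make_gene("ACGTACGTACGTACGTACGTNNNNACGTACGTACGTACGT", "g", "A")
        contig = "TTTT" + gene.sequence.replace("N", "A") + "TTTT"
        genome = make_genome("B", {"c": contig})
        hit = top_hit(align_gene_to_genome(gene, genome))
        assert hit.identity < 1.0


class TestDeterminism:
    def test_repeated_runs_byte_identical(self, rng, tmp_path):
        contig = random_seq(rng, 3000)
        genes = [make_gene(mutate(rng, contig[i * 500 : i * 500 + 400], 0.01), f"g{i}", "A")
                 for i in range(4)]
        genome = make_genome("B", {"c": contig})
        outputs = []
        for run in range(2):
            hitsets = [align_gene_to_genome(g, genome) for g in genes]
            path = tmp_path / f"hits{run}.tsv"
            write_hits_tsv(hitsets, path)
            outputs.append(path.read_bytes())
        assert outputs[0] == outputs[1]


class TestBestHitStatistics:
    def _hit(self, q0, q1, identity=1.0, score=100):
        return AlignmentHit("g", "B", "c", q0, q1, 0, q1 - q0, "+", identity, score)

    def test_full_length_perfect(self):
        hs = HitSet("g", "B", [self._hit(0, 100)])
        stats = best_hit_statistics(hs, 100)
        assert stats.top_identity == 1.0
        assert stats.coverages == (1.0,)

    def test_empty(self):
        stats = best_hit_statistics(HitSet("g", "B", []), 100)
        assert stats.top_identity is None
        assert stats.top_score == 0
        assert stats.coverages == ()

    def test_two_overlapping_hits(self):
        hs = HitSet("g", "B", [self._hit(0, 50), self._hit(25, 75)])
        stats = best_hit_statistics(hs, 100)
        assert stats.coverages == (0.5, 0.5)

    def test_invalid_gene_length(self):
        with pytest.raises(ValueError):
            best_hit_statistics(HitSet("g", "B", []), 0)


def test_scoring_scheme_validation():
    with pytest.raises(ValueError):
        ScoringScheme(match=0)
    with pytest.raises(ValueError):
        ScoringScheme(mismatch=-1)
    with pytest.raises(ValueError):
        ScoringScheme(seed_k=3)


def test_hits_tsv_one_based_inclusive(tmp_path, rng):
    contig = random_seq(rng, 500)
    gene = make_gene(contig[100:200], "g", "A")
    genome = make_genome("B", {"c": contig})
    hs = align_gene_to_genome(gene, genome)
    path = tmp_path / "hits.tsv"
    write_hits_tsv([hs], path)
    header, row = path.read_text().splitlines()[:2]
    fields = dict(zip(header.split("\t"), row.split("\t")))
    assert (fields["qstart"], fields["qend"]) == ("1", "100")
    assert (fields["sstart"], fields["send"]) == ("101", "200")
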
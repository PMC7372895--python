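import numpy as np
import pytest

from fragpan.alignment import AlignmentHit, HitSet
from fragpan.calling import (
    CallThresholds,
    PresenceAbsenceMatrix,
    PresenceCall,
    build_matrix,
    call_presence,
    merged_coverage,
    read_matrix_tsv,
    write_matrix_tsv,
)
from fragpan.genome_io import filter_short_genes
from fragpan.pangenome import cluster_genes
from fragpan.synth import SimParams, simulate_dataset

from conftest import make_gene, make_genome, random_seq
from oracles import coverage_by_occupancy


def hit(q0, q1, identity=1.0, score=100, contig="c", strand="+"):
    return AlignmentHit("g", "B", contig, q0, q1, 0, max(q1 - q0, 1), strand,
                        identity, score)


def hitset(*hits):
    return HitSet("g", "B", list(hits))


class TestMergedCoverage:
    def test_overlapping_union(self):
        hs = hitset(hit(0, 50), hit(25, 75))
        assert merged_coverage(hs, 100, 0.98) == 0.75

    def test_disjoint_union(self):
        hs = hitset(hit(0, 30), hit(60, 90))
        assert merged_coverage(hs, 100, 0.98) == 0.60

    def test_empty(self):
        assert merged_coverage(hitset(), 100, 0.98) == 0.0

    def test_identity_gate_is_per_hit(self):
        hs = hitset(hit(0, 50, identity=0.95), hit(50, 100, identity=0.99))
        assert merged_coverage(hs, 100, 0.98) == 0.5
        assert merged_coverage(hs, 100, 0.90) == 1.0

    def test_random_sets_match_per_base_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            gene_len = int(rng.integers(50, 500))
            n = int(rng.integers(0, 8))
            hits = []
            intervals = []
            for _ in range(n):
                a = int(rng.integers(0, gene_len - 1))
                b = int(rng.integers(a + 1, gene_len + 1))
                hits.append(hit(a, b))
                intervals.append((a, b))
            got = merged_coverage(hitset(*hits), gene_len, 0.5)
            want = coverage_by_occupancy(intervals, gene_len)
            assert got == pytest.approx(want, abs=1e-12)

    def test_invalid_gene_length(self):
        with pytest.raises(ValueError):
            merged_coverage(hitset(), 0, 0.9)


class TestCallPresence:
    def test_rule_a_boundary_inclusive(self):
        call = call_presence(hitset(hit(0, 25, identity=0.98)), 100)
        assert (call.present, call.rule_fired) == (1, "A")

    def test_rule_b_boundary_inclusive(self):
        call = call_presence(hitset(hit(0, 50, identity=0.90)), 100)
        assert (call.present, call.rule_fired) == (1, "B")

    def test_between_rules_absent(self):
        # 49% coverage at 95% identity fails A on coverage... and B on coverage
        call = call_presence(hitset(hit(0, 49, identity=0.95)), 100)
        assert (call.present, call.rule_fired) == (0, "none")

    def test_short_gene_cautionary_example(self):
        # a 100 bp gene with a 25 bp high-identity hit is called present
        # (the reason short genes are filtered by default)
        call = call_presence(hitset(hit(10, 35, identity=0.98)), 100)
        assert call.present == 1
        assert call.rule_fired == "A"

    def test_rule_a_checked_first(self):
        call = call_presence(hitset(hit(0, 60, identity=0.99)), 100)
        assert call.rule_fired == "A"

    def test_split_hits_merge_across_contigs_and_strands(self):
        hs = hitset(
            hit(0, 30, contig="c1", strand="+"),
            hit(30, 55, contig="c2", strand="-"),
        )
        call = call_presence(hs, 100)
        assert call.present == 1
        assert call.merged_coverage_a == 0.55

    def test_monotonicity_under_perturbation(self):
        rng = np.random.default_rng(9)
        thresholds = CallThresholds()
        for _ in range(300):
            gene_len = int(rng.integers(100, 400))
            hits = []
            for _ in range(int(rng.integers(0, 5))):
                a = int(rng.integers(0, gene_len - 20))
                b = int(rng.integers(a + 10, min(a + 200, gene_len) + 1))
                hits.append(hit(a, b, identity=float(rng.uniform(0.85, 1.0))))
            before = call_presence(hitset(*hits), gene_len, thresholds).present
            # grow: add a hit, or raise an identity, or widen an interval
            choice = int(rng.integers(0, 3))
            if choice == 0 or not hits:
                a = int(rng.integers(0, gene_len - 20))
                b = int(rng.integers(a + 10, gene_len + 1))
                hits.append(hit(a, b, identity=float(rng.uniform(0.85, 1.0))))
            elif choice == 1:
                i = int(rng.integers(0, len(hits)))
                h = hits[i]
                hits[i] = hit(h.q_start, h.q_end, identity=min(1.0, h.identity + 0.05))
            else:
                i = int(rng.integers(0, len(hits)))
                h = hits[i]
                hits[i] = hit(max(0, h.q_start - 10), min(gene_len, h.q_end + 10),
                              identity=h.identity)
            after = call_presence(hitset(*hits), gene_len, thresholds).present
            assert after >= before


class TestBuildMatrix:
    def test_identical_genomes_all_ones(self, rng):
        contig = random_seq(rng, 3000)
        genomes = [make_genome(f"G{i}", {"c": contig}) for i in range(3)]
        for g in genomes:
            for j in range(5):
                seq = contig[j * 600 : j * 600 + 400]
                g.genes.append(make_gene(seq, f"g{j}", g.genome_id))
        pan = cluster_genes([gene for g in genomes for gene in g.genes])
        matrix = build_matrix(pan, genomes)
        assert matrix.cells.all()

    def test_deleted_gene_zero_cell(self, rng):
        genes = {f"g{j}": random_seq(rng, 400) for j in range(4)}
        spacer = lambda: random_seq(rng, 100)

        def assemble(gene_ids):
            parts, feats, pos = [], [], 0
            for gid in gene_ids:
                sp = spacer()
                parts.append(sp)
                pos += len(sp)
                parts.append(genes[gid])
                feats.append((gid, pos, pos + len(genes[gid])))
                pos += len(genes[gid])
            return "".join(parts), feats

        built = []
        for i, gene_ids in enumerate([list(genes), list(genes), ["g0", "g1", "g2"]]):
            contig, feats = assemble(gene_ids)
            genome = make_genome(f"G{i}", {"c": contig})
            for gid, a, b in feats:
                genome.genes.append(
                    make_gene(contig[a:b], gid, f"G{i}")
                )
            built.append(genome)
        pan = cluster_genes([gene for g in built for gene in g.genes])
        matrix = build_matrix(pan, built)
        # find the cluster whose representative is g3
        (g3_cluster,) = [cid for cid, rep in matrix.rep_ids.items() if rep == "g3"]
        assert matrix.cell(g3_cluster, "G2") == 0
        assert matrix.cell(g3_cluster, "G0") == 1
        assert matrix.cells.sum() == 4 + 4 + 3

    def test_fewer_than_two_genomes_rejected(self, rng):
        contig = random_seq(rng, 500)
        genome = make_genome("G0", {"c": contig})
        genome.genes.append(make_gene(contig[:300], "g0", "G0"))
        pan = cluster_genes(genome.genes)
        with pytest.raises(ValueError, match="two genomes"):
            build_matrix(pan, [genome])

    def test_self_consistency_on_unfragmented_genomes(self):
        params = SimParams(n_genomes=3, n_genes=12, deletion_count=0,
                           gene_length_range=(300, 900), seed=5)
        genomes, _ledger = simulate_dataset(params)
        all_genes = [g for genome in genomes for g in
                     filter_short_genes(genome.genes, 150)]
        pan = cluster_genes(all_genes)
        matrix = build_matrix(pan, genomes)
        assert matrix.cells.all(), "every gene must be present in its source genome"


class TestMatrixIO:
    def test_round_trip(self, tmp_path):
        cells = np.array([[1, 0], [0, 1], [1, 1]], dtype=np.int8)
        m = PresenceAbsenceMatrix(["a", "b", "c"], ["G1", "G2"], cells)
        path = tmp_path / "matrix.tsv"
        write_matrix_tsv(m, path)
        m2 = read_matrix_tsv(path)
        assert m2.gene_order == m.gene_order
        assert m2.genome_order == m.genome_order
        assert (m2.cells == m.cells).all()

    def test_cell_validation(self):
        with pytest.raises(ValueError):
            PresenceAbsenceMatrix(["a"], ["G1"], np.array([[2]], dtype=np.int8))
        with pytest.raises(ValueError):
            PresenceAbsenceMatrix(["a"], ["G1", "G2"], np.zeros((1, 1), dtype=np.int8))


def test_thresholds_validation():
    with pytest.raises(ValueError):
        CallThresholds(rule_a_coverage=0.6)  # must stay below rule B coverage
    with pytest.raises(ValueError):
        CallThresholds(rule_a_identity=0.85)  # must exceed rule B identity
    with pytest.raises(ValueError):
        CallThresholds(rule_b_coverage=0.0)


def test_presence_call_consistency_enforced():
    with pytest.raises(ValueError):
        PresenceCall("g", "G", 1, "none", 0.0, 0.0)
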
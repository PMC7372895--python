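import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from fragpan.genome_io import AnnotatedGenome, Contig, GeneRecord


def make_gene(
    seq: str,
    gene_id: str = "g1",
    genome_id: str = "G1",
    contig_id: str = "c1",
    strand: str = "+",
) -> GeneRecord:
    return GeneRecord(
        gene_id=gene_id,
        genome_id=genome_id,
        contig_id=contig_id,
        start=0,
        end=len(seq),
        strand=strand,
        sequence=seq,
    )


def make_genome(genome_id: str, contig_seqs: dict[str, str]) -> AnnotatedGenome:
    return AnnotatedGenome(
        genome_id=genome_id,
        contigs={cid: Contig(id=cid, sequence=s) for cid, s in contig_seqs.items()},
    )


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = "ACGT"[(("ACGT".index(out[i])) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_dataset():
    """A small fragmented dataset with deletions and noise, shared across
    test modules to amortize the simulation cost."""
    from fragpan.synth import SimParams, simulate_dataset

    params = SimParams(
        n_genomes=4,
        n_genes=30,
        gene_length_range=(300, 1200),
        deletion_count=6,
        breaks_per_genome=12,
        p_break_in_gene=0.9,
        substitution_rate=0.002,
        seed=7,
    )
    genomes, ledger = simulate_dataset(params)
    return params, genomes, ledger
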
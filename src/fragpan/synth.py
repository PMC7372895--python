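"""Synthetic multi-genome datasets with known deletions and controlled
assembly fragmentation.

An ancestral gene repertoire is generated once; each genome carries the
ancestral genes minus its assigned whole-gene deletions, laid out on
contigs with random intergenic spacers.  Contig breaks then fragment the
assembly: breaks between genes simply split contigs, while breaks inside a
gene either truncate it (a contiguous piece survives at a contig end) or
split it over 2-3 contigs with every piece annotated.  Uniform per-base
substitutions model sequencing/assembly noise.  Every decision is recorded
in a truth ledger, and all randomness flows from a single seeded generator
in a fixed draw order, so outputs are byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from fragpan.genome_io import AnnotatedGenome, Contig, GeneRecord, reverse_complement

_BASES = np.array(list("ACGT"))
_MIN_PIECE = 40  # smallest annotated gene fragment the generator emits


@dataclass(frozen=True)
class SimParams:
    n_genomes: int = 8
    n_genes: int = 500
    gene_length_range: tuple[int, int] = (300, 3000)
    intergenic_length_range: tuple[int, int] = (50, 200)
    deletion_count: int = 49
    breaks_per_genome: int = 0
    p_break_in_gene: float = 0.0
    split_probability: float = 0.5
    max_truncation: float = 0.75
    substitution_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 1 or self.n_genes < 1:
            raise ValueError("n_genomes and n_genes must be >= 1")
        if self.deletion_count < 0 or self.deletion_count > self.n_genomes * self.n_genes:
            raise ValueError("deletion_count out of range")
        for p in (self.p_break_in_gene, self.split_probability, self.substitution_rate):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if not (0.0 <= self.max_truncation < 1.0):
            raise ValueError("max_truncation must be in [0, 1)")
        lo, hi = self.gene_length_range
        if lo < _MIN_PIECE or hi < lo:
            raise ValueError("invalid gene_length_range")
        if round(lo * (1.0 - self.max_truncation)) < 1:
            raise ValueError("max_truncation would leave genes shorter than 1 bp")


@dataclass
class TruthLedger:
    """Ground truth: per (genome, gene) presence plus fragmentation record."""

    gene_ids: list[str]
    genome_ids: list[str]
    # (genome_id, gene_id) -> (status, fragmentation); status "present"/"deleted"
    records: dict[tuple[str, str], tuple[str, str]] = field(default_factory=dict)

    def absences(self) -> set[tuple[str, str]]:
        return {k for k, (status, _f) in self.records.items() if status == "deleted"}

    def is_deleted(self, genome_id: str, gene_id: str) -> bool:
        return self.records[(genome_id, gene_id)][0] == "deleted"

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as out:
            out.write("genome_id\tgene_id\tstatus\tfragmentation\n")
            for gid in self.genome_ids:
                for gene in self.gene_ids:
                    status, frag = self.records[(gid, gene)]
                    out.write(f"{gid}\t{gene}\t{status}\t{frag}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TruthLedger":
        records: dict[tuple[str, str], tuple[str, str]] = {}
        genome_ids: list[str] = []
        gene_ids: list[str] = []
        with open(path) as fh:
            fh.readline()
            for line in fh:
                gid, gene, status, frag = line.rstrip("\n").split("\t")
                records[(gid, gene)] = (status, frag)
                if gid not in genome_ids:
                    genome_ids.append(gid)
                if gene not in gene_ids:
                    gene_ids.append(gene)
        return cls(gene_ids=gene_ids, genome_ids=genome_ids, records=records)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _split_lengths(rng: np.random.Generator, length: int, k: int) -> list[int]:
    """k piece lengths, each >= _MIN_PIECE, summing to length."""
    extra = length - _MIN_PIECE * k
    if extra < 0:
        raise ValueError(f"gene of {length} bp cannot be split into {k} pieces")
    parts = rng.multinomial(extra, [1.0 / k] * k)
    return [_MIN_PIECE + int(p) for p in parts]


def fragment_gene(
    gene: GeneRecord,
    mode: str,
    rng: np.random.Generator,
    fraction: float | None = None,
    pieces: int | None = None,
    max_truncation: float = 0.75,
) -> list[GeneRecord]:
    """Fragment one gene record.

    mode "truncate_f": keep a contiguous (1 - fraction) of the gene (the
    piece the assembler recovered at a contig end); the lost fraction is
    drawn uniformly from (0, max_truncation] when not given.
    mode "split_k": split the full gene into ``pieces`` (2 or 3) annotated
    fragments that concatenate back to the original sequence.
    """
    length = len(gene.sequence)
    if mode == "truncate_f":
        f = fraction if fraction is not None else float(rng.uniform(0.0, max_truncation))
        if f > max_truncation:
            raise ValueError("truncation fraction exceeds max_truncation")
        keep = int(round(length * (1.0 - f)))
        if keep < 1:
            raise ValueError("truncation would leave an empty fragment")
        keep_prefix = bool(rng.integers(0, 2)) if fraction is None else True
        seq = gene.sequence[:keep] if keep_prefix else gene.sequence[length - keep:]
        return [
            GeneRecord(
                gene_id=gene.gene_id,
                genome_id=gene.genome_id,
                contig_id=gene.contig_id,
                start=0,
                end=keep,
                strand=gene.strand,
                sequence=seq,
            )
        ]
    if mode == "split_k":
        k = pieces if pieces is not None else int(rng.integers(2, 4))
        if k not in (2, 3):
            raise ValueError("split_k supports k in {2, 3}")
        lens = _split_lengths(rng, length, k)
        out = []
        offset = 0
        for i, plen in enumerate(lens, start=1):
            out.append(
                GeneRecord(
                    gene_id=f"{gene.gene_id}_p{i}",
                    genome_id=gene.genome_id,
                    contig_id=f"{gene.contig_id}#p{i}",
                    start=0,
                    end=plen,
                    strand=gene.strand,
                    sequence=gene.sequence[offset : offset + plen],
                )
            )
            offset += plen
        return out
    raise ValueError(f"unknown fragmentation mode {mode!r}")


class _ContigBuilder:
    def __init__(self) -> None:
        self.parts: list[str] = []
        self.length = 0
        self.features: list[tuple[str, int, int, str]] = []  # id, start, end, strand

    def add_spacer(self, seq: str) -> None:
        self.parts.append(seq)
        self.length += len(seq)

    def add_feature(self, fid: str, seq: str, strand: str) -> None:
        start = self.length
        self.parts.append(seq)
        self.length += len(seq)
        self.features.append((fid, start, self.length, strand))

    @property
    def empty(self) -> bool:
        return self.length == 0


def _assign_deletions(rng, params: SimParams) -> set[tuple[int, int]]:
    """Deletion pairs, never deleting a gene from every genome."""
    pairs = [(gi, ji) for gi in range(params.n_genes) for ji in range(params.n_genomes)]
    order = rng.permutation(len(pairs))
    per_gene: dict[int, int] = {}
    chosen: set[tuple[int, int]] = set()
    cap = max(params.n_genomes - 1, 1) if params.n_genomes > 1 else 1
    for idx in order:
        if len(chosen) == params.deletion_count:
            break
        gi, ji = pairs[idx]
        if per_gene.get(gi, 0) >= cap:
            continue
        chosen.add((gi, ji))
        per_gene[gi] = per_gene.get(gi, 0) + 1
    if len(chosen) < params.deletion_count:
        raise ValueError("could not place the requested number of deletions")
    return chosen


def simulate_dataset(params: SimParams) -> tuple[list[AnnotatedGenome], TruthLedger]:
    rng = np.random.default_rng(params.seed)

    gene_ids = [f"g{i + 1:05d}" for i in range(params.n_genes)]
    lo, hi = params.gene_length_range
    gene_lengths = rng.integers(lo, hi + 1, size=params.n_genes)
    gene_seqs = [_random_seq(rng, int(L)) for L in gene_lengths]

    deletions = _assign_deletions(rng, params)
    genome_ids = [f"G{j + 1:02d}" for j in range(params.n_genomes)]
    ledger = TruthLedger(gene_ids=list(gene_ids), genome_ids=list(genome_ids))
    genomes: list[AnnotatedGenome] = []

    ig_lo, ig_hi = params.intergenic_length_range

    for ji, genome_id in enumerate(genome_ids):
        present = [gi for gi in range(params.n_genes) if (gi, ji) not in deletions]
        for gi in range(params.n_genes):
            if (gi, ji) in deletions:
                ledger.records[(genome_id, gene_ids[gi])] = ("deleted", "-")

        # decide the fragmentation plan for this genome
        n_in_gene = 0
        n_between = 0
        for _ in range(params.breaks_per_genome):
            if rng.random() < params.p_break_in_gene:
                n_in_gene += 1
            else:
                n_between += 1
        eligible = [
            gi for gi in present
            if gene_lengths[gi] >= max(4 * _MIN_PIECE, 160)
        ]
        n_in_gene = min(n_in_gene, len(eligible))
        frag_sel = rng.choice(len(eligible), size=n_in_gene, replace=False) if n_in_gene else []
        frag_plan: dict[int, tuple[str, float, int, bool]] = {}
        for idx in frag_sel:
            gi = eligible[int(idx)]
            if rng.random() < params.split_probability:
                k = int(rng.integers(2, 4))
                frag_plan[gi] = ("split", 0.0, k, False)
            else:
                f = float(rng.uniform(0.05, params.max_truncation))
                keep_prefix = bool(rng.integers(0, 2))
                frag_plan[gi] = ("truncate", f, 0, keep_prefix)
        between_breaks: set[int] = set()
        if n_between and len(present) > 1:
            pick = rng.choice(len(present) - 1, size=min(n_between, len(present) - 1),
                              replace=False)
            between_breaks = {int(p) for p in pick}

        # lay out genes onto contigs
        contigs: list[_ContigBuilder] = []
        cur = _ContigBuilder()

        def close() -> None:
            nonlocal cur
            if not cur.empty:
                contigs.append(cur)
            cur = _ContigBuilder()

        for order_idx, gi in enumerate(present):
            gene_id = gene_ids[gi]
            seq = gene_seqs[gi]
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            oriented = seq if strand == "+" else reverse_complement(seq)
            cur.add_spacer(_random_seq(rng, int(rng.integers(ig_lo, ig_hi + 1))))
            plan = frag_plan.get(gi)
            if plan is None:
                cur.add_feature(gene_id, oriented, strand)
                ledger.records[(genome_id, gene_id)] = ("present", "intact")
            elif plan[0] == "truncate":
                _mode, f, _k, keep_prefix = plan
                keep = int(round(len(seq) * (1.0 - f)))
                keep = max(keep, _MIN_PIECE)
                piece = seq[:keep] if keep_prefix else seq[len(seq) - keep:]
                oriented_piece = piece if strand == "+" else reverse_complement(piece)
                # the surviving piece sits at a contig edge
                if keep_prefix:
                    cur.add_feature(gene_id, oriented_piece, strand)
                    close()
                else:
                    close()
                    cur.add_feature(gene_id, oriented_piece, strand)
                ledger.records[(genome_id, gene_id)] = (
                    "present", f"truncated:kept={keep / len(seq):.3f}"
                )
            else:  # split
                k = plan[2]
                if len(seq) < _MIN_PIECE * k:
                    k = 2
                lens = _split_lengths(rng, len(seq), k)
                offset = 0
                for pi, plen in enumerate(lens, start=1):
                    piece = seq[offset : offset + plen]
                    offset += plen
                    oriented_piece = piece if strand == "+" else reverse_complement(piece)
                    if pi > 1:
                        close()
                    cur.add_feature(f"{gene_id}_p{pi}", oriented_piece, strand)
                close()
                ledger.records[(genome_id, gene_id)] = ("present", f"split:k={k}")
            if order_idx in between_breaks:
                cur.add_spacer(_random_seq(rng, int(rng.integers(ig_lo, ig_hi + 1))))
                close()
        cur.add_spacer(_random_seq(rng, int(rng.integers(ig_lo, ig_hi + 1))))
        close()

        # apply substitutions and materialize the genome
        genome = AnnotatedGenome(genome_id=genome_id)
        for ci, builder in enumerate(contigs):
            contig_id = f"{genome_id}_c{ci + 1:04d}"
            contig_seq = "".join(builder.parts)
            if params.substitution_rate > 0:
                arr = np.frombuffer(contig_seq.encode("ascii"), dtype=np.uint8).copy()
                mask = rng.random(arr.shape[0]) < params.substitution_rate
                idx = np.nonzero(mask)[0]
                if idx.size:
                    base_map = {65: 0, 67: 1, 71: 2, 84: 3}
                    shifts = rng.integers(1, 4, size=idx.size)
                    for pos, shift in zip(idx, shifts):
                        code = (base_map[arr[pos]] + shift) % 4
                        arr[pos] = ord("ACGT"[code])
                contig_seq = arr.tobytes().decode("ascii")
            genome.contigs[contig_id] = Contig(id=contig_id, sequence=contig_seq)
            for fid, start, end, strand in builder.features:
                piece = contig_seq[start:end]
                genome.genes.append(
                    GeneRecord(
                        gene_id=fid,
                        genome_id=genome_id,
                        contig_id=contig_id,
                        start=start,
                        end=end,
                        strand=strand,
                        sequence=piece if strand == "+" else reverse_complement(piece),
                    )
                )
        genome.validate()
        genomes.append(genome)

    return genomes, ledger


def write_dataset(
    genomes: list[AnnotatedGenome],
    ledger: TruthLedger,
    params: SimParams,
    outdir: str | Path,
) -> None:
    """Write per-genome GFF3 + FASTA, the truth ledger and the parameters."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for genome in genomes:
        fasta = outdir / f"{genome.genome_id}.fna"
        with open(fasta, "w") as out:
            for contig in genome.contigs.values():
                out.write(f">{contig.id}\n")
                for i in range(0, len(contig.sequence), 70):
                    out.write(contig.sequence[i : i + 70] + "\n")
        gff = outdir / f"{genome.genome_id}.gff"
        with open(gff, "w") as out:
            out.write("##gff-version 3\n")
            for g in genome.genes:
                out.write(
                    f"{g.contig_id}\tfragpan_sim\tCDS\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t0\tID={g.gene_id}\n"
                )
    ledger.write_tsv(outdir / "truth.tsv")
    with open(outdir / "params.txt", "w") as out:
        for key, value in asdict(params).items():
            out.write(f"{key}={value}\n")
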
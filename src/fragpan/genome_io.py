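"""Reading annotated assemblies (GFF3 + FASTA) and extracting gene sequences.

Supports two input dialects: a GFF3 file plus a separate contig FASTA, or a
single Prokka-style GFF3 with an embedded ``##FASTA`` section.  Both are
gzip-transparent.  Coordinates are 1-based inclusive on disk and 0-based
half-open internally; minus-strand gene sequences are stored
reverse-complemented (i.e. in reading orientation).
"""

from __future__ import annotations

import gzip
import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

#: GFF3 feature types extracted by default (Prokka's gene-level output).
DEFAULT_FEATURE_TYPES = ("CDS", "rRNA", "tRNA", "tmRNA")

_VALID_BASES = frozenset("ACGTN")
_AMBIG_RE = re.compile(r"[^ACGTN]")


class GFF3ParseError(ValueError):
    """Raised for a malformed GFF3 feature line; carries the line number."""


@dataclass(frozen=True)
class Contig:
    """One assembly fragment."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"contig {self.id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene, with its strand-corrected nucleotide sequence.

    ``start``/``end`` are 0-based half-open offsets on the contig; for
    minus-strand genes ``sequence`` is the reverse complement of the contig
    slice ``[start, end)``.
    """

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    sequence: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        if len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"gene {self.gene_id!r}: sequence length {len(self.sequence)} "
                f"!= interval length {self.end - self.start}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AnnotatedGenome:
    """A genome assembly: contigs plus the genes annotated on them."""

    genome_id: str
    contigs: dict[str, Contig] = field(default_factory=dict)
    genes: list[GeneRecord] = field(default_factory=list)

    def validate(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(
                    f"duplicate gene id {g.gene_id!r} in genome {self.genome_id!r}"
                )
            seen.add(g.gene_id)
            contig = self.contigs.get(g.contig_id)
            if contig is None:
                raise ValueError(
                    f"gene {g.gene_id!r} references unknown contig {g.contig_id!r}"
                )
            if g.end > len(contig):
                raise ValueError(
                    f"gene {g.gene_id!r} end {g.end} exceeds contig "
                    f"{g.contig_id!r} length {len(contig)}"
                )


def _open_text(path: str | Path) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def sanitize_sequence(seq: str, context: str = "") -> str:
    """Uppercase and map ambiguity codes other than N to N (with a warning)."""
    seq = seq.upper().replace("U", "T")
    n_ambig = len(_AMBIG_RE.findall(seq))
    if n_ambig:
        logger.warning(
            "%s: %d ambiguous base(s) mapped to N", context or "sequence", n_ambig
        )
        seq = _AMBIG_RE.sub("N", seq)
    return seq


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


_ID_ATTR_RE = re.compile(r"(?:^|;)ID=([^;]+)")


def _parse_gff_features(handle: io.TextIOBase, path: str) -> tuple[list[tuple], str]:
    """Return (feature tuples, embedded FASTA text).

    Feature tuples are (line_no, seqid, ftype, start1, end1, strand, attrs).
    """
    features: list[tuple] = []
    fasta_lines: list[str] = []
    in_fasta = False
    for line_no, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n")
        if in_fasta:
            fasta_lines.append(line)
            continue
        if line.startswith("##FASTA"):
            in_fasta = True
            continue
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GFF3ParseError(
                f"{path}: line {line_no}: expected 9 tab-separated columns, "
                f"got {len(fields)}"
            )
        seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError:
            raise GFF3ParseError(
                f"{path}: line {line_no}: non-integer coordinates "
                f"{start_s!r}..{end_s!r}"
            ) from None
        if start1 < 1 or end1 < start1:
            raise GFF3ParseError(
                f"{path}: line {line_no}: invalid coordinate range {start1}..{end1}"
            )
        if strand not in ("+", "-", "."):
            raise GFF3ParseError(
                f"{path}: line {line_no}: invalid strand {strand!r}"
            )
        features.append((line_no, seqid, ftype, start1, end1, strand, attrs))
    return features, "\n".join(fasta_lines)


def _read_fasta_text(text: str, label: str) -> dict[str, Contig]:
    contigs: dict[str, Contig] = {}
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        if rec.id in contigs:
            raise ValueError(f"{label}: duplicate contig id {rec.id!r}")
        contigs[rec.id] = Contig(
            id=rec.id, sequence=sanitize_sequence(str(rec.seq), f"contig {rec.id}")
        )
    return contigs


def read_annotated_genome(
    gff_path: str | Path,
    fasta_path: str | Path | None = None,
    genome_id: str | None = None,
    feature_types: Sequence[str] = DEFAULT_FEATURE_TYPES,
) -> AnnotatedGenome:
    """Read a genome from GFF3 (+ optional separate FASTA).

    If ``fasta_path`` is None the GFF3 must carry an embedded ``##FASTA``
    section (Prokka dialect).  Only features whose type is in
    ``feature_types`` become :class:`GeneRecord` entries.  Gene IDs come from
    the GFF3 ``ID`` attribute, falling back to ``genome:contig:start-end``.
    """
    gff_path = Path(gff_path)
    if genome_id is None:
        genome_id = gff_path.name.removesuffix(".gz").removesuffix(".gff3").removesuffix(".gff")

    with _open_text(gff_path) as fh:
        features, embedded_fasta = _parse_gff_features(fh, str(gff_path))

    if fasta_path is not None:
        with _open_text(fasta_path) as fh:
            contigs = _read_fasta_text(fh.read(), str(fasta_path))
    elif embedded_fasta.strip():
        contigs = _read_fasta_text(embedded_fasta, str(gff_path))
    else:
        raise ValueError(
            f"{gff_path}: no FASTA given and no embedded ##FASTA section found"
        )

    wanted = set(feature_types)
    genome = AnnotatedGenome(genome_id=genome_id, contigs=contigs)
    seen_ids: set[str] = set()
    for line_no, seqid, ftype, start1, end1, strand, attrs in features:
        if ftype not in wanted:
            continue
        contig = contigs.get(seqid)
        if contig is None:
            raise ValueError(
                f"{gff_path}: line {line_no}: feature references contig "
                f"{seqid!r} absent from the assembly"
            )
        if end1 > len(contig):
            raise ValueError(
                f"{gff_path}: line {line_no}: feature end {end1} exceeds "
                f"contig {seqid!r} length {len(contig)}"
            )
        start, end = start1 - 1, end1  # to 0-based half-open
        m = _ID_ATTR_RE.search(attrs)
        gene_id = m.group(1) if m else f"{genome_id}:{seqid}:{start}-{end}"
        if gene_id in seen_ids:
            raise ValueError(
                f"{gff_path}: line {line_no}: duplicate gene id {gene_id!r}"
            )
        seen_ids.add(gene_id)
        seq = contig.sequence[start:end]
        if strand == "-":
            seq = reverse_complement(seq)
        genome.genes.append(
            GeneRecord(
                gene_id=gene_id,
                genome_id=genome_id,
                contig_id=seqid,
                start=start,
                end=end,
                strand="-" if strand == "-" else "+",
                sequence=seq,
            )
        )
    genome.validate()
    return genome


def filter_short_genes(
    genes: Iterable[GeneRecord], min_len: int = 150
) -> list[GeneRecord]:
    """Drop genes shorter than ``min_len`` bp (0 disables the filter).

    The boundary is inclusive: a gene of exactly ``min_len`` bp is kept.
    """
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    genes = list(genes)
    kept = [g for g in genes if len(g) >= min_len]
    removed = len(genes) - len(kept)
    if removed:
        logger.info("filtered %d gene(s) shorter than %d bp", removed, min_len)
    return kept


def write_gene_fasta(genes: Iterable[GeneRecord], path: str | Path) -> None:
    """Write extracted genes as multi-FASTA with ``genome_id|gene_id`` headers."""
    with open(path, "w") as out:
        for g in genes:
            out.write(f">{g.genome_id}|{g.gene_id}\n")
            for i in range(0, len(g.sequence), 70):
                out.write(g.sequence[i : i + 70] + "\n")
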
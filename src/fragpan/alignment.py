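"""Seed-and-extend local alignment of pan-genome representatives to genomes.

Each representative is compared against both strands of every contig.
Exact k-mer seeds are grouped into diagonal clusters; each cluster is
resolved by a dynamic-programming local alignment restricted to a window
(and, for large windows, a diagonal band) around the cluster.  Windows
small enough to be cheap are solved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from fragpan._sw import encode, kmer_hashes, seed_boxes, sw_align
from fragpan.genome_io import AnnotatedGenome, GeneRecord, reverse_complement

# seeds whose diagonals differ by more than this found separate clusters
_DIAG_GAP = 30
# seeds further apart than this along the subject found separate clusters
_POS_GAP = 300
# window padding around a seed cluster before DP
_PAD = 120
# extra band margin around the cluster's diagonal range
_BAND_PAD = 50
# windows with at most this many cells are solved with a full (unbanded) DP
_FULL_DP_CELLS = 1 << 20
# chance seed matches against ~Mb of genome are plentiful; demand more
# seeds per cluster for longer queries before spending a window DP.  Any
# genuine hit clearing min_hit_score (>= ~20 matching bases) carries many
# overlapping seeds, so these floors cost no sensitivity.
def _min_seed_count(n_query_kmers: int) -> int:
    if n_query_kmers < 64:
        return 1
    if n_query_kmers < 512:
        return 2
    return 3
# coordinate gap inserted between contigs in the genome-wide seed table so
# seed clusters can never straddle a contig boundary
_CONTIG_GAP = 10_000


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring; penalties are stored as non-negative magnitudes."""

    match: int = 1
    mismatch: int = 2
    gap_open: int = 5
    gap_extend: int = 2
    min_hit_score: int = 20
    seed_k: int = 11

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match reward must be > 0")
        if min(self.mismatch, self.gap_open, self.gap_extend) < 0:
            raise ValueError("penalties must be >= 0")
        if self.seed_k < 4:
            raise ValueError("seed_k must be >= 4")


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment between a representative (query) and a contig."""

    gene_id: str
    genome_id: str
    contig_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    identity: float
    score: int

    def __post_init__(self) -> None:
        if not (0 <= self.q_start < self.q_end):
            raise ValueError("invalid query interval")
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError("identity outside [0, 1]")


@dataclass
class HitSet:
    gene_id: str
    genome_id: str
    hits: list[AlignmentHit] = field(default_factory=list)

    def __iter__(self):
        return iter(self.hits)

    def __len__(self) -> int:
        return len(self.hits)


@dataclass(frozen=True)
class BestHitStats:
    """Summary of a hit set: top identity/score and per-hit query coverage."""

    gene_id: str
    genome_id: str
    n_hits: int
    top_score: int
    top_identity: float | None  # None when there are no hits
    coverages: tuple[float, ...]


class GenomeIndex:
    """Genome-wide sorted k-mer table, built once and reused across queries.

    Contig k-mer positions live in one global coordinate space with a
    ``_CONTIG_GAP`` spacer between contigs, so one vectorised lookup serves
    the whole genome and seed clusters can never span two contigs.
    """

    def __init__(self, genome: AnnotatedGenome, k: int) -> None:
        self.genome_id = genome.genome_id
        self.k = k
        self.contig_ids = sorted(genome.contigs)
        self.contig_codes = [encode(genome.contigs[c].sequence) for c in self.contig_ids]
        starts = []
        offset = 0
        all_hashes = []
        all_positions = []
        for codes in self.contig_codes:
            starts.append(offset)
            hashes = kmer_hashes(codes, k)
            valid = hashes >= 0
            pos = np.nonzero(valid)[0].astype(np.int64) + offset
            all_hashes.append(hashes[valid])
            all_positions.append(pos)
            offset += codes.shape[0] + _CONTIG_GAP
        self.contig_starts = np.asarray(starts, dtype=np.int64)
        hashes = np.concatenate(all_hashes) if all_hashes else np.empty(0, np.int64)
        positions = (
            np.concatenate(all_positions) if all_positions else np.empty(0, np.int64)
        )
        order = np.argsort(hashes, kind="stable")
        self.sorted_hashes = hashes[order]
        self.sorted_positions = positions[order]

    def lookup(self, query_hashes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(query positions, global subject positions) of all seed matches."""
        valid_q = np.nonzero(query_hashes >= 0)[0]
        qh = query_hashes[valid_q]
        left = np.searchsorted(self.sorted_hashes, qh, side="left")
        right = np.searchsorted(self.sorted_hashes, qh, side="right")
        counts = right - left
        nz = np.nonzero(counts)[0]
        hit_q = np.repeat(valid_q[nz], counts[nz])
        total = int(counts[nz].sum())
        hit_s = np.empty(total, dtype=np.int64)
        pos = 0
        for qi in nz:
            lo, hi = left[qi], right[qi]
            hit_s[pos : pos + (hi - lo)] = self.sorted_positions[lo:hi]
            pos += hi - lo
        return hit_q, hit_s

    def contig_of(self, global_pos: int) -> int:
        """Index of the contig containing a global position."""
        return int(np.searchsorted(self.contig_starts, global_pos, side="right")) - 1


def _cluster_seeds(
    hit_q: np.ndarray, hit_s: np.ndarray, min_count: int = 1
) -> list[tuple[int, int, int, int, int, int, int]]:
    """Group seeds into (qlo, qhi, slo, shi, dlo, dhi, count) clusters,
    first splitting on diagonal gaps, then on subject-position gaps."""
    if hit_q.size == 0:
        return []
    diag = hit_s - hit_q
    order = np.lexsort((hit_s, diag))
    boxes = seed_boxes(
        np.ascontiguousarray(hit_q[order]),
        np.ascontiguousarray(hit_s[order]),
        _DIAG_GAP,
        _POS_GAP,
        min_count,
    )
    return [tuple(int(v) for v in row) for row in boxes]


def _align_codes_to_genome(
    q_codes: np.ndarray,
    q_hashes: np.ndarray,
    index: GenomeIndex,
    scoring: ScoringScheme,
) -> list[tuple[int, int, int, int, int, int, float]]:
    """All window alignments of an encoded query against a genome (forward
    strand of every contig).

    Returns (contig idx, score, q_start, q_end, s_start, s_end, identity)
    tuples with contig-local subject coordinates.
    """
    k = scoring.seed_k
    m = q_codes.shape[0]
    min_seeds = _min_seed_count(int((q_hashes >= 0).sum()))
    hit_q, hit_s = index.lookup(q_hashes)
    results = []
    for qlo, qhi, slo, shi, dlo, dhi, _count in _cluster_seeds(
        hit_q, hit_s, min_count=min_seeds
    ):
        ci = index.contig_of(slo)
        c_start = int(index.contig_starts[ci])
        s_codes = index.contig_codes[ci]
        n = s_codes.shape[0]
        w_qlo = max(0, qlo - _PAD)
        w_qhi = min(m, qhi + k + _PAD)
        w_slo = max(0, slo - c_start - _PAD)
        w_shi = min(n, shi - c_start + k + _PAD)
        wq = q_codes[w_qlo:w_qhi]
        ws = s_codes[w_slo:w_shi]
        if wq.shape[0] * ws.shape[0] <= _FULL_DP_CELLS:
            band_lo, band_hi = -wq.shape[0], ws.shape[0]
        else:
            # band around the cluster's diagonals, in window coordinates
            band_lo = (dlo - c_start - (w_slo - w_qlo)) - _BAND_PAD
            band_hi = (dhi - c_start - (w_slo - w_qlo)) + _BAND_PAD
        score, qs, qe, ss, se, n_match, n_cols = sw_align(
            wq,
            ws,
            scoring.match,
            scoring.mismatch,
            scoring.gap_open,
            scoring.gap_extend,
            band_lo,
            band_hi,
        )
        if score < scoring.min_hit_score or n_cols == 0:
            continue
        results.append(
            (
                ci,
                int(score),
                w_qlo + qs,
                w_qlo + qe,
                w_slo + ss,
                w_slo + se,
                n_match / n_cols,
            )
        )
    return results


def best_local_alignment_from_seeds(
    q_codes: np.ndarray,
    s_codes: np.ndarray,
    hit_q: np.ndarray,
    hit_s: np.ndarray,
    scoring: ScoringScheme,
    min_seeds: int = 1,
) -> tuple[int, int, int, int, int, float] | None:
    """Best window alignment given precomputed seed matches.

    Used by the clustering stage, where seeds come from a shared k-mer
    table rather than a per-contig index.  Returns
    (score, q_start, q_end, s_start, s_end, identity) or None.
    """
    m, n = q_codes.shape[0], s_codes.shape[0]
    best = None
    for qlo, qhi, slo, shi, dlo, dhi, _count in _cluster_seeds(
        hit_q, hit_s, min_count=min_seeds
    ):
        w_qlo = max(0, qlo - _PAD)
        w_qhi = min(m, qhi + scoring.seed_k + _PAD)
        w_slo = max(0, slo - _PAD)
        w_shi = min(n, shi + scoring.seed_k + _PAD)
        wq = q_codes[w_qlo:w_qhi]
        ws = s_codes[w_slo:w_shi]
        if wq.shape[0] * ws.shape[0] <= _FULL_DP_CELLS:
            band_lo, band_hi = -wq.shape[0], ws.shape[0]
        else:
            band_lo = (dlo - (w_slo - w_qlo)) - _BAND_PAD
            band_hi = (dhi - (w_slo - w_qlo)) + _BAND_PAD
        score, qs, qe, ss, se, n_match, n_cols = sw_align(
            wq, ws, scoring.match, scoring.mismatch, scoring.gap_open,
            scoring.gap_extend, band_lo, band_hi,
        )
        if n_cols == 0:
            continue
        cand = (
            int(score), w_qlo + qs, w_qlo + qe, w_slo + ss, w_slo + se,
            n_match / n_cols,
        )
        if best is None or cand[0] > best[0]:
            best = cand
    return best


def align_gene_to_genome(
    gene: GeneRecord,
    genome: AnnotatedGenome,
    scoring: ScoringScheme = ScoringScheme(),
    index: GenomeIndex | None = None,
) -> HitSet:
    """Find all local alignments of ``gene`` against both strands of every
    contig of ``genome`` scoring at least ``scoring.min_hit_score``.

    Query intervals are always reported on the forward orientation of the
    gene; minus-strand hits have their subject interval on the forward
    contig and ``strand == '-'``.
    """
    if not gene.sequence:
        raise ValueError("gene sequence must be non-empty")
    if index is None:
        index = GenomeIndex(genome, scoring.seed_k)
    m = len(gene.sequence)
    fwd_codes = encode(gene.sequence)
    rev_codes = encode(reverse_complement(gene.sequence))
    fwd_hashes = kmer_hashes(fwd_codes, scoring.seed_k)
    rev_hashes = kmer_hashes(rev_codes, scoring.seed_k)

    seen: set[tuple] = set()
    hits: list[AlignmentHit] = []
    for strand, codes, hashes in (
        ("+", fwd_codes, fwd_hashes),
        ("-", rev_codes, rev_hashes),
    ):
        for ci, score, qs, qe, ss, se, ident in _align_codes_to_genome(
            codes, hashes, index, scoring
        ):
            cid = index.contig_ids[ci]
            if strand == "-":
                qs, qe = m - qe, m - qs
            key = (cid, strand, qs, qe, ss, se)
            if key in seen:
                continue
            seen.add(key)
            hits.append(
                AlignmentHit(
                    gene_id=gene.gene_id,
                    genome_id=genome.genome_id,
                    contig_id=cid,
                    q_start=qs,
                    q_end=qe,
                    s_start=ss,
                    s_end=se,
                    strand=strand,
                    identity=ident,
                    score=score,
                )
            )
    hits.sort(key=lambda h: (-h.score, h.contig_id, h.strand, h.s_start, h.q_start))
    return HitSet(gene_id=gene.gene_id, genome_id=genome.genome_id, hits=hits)


def best_hit_statistics(hitset: HitSet, gene_length: int) -> BestHitStats:
    """Deterministic summary of a hit set relative to the gene's length."""
    if gene_length <= 0:
        raise ValueError("gene_length must be > 0")
    if not hitset.hits:
        return BestHitStats(
            gene_id=hitset.gene_id,
            genome_id=hitset.genome_id,
            n_hits=0,
            top_score=0,
            top_identity=None,
            coverages=(),
        )
    top = max(hitset.hits, key=lambda h: (h.score, h.identity))
    coverages = tuple((h.q_end - h.q_start) / gene_length for h in hitset.hits)
    return BestHitStats(
        gene_id=hitset.gene_id,
        genome_id=hitset.genome_id,
        n_hits=len(hitset.hits),
        top_score=top.score,
        top_identity=top.identity,
        coverages=coverages,
    )


def write_hits_tsv(hitsets: Iterable[HitSet], path: str | Path) -> None:
    """BLAST outfmt-6-like hit table, 1-based inclusive coordinates."""
    columns = [
        "qseqid",
        "sseqid",
        "pident",
        "length",
        "qstart",
        "qend",
        "sstart",
        "send",
        "score",
        "strand",
    ]
    with open(path, "w") as out:
        out.write("\t".join(columns) + "\n")
        for hs in hitsets:
            for h in hs.hits:
                out.write(
                    "\t".join(
                        [
                            h.gene_id,
                            h.contig_id,
                            f"{h.identity * 100:.2f}",
                            str(h.q_end - h.q_start),
                            str(h.q_start + 1),
                            str(h.q_end),
                            str(h.s_start + 1),
                            str(h.s_end),
                            str(h.score),
                            h.strand,
                        ]
                    )
                    + "\n"
                )
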
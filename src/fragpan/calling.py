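"""Presence/absence calling from alignment hit sets.

A gene is present in a genome when the union of its qualifying alignment
intervals covers enough of the representative: at least 25% coverage at
98% identity (rule A) or 50% coverage at 90% identity (rule B), boundaries
inclusive.  Coverage is measured on the representative's length and merged
across hits — including hits on different contigs and strands — so genes
truncated at contig ends or split across contigs are still recovered.
Identity gating is per hit: a hit contributes to a tier only if its own
identity meets that tier's threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from fragpan.alignment import (
    BestHitStats,
    GenomeIndex,
    HitSet,
    ScoringScheme,
    align_gene_to_genome,
    best_hit_statistics,
)
from fragpan.genome_io import AnnotatedGenome
from fragpan.pangenome import PanGenome

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CallThresholds:
    rule_a_coverage: float = 0.25
    rule_a_identity: float = 0.98
    rule_b_coverage: float = 0.50
    rule_b_identity: float = 0.90

    def __post_init__(self) -> None:
        for name in (
            "rule_a_coverage",
            "rule_a_identity",
            "rule_b_coverage",
            "rule_b_identity",
        ):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")
        if not self.rule_a_coverage < self.rule_b_coverage:
            raise ValueError("rule A coverage must be below rule B coverage")
        if not self.rule_a_identity > self.rule_b_identity:
            raise ValueError("rule A identity must exceed rule B identity")


@dataclass(frozen=True)
class PresenceCall:
    gene_id: str
    genome_id: str
    present: int
    rule_fired: str  # "A", "B", or "none"
    merged_coverage_a: float
    merged_coverage_b: float

    def __post_init__(self) -> None:
        if (self.present == 1) != (self.rule_fired in ("A", "B")):
            raise ValueError("present flag inconsistent with rule_fired")


def merged_coverage(
    hits: HitSet | Sequence, gene_length: int, min_identity: float
) -> float:
    """Fraction of the representative covered by the union of the query
    intervals of hits with identity >= ``min_identity``."""
    if gene_length <= 0:
        raise ValueError("gene_length must be > 0")
    intervals = sorted(
        (h.q_start, h.q_end) for h in hits if h.identity >= min_identity
    )
    covered = 0
    cur_start = cur_end = None
    for start, end in intervals:
        if cur_end is None or start > cur_end:
            if cur_end is not None:
                covered += cur_end - cur_start
            cur_start, cur_end = start, end
        elif end > cur_end:
            cur_end = end
    if cur_end is not None:
        covered += cur_end - cur_start
    return min(covered / gene_length, 1.0)


def call_presence(
    hits: HitSet, gene_length: int, thresholds: CallThresholds = CallThresholds()
) -> PresenceCall:
    """Apply the dual coverage/identity rule (rule A checked first)."""
    cov_a = merged_coverage(hits, gene_length, thresholds.rule_a_identity)
    cov_b = merged_coverage(hits, gene_length, thresholds.rule_b_identity)
    if cov_a >= thresholds.rule_a_coverage:
        rule, present = "A", 1
    elif cov_b >= thresholds.rule_b_coverage:
        rule, present = "B", 1
    else:
        rule, present = "none", 0
    return PresenceCall(
        gene_id=hits.gene_id,
        genome_id=hits.genome_id,
        present=present,
        rule_fired=rule,
        merged_coverage_a=cov_a,
        merged_coverage_b=cov_b,
    )


@dataclass
class PresenceAbsenceMatrix:
    gene_order: list[str]  # cluster ids, pan-genome file order
    genome_order: list[str]  # input order
    cells: np.ndarray  # int8, genes x genomes
    calls: dict[tuple[str, str], PresenceCall] = field(default_factory=dict)
    stats: dict[tuple[str, str], BestHitStats] = field(default_factory=dict)
    rep_ids: dict[str, str] = field(default_factory=dict)  # cluster -> rep gene id

    def __post_init__(self) -> None:
        expected = (len(self.gene_order), len(self.genome_order))
        if tuple(self.cells.shape) != expected:
            raise ValueError(f"cells shape {self.cells.shape} != {expected}")
        if not np.isin(self.cells, (0, 1)).all():
            raise ValueError("matrix cells must be 0/1")

    def cell(self, cluster_id: str, genome_id: str) -> int:
        i = self.gene_order.index(cluster_id)
        j = self.genome_order.index(genome_id)
        return int(self.cells[i, j])


def build_matrix(
    pan: PanGenome,
    genomes: Sequence[AnnotatedGenome],
    thresholds: CallThresholds = CallThresholds(),
    scoring: ScoringScheme = ScoringScheme(),
) -> PresenceAbsenceMatrix:
    """Align every representative to every genome and call presence.

    Rows follow the pan-genome file order (descending representative
    length, then cluster_id); columns follow the genome input order.
    """
    if len(genomes) < 2:
        raise ValueError("at least two genomes required")
    ordered = pan.ordered_clusters()
    gene_order = [c.cluster_id for c in ordered]
    genome_order = [g.genome_id for g in genomes]
    cells = np.zeros((len(ordered), len(genomes)), dtype=np.int8)
    calls: dict[tuple[str, str], PresenceCall] = {}
    stats: dict[tuple[str, str], BestHitStats] = {}
    for j, genome in enumerate(genomes):
        index = GenomeIndex(genome, scoring.seed_k)
        for i, cluster in enumerate(ordered):
            rep = cluster.representative
            hitset = align_gene_to_genome(rep, genome, scoring, index=index)
            # presence is keyed by cluster, not by the representative's id
            hitset = HitSet(
                gene_id=cluster.cluster_id, genome_id=genome.genome_id, hits=hitset.hits
            )
            call = call_presence(hitset, len(rep.sequence), thresholds)
            cells[i, j] = call.present
            key = (cluster.cluster_id, genome.genome_id)
            calls[key] = call
            stats[key] = best_hit_statistics(hitset, len(rep.sequence))
        logger.info("called %s: %d/%d present", genome.genome_id,
                    int(cells[:, j].sum()), len(ordered))
    return PresenceAbsenceMatrix(
        gene_order=gene_order, genome_order=genome_order, cells=cells,
        calls=calls, stats=stats,
        rep_ids={c.cluster_id: c.representative.gene_id for c in ordered},
    )


def write_matrix_tsv(matrix: PresenceAbsenceMatrix, path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("gene\t" + "\t".join(matrix.genome_order) + "\n")
        for i, cid in enumerate(matrix.gene_order):
            row = "\t".join(str(int(v)) for v in matrix.cells[i])
            out.write(f"{cid}\t{row}\n")


def read_matrix_tsv(path: str | Path) -> PresenceAbsenceMatrix:
    gene_order: list[str] = []
    rows: list[list[int]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        genome_order = header[1:]
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            gene_order.append(fields[0])
            rows.append([int(v) for v in fields[1:]])
    return PresenceAbsenceMatrix(
        gene_order=gene_order,
        genome_order=genome_order,
        cells=np.array(rows, dtype=np.int8).reshape(len(gene_order), len(genome_order)),
    )


def write_stats_tsv(matrix: PresenceAbsenceMatrix, path: str | Path) -> None:
    """Per-(gene, genome) best-alignment statistics."""
    with open(path, "w") as out:
        out.write(
            "gene\tgenome\tpresent\trule\tcoverage_a\tcoverage_b\t"
            "n_hits\ttop_score\ttop_identity\n"
        )
        for cid in matrix.gene_order:
            for gid in matrix.genome_order:
                call = matrix.calls[(cid, gid)]
                st = matrix.stats[(cid, gid)]
                ident = "NA" if st.top_identity is None else f"{st.top_identity:.4f}"
                out.write(
                    f"{cid}\t{gid}\t{call.present}\t{call.rule_fired}\t"
                    f"{call.merged_coverage_a:.4f}\t{call.merged_coverage_b:.4f}\t"
                    f"{st.n_hits}\t{st.top_score}\t{ident}\n"
                )
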
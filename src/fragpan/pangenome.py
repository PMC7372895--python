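"""Greedy longest-first clustering of genes into a pan-genome.

Genes from all genomes are sorted by length (descending, ties broken by
(genome_id, gene_id) for determinism) and assigned first-fit: a gene joins
the earliest-founded cluster whose representative it matches at
``identity_threshold`` identity over ``member_coverage_threshold`` of the
gene's own (shorter) length, otherwise it founds a new cluster.  The
founder of each cluster is its longest member and serves as the
representative.  A shared k-mer (k = 11) seed table shortlists candidate
clusters; the decision is a dynamic-programming alignment in a window
around the seeds (exact full DP whenever the pair is small).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from fragpan._sw import encode, kmer_hashes, sw_align
from fragpan.alignment import (
    ScoringScheme,
    _min_seed_count,
    best_local_alignment_from_seeds,
)
from fragpan.genome_io import GeneRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusterParams:
    identity_threshold: float = 0.90
    member_coverage_threshold: float = 0.80

    def __post_init__(self) -> None:
        for name in ("identity_threshold", "member_coverage_threshold"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass
class GeneCluster:
    cluster_id: str
    representative: GeneRecord
    members: list[GeneRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class PanGenome:
    clusters: list[GeneCluster]
    params: ClusterParams

    def __len__(self) -> int:
        return len(self.clusters)

    def ordered_clusters(self) -> list[GeneCluster]:
        """Deterministic output order: longest representative first."""
        return sorted(
            self.clusters,
            key=lambda c: (-len(c.representative.sequence), c.cluster_id),
        )


def member_matches_representative(
    member_seq: str,
    rep_seq: str,
    params: ClusterParams,
    scoring: ScoringScheme = ScoringScheme(),
) -> bool:
    """Alignment-based membership test.

    The best local alignment must reach ``identity_threshold`` identity and
    span at least ``member_coverage_threshold`` of the member's length.
    Clustering happens on the annotated strand only.
    """
    q = encode(member_seq)
    s = encode(rep_seq)
    score, qs, qe, _ss, _se, n_match, n_cols = sw_align(
        q, s, scoring.match, scoring.mismatch, scoring.gap_open,
        scoring.gap_extend, -q.shape[0], s.shape[0],
    )
    if n_cols == 0:
        return False
    identity = n_match / n_cols
    coverage = (qe - qs) / len(member_seq)
    return identity >= params.identity_threshold and coverage >= params.member_coverage_threshold


def _sort_key(gene: GeneRecord):
    return (-len(gene.sequence), gene.genome_id, gene.gene_id)


def _decide_membership(
    member_codes: np.ndarray,
    rep_codes: np.ndarray,
    seed_q: np.ndarray,
    seed_s: np.ndarray,
    params: ClusterParams,
    scoring: ScoringScheme,
    min_seeds: int = 1,
) -> bool:
    best = best_local_alignment_from_seeds(
        member_codes, rep_codes, seed_q, seed_s, scoring, min_seeds=min_seeds
    )
    if best is None:
        return False
    _score, qs, qe, _ss, _se, identity = best
    coverage = (qe - qs) / member_codes.shape[0]
    return (
        identity >= params.identity_threshold
        and coverage >= params.member_coverage_threshold
    )


def cluster_genes(
    genes: Iterable[GeneRecord],
    params: ClusterParams = ClusterParams(),
    scoring: ScoringScheme = ScoringScheme(),
) -> PanGenome:
    """Greedy longest-first, first-fit clustering of all genes."""
    genes = sorted(genes, key=_sort_key)
    if not genes:
        raise ValueError("no genes to cluster")

    clusters: list[GeneCluster] = []
    rep_codes: list[np.ndarray] = []
    # k-mer hash -> [(founding-order cluster idx, rep position), ...]
    seed_table: dict[int, list[tuple[int, int]]] = {}

    for gene in genes:
        codes = encode(gene.sequence)
        hashes = kmer_hashes(codes, scoring.seed_k)
        # gather seed matches against every representative in one pass
        cand_q: dict[int, list[int]] = {}
        cand_s: dict[int, list[int]] = {}
        for pos in range(hashes.shape[0]):
            h = hashes[pos]
            if h < 0:
                continue
            entries = seed_table.get(int(h))
            if not entries:
                continue
            for ci, spos in entries:
                cand_q.setdefault(ci, []).append(pos)
                cand_s.setdefault(ci, []).append(spos)
        # chance seed sharing with unrelated representatives is common for
        # long genes; any genuine >=80%-coverage match carries many seeds
        min_seeds = _min_seed_count(int((hashes >= 0).sum()))
        assigned = False
        for ci in sorted(cand_q):  # first-fit in founding order
            if len(cand_q[ci]) < min_seeds:
                continue
            if _decide_membership(
                codes,
                rep_codes[ci],
                np.asarray(cand_q[ci], dtype=np.int64),
                np.asarray(cand_s[ci], dtype=np.int64),
                params,
                scoring,
                min_seeds=min_seeds,
            ):
                clusters[ci].members.append(gene)
                assigned = True
                break
        if not assigned:
            ci = len(clusters)
            clusters.append(
                GeneCluster(cluster_id=f"C{ci + 1:05d}", representative=gene, members=[gene])
            )
            rep_codes.append(codes)
            for pos in range(hashes.shape[0]):
                h = hashes[pos]
                if h >= 0:
                    seed_table.setdefault(int(h), []).append((ci, pos))

    logger.info("clustered %d genes into %d clusters", len(genes), len(clusters))
    return PanGenome(clusters=clusters, params=params)


def write_pangenome(pan: PanGenome, path: str | Path) -> None:
    """Representative multi-FASTA, one record per cluster.

    Header: ``cluster_id members=N representative=genome|gene``; order is
    descending representative length, then cluster_id.
    """
    if not pan.clusters:
        raise ValueError("empty pan-genome")
    with open(path, "w") as out:
        for cluster in pan.ordered_clusters():
            rep = cluster.representative
            out.write(
                f">{cluster.cluster_id} members={len(cluster.members)} "
                f"representative={rep.genome_id}|{rep.gene_id}\n"
            )
            for i in range(0, len(rep.sequence), 70):
                out.write(rep.sequence[i : i + 70] + "\n")


def write_membership_tsv(pan: PanGenome, path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("cluster_id\trepresentative_id\tmembers\n")
        for cluster in pan.ordered_clusters():
            rep = cluster.representative
            members = ",".join(
                f"{m.genome_id}|{m.gene_id}"
                for m in sorted(cluster.members, key=lambda m: (m.genome_id, m.gene_id))
            )
            out.write(
                f"{cluster.cluster_id}\t{rep.genome_id}|{rep.gene_id}\t{members}\n"
            )
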
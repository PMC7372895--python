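"""Scoring presence-absence calls against a truth ledger.

Absence is the positive class: TP = correctly called absent, FP = called
absent but truly present, FN = called present but truly absent.  Counts
are restricted to genes that show variation across genomes (in truth or in
the calls); rows uniformly present-and-called-present or uniformly
absent-and-called-absent are excluded.

Precision and recall use the conventional orientation (precision =
TP/(TP+FP), recall = TP/(TP+FN)); a literal-formula variant with the two
denominators swapped is available behind ``literal_formulas=True``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

from fragpan.calling import PresenceAbsenceMatrix
from fragpan.synth import TruthLedger

_PIECE_RE = re.compile(r"_p\d+$")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be >= 0")


@dataclass(frozen=True)
class Scores:
    precision: float | None
    recall: float | None
    f1: float | None


def base_gene_id(gene_id: str) -> str:
    """Strip a split-piece suffix (``_pN``) from a gene id."""
    return _PIECE_RE.sub("", gene_id)


def cluster_gene_map(pan, truth: TruthLedger) -> dict[str, str]:
    """Map cluster_id -> ledger gene id via the representative's id.

    Raises if any cluster's representative cannot be resolved.
    """
    known = set(truth.gene_ids)
    mapping: dict[str, str] = {}
    unresolved: list[str] = []
    for cluster in pan.ordered_clusters():
        base = base_gene_id(cluster.representative.gene_id)
        if base in known:
            mapping[cluster.cluster_id] = base
        else:
            unresolved.append(cluster.cluster_id)
    if unresolved:
        raise ValueError(
            "clusters with unresolvable gene mapping: " + ", ".join(unresolved)
        )
    return mapping


def score_calls(
    matrix: PresenceAbsenceMatrix,
    truth: TruthLedger,
    gene_map: dict[str, str] | None = None,
) -> ConfusionCounts:
    """Confusion counts of absence calls against the ledger.

    ``gene_map`` maps matrix rows (cluster ids) to ledger gene ids; when
    None, the matrix's own cluster->representative mapping is used if set,
    otherwise the row names themselves (after stripping piece suffixes)
    must be ledger gene ids.  Several rows may map to one gene (e.g.
    unmerged fragments); the gene is called present in a genome if any of
    its rows is present there.
    """
    if set(matrix.genome_order) != set(truth.genome_ids):
        raise ValueError("matrix and truth ledger cover different genomes")
    if gene_map is None and getattr(matrix, "rep_ids", None):
        gene_map = {cid: base_gene_id(rep) for cid, rep in matrix.rep_ids.items()}
    known = set(truth.gene_ids)
    unresolved = []
    per_gene_rows: dict[str, list[int]] = {}
    for i, row_name in enumerate(matrix.gene_order):
        gene = gene_map.get(row_name) if gene_map is not None else base_gene_id(row_name)
        if gene is None or gene not in known:
            unresolved.append(row_name)
            continue
        per_gene_rows.setdefault(gene, []).append(i)
    if unresolved:
        raise ValueError(
            "clusters with unresolvable gene mapping: " + ", ".join(unresolved)
        )

    tp = fp = fn = 0
    genome_cols = [matrix.genome_order.index(g) for g in truth.genome_ids]
    for gene in truth.gene_ids:
        rows = per_gene_rows.get(gene)
        truth_absent = [truth.is_deleted(g, gene) for g in truth.genome_ids]
        if rows is None:
            call_absent = [True] * len(truth.genome_ids)
        else:
            call_absent = [
                not any(matrix.cells[r, c] for r in rows) for c in genome_cols
            ]
        # only genes showing variation (in truth or calls) are counted
        if not any(truth_absent) and not any(call_absent):
            continue
        if all(truth_absent) and all(call_absent):
            continue
        for t, c in zip(truth_absent, call_absent):
            if c and t:
                tp += 1
            elif c and not t:
                fp += 1
            elif t and not c:
                fn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn)


def precision_recall_f1(
    counts: ConfusionCounts, literal_formulas: bool = False
) -> Scores:
    """Precision/recall/F1 of absence calls.

    The conventional orientation reproduces the published summary values
    from the published counts; ``literal_formulas`` swaps the two
    denominators instead.  Undefined ratios (zero denominator) are None.
    """
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    if literal_formulas:
        recall = tp / (tp + fp) if tp + fp else None
        precision = tp / (tp + fn) if tp + fn else None
    else:
        precision = tp / (tp + fp) if tp + fp else None
        recall = tp / (tp + fn) if tp + fn else None
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return Scores(precision=precision, recall=recall, f1=f1)


def display_round(value: float | None, ndigits: int = 2) -> float | None:
    """Half-up decimal rounding for report display."""
    if value is None:
        return None
    quant = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quant, rounding=ROUND_HALF_UP))


def write_scores_tsv(
    rows: list[tuple[str, ConfusionCounts, Scores]], path: str | Path
) -> None:
    with open(path, "w") as out:
        out.write("label\ttp\tfp\tfn\tprecision\trecall\tf1\n")
        for label, counts, scores in rows:
            def fmt(v: float | None) -> str:
                return "NA" if v is None else f"{display_round(v):.2f}"
            out.write(
                f"{label}\t{counts.tp}\t{counts.fp}\t{counts.fn}\t"
                f"{fmt(scores.precision)}\t{fmt(scores.recall)}\t{fmt(scores.f1)}\n"
            )
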
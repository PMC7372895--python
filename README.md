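# fragpan

Gene presence-absence calling across closely related bacterial genomes whose
assemblies are fragmented. Draft assemblies truncate genes at contig ends and
split them across contigs; naive pan-genome tools then call those genes
absent. `fragpan` compensates: it clusters all annotated genes into a
pan-genome of representatives, locally aligns every representative back to
every assembly, merges alignment intervals across contigs and strands, and
calls a gene present if the merged coverage of the representative reaches
**25% at 98% identity** or **50% at 90% identity** (boundaries inclusive).

## What's in the box

| module | role |
| --- | --- |
| `fragpan.genome_io` | GFF3 + FASTA reading (separate files or Prokka-style embedded `##FASTA`, gzip-transparent), strand-correct gene extraction, short-gene filter (default 150 bp) |
| `fragpan.pangenome` | greedy longest-first clustering (90% identity over 80% of the member's length); longest member is the representative |
| `fragpan.alignment` | seed-and-extend local alignment (k-mer seeds, affine-gap Smith-Waterman windows, numba), both strands, BLAST-outfmt6-like hit tables |
| `fragpan.calling` | interval-merged dual coverage/identity presence rule; presence-absence matrix + per-cell best-alignment statistics |
| `fragpan.phylo` | Jaccard/Hamming gene-content distances, neighbor joining, Newick output, CFN fixed-topology log-likelihood |
| `fragpan.synth` | synthetic multi-genome datasets with known deletions, contig breaks, gene truncation/splitting, substitution noise, and a truth ledger |
| `fragpan.bench` | precision/recall/F1 of absence calls against a truth ledger (absence is the positive class) |
| `fragpan.pipeline` / `fragpan.cli` | end-to-end orchestration, deterministic outputs, `fragpan` console command |

## CLI

```sh
# simulate a fragmented 8-genome dataset with 49 known deletions
fragpan simulate --out data/ --genomes 8 --genes 500 --deletions 49 \
    --breaks 180 --p-break-in-gene 0.95 --substitution-rate 0.0025 --seed 1

# run the pipeline on a directory of GFF3(+FASTA) genomes
fragpan call --gff data/ --out run/ \
    [--min-gene-length 150] [--cluster-identity 0.90] [--cluster-coverage 0.80] \
    [--rule-a 0.25:0.98] [--rule-b 0.50:0.90]

# score the matrix against the simulator's truth ledger
fragpan score --matrix run/matrix.tsv --truth data/truth.tsv \
    --clusters run/clusters.tsv --out scores.tsv

# neighbor-joining gene-content tree
fragpan tree --matrix run/matrix.tsv --out tree.nwk
```

`fragpan call` writes `pangenome.fasta`, `clusters.tsv`, `matrix.tsv`
(genes × genomes, 1/0), `alignment_stats.tsv`, `distances.tsv`, `tree.nwk`
(3+ genomes), `config.txt` and `run.log`. Reruns with the same inputs are
byte-identical.

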
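# plastophylo

A toolkit for plastome (chloroplast genome) phylogenomics:

- **seqio** — FASTA/FASTQ/GenBank and a minimal JSON annotation dialect;
  CDS peptide extraction (plastid codon table 11, minus-strand joins),
  GC content, FASTQ subsetting and statistics.
- **orthofilter** — pre-clustering peptide trimming (exact duplicates
  within a species, `*`-containing sequences, short sequences) and the
  four-step orthogroup cleaning: (1) gene-tree pendant-branch outlier
  removal by the 1.5·IQR fence, (2) linked-presence filtering for
  species/reference pairs, (3) an outgroup-count species threshold with
  an exemption for outgroup-only groups, (4) longest-per-species paralog
  dedupe.
- **supermatrix** — deterministic center-star alignment (BLOSUM62,
  affine gaps) or a pluggable external aligner, concatenation with
  partitions, neighbor-joining trees on p-distances with bootstrap
  support, and relaxed PHYLIP/NEXUS export for external ML inference.
- **polish** — homopolymer frameshift detection in a draft assembly and
  read-support-gated correction: a run is corrected to the
  best-supported alternative length only when backed by at least 10
  spanning reads making up more than a quarter of the spanning coverage.
- **seqplan** — sequencing-requirement arithmetic
  (`size × coverage / plastid_fraction`).
- **synthdata** — deterministic synthetic fixtures with ground truth:
  peptides evolved down a species tree (with planted paralogs, losses
  and long-branch outliers) and a draft plastome with planted
  homopolymer indels plus simulated read alignments (SAM).
- **pipeline** — one-command orchestration with a reconciling report.

## CLI

```sh
plastophylo plan --size 160000 --coverage 50 --fraction 0.03
plastophylo gc assembly.fasta
plastophylo extract-peptides annotation.json --species Csub --out peptides.fasta
plastophylo subset-fastq reads.fastq --ids ids.txt --out subset.fastq
plastophylo fastq-stats subset.fastq --total-of reads.fastq
plastophylo pretrim peptides.fasta --out trimmed.fasta
plastophylo filter-ogs --table orthogroups.tsv --fasta trimmed.fasta \
    --tree-dir trees/ --outgroup outgroup --linked interest,reference \
    --out cleaned.tsv
plastophylo align og.fasta --out og.aln.fasta
plastophylo concat og1.aln.fasta og2.aln.fasta --outdir ml/
plastophylo nj ml/supermatrix.phy --bootstrap 100 --seed 1
plastophylo polish --assembly draft.fasta --reads-aln reads.sam \
    --out polished.fasta --report decisions.tsv
plastophylo simulate --seed 1 --n-genes 20 --outdir fixture/ --plastome
plastophylo run pipeline.toml
```

`plastophylo run` takes a TOML config naming `peptides_dir` (one FASTA
per species), optional `orthogroup_table`/`tree_dir`, the
`species_of_interest`, `linked_groups` and `outgroup` roles, and
built-in/bootstrap settings; see `tests/test_pipeline.py` for a working
example.

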
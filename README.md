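# trnakit

Analysis toolkit for tRNA gene repertoires and their expression dynamics:

- **decoding-potential graph** — a directed graph over the 61 sense
  anticodons whose wobble-labelled arcs (G:U, U:G, I:C, I:A; anticodon base
  first) record which anticodon can substitute for another during
  translation, with existing/missing repertoire flags, compensation queries
  and arc-grouped copy-number/codon-usage correlation;
- **repertoire** — tRNA gene-prediction (tRNAscan-SE-style tabular) parsing,
  mature-sequence extraction with intron removal, isodecoder clustering with
  artificial references (10 nt 5' flank + mature + CCA), repertoire
  summaries, and a seeded Monte-Carlo multivariate hypergeometric test of
  chromosomal isotype localization;
- **codon usage** — pooled in-frame codon counting from CDS FASTA and
  Pearson correlation reports at isotype / isoacceptor / graph-grouped /
  per-wobble-type levels;
- **accessibility** — full-embedding classification of genes in
  open-chromatin peaks (BED3+) per stage, with constitutive / stage-specific /
  partial / never categories and union/intersection stage-combination counts;
- **lotte_quant** — genome hard-masking, 8/22 nt read-length routing, SAM
  alignment validation against cluster references (unique mapping, past the
  flank, CCA 3' end, alignment reaching the reference 3' end), cluster
  counting and aggregation to isoacceptor/isotype;
- **diffexp** — a lightweight negative-binomial differential-expression
  stage (TMM-anchored scaling, method-of-moments dispersion with shrinkage,
  exact-style conditional test, Holm correction, signed calls) plus
  per-transition up/down/unchanged reports;
- **synthetic_data** — seeded generators for every input above with planted
  ground truth (genomes with isotype skew, wobble-skewed CDS, peak sets with
  known availability categories, labelled alignment records, NB count
  matrices with planted fold changes including the opposite-sign-isodecoder
  construction).

## CLI

The `trnakit` entry point exposes one subcommand group per stage:

```bash
trnakit simulate --seed 1 --out sim/          # synthetic inputs + truth/
trnakit graph build --out edges.tsv
trnakit graph correlate --copies sim/copies.tsv --usage usage.tsv --mode per_arc
trnakit repertoire summarize --trnascan sim/trnascan.tsv --genome sim/genome.fasta
trnakit repertoire chromtest --trnascan sim/trnascan.tsv --draws 10000 --seed 7
trnakit usage count --cds sim/cds.fasta --out usage.tsv
trnakit access classify --genes sim/trnascan.tsv \
    --stage vegetative=sim/peaks_vegetative.bed --stage streaming=sim/peaks_streaming.bed \
    --stage mound=sim/peaks_mound.bed --stage fruiting=sim/peaks_fruiting.bed \
    --out avail.tsv
trnakit lotte refs --trnascan sim/trnascan.tsv --genome sim/genome.fasta --out refs.fasta
trnakit lotte count --sam sim/reads.sam --trnascan sim/trnascan.tsv \
    --genome sim/genome.fasta --out counts.tsv
trnakit de run --counts sim/counts.tsv --design sim/design.tsv \
    --contrast vegetative:streaming --out de.tsv
```

## Conventions

- Codons and anticodons are DNA strings 5'→3'; inosine is the genomically
  encoded A34.  Cognate codon = reverse complement of the anticodon.
- TGA is a stop (selenocysteine excluded); stop-codon anticodons are never
  graph vertices.
- Gene coordinates are 1-based inclusive internally (predictor dialect);
  BED I/O is 0-based half-open at the boundary.
- All Monte-Carlo and simulation entry points require an explicit seed and
  are byte-reproducible.
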
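# cd45iso

Per-cell quantification of alternatively spliced **PTPRC/CD45 isoform
features** directly from barcoded 5' single-cell RNA-seq alignments.

CD45, the pan-leukocyte phosphatase encoded by *PTPRC*, is alternatively
spliced at exons 4, 5 and 6 (protein domains A, B, C), producing isoforms
such as CD45RABC (all three included) and CD45RO (all three skipped) that
distinguish naive from memory/effector lymphocytes. Standard scRNA-seq
pipelines count whole-gene expression and discard this splicing signal;
recovering it otherwise requires CITE-seq with isoform-specific antibodies
and an extra sequencing library. `cd45iso` extracts the signal that is
already present in a 10x Cell Ranger BAM: because the alternative exons lie
near the 5' end of the transcript, 5' gene-expression libraries contain
reads that overlap exon 4/5/6 or span the exon 3–exon 7 junction, and those
reads identify the features **RA**, **RB**, **RC** and **RO** per cell.

## Method

1. **Discriminating reference.** For each feature (alternative exon or the
   3–7 junction), every admissible flanking exon chain is enumerated from
   *transcript building rules* (an exon adjacency: which exon may follow
   which). Each chain combination yields one reference sequence: the feature
   surrounded by flanks truncated to `R − k` bases, where `R` is the read
   length and `k` the minimum required overlap. Any length-`R` read that maps
   fully inside such a sequence must overlap the feature by at least `k`
   bases — so mapping to the reference certifies feature presence.
2. **Classification.** Reads overlapping the locus are classified by
   co-linear k-mer matching (both strands, default `k = 21`, minimum matched
   fraction 0.7) against the reference; hits collapse to the feature level.
   An independent CIGAR-walking classifier on genomic coordinates serves as
   an oracle in the test suite.
3. **Counting.** Reads are collapsed by (cell barcode, UMI). Each molecule
   contributes total weight 1, split equally over the union of its reads'
   features (a molecule matching *n* features adds 1/*n* to each). Columns
   are a barcode whitelist, or the top-N barcodes by weight (`N = 3000` by
   default). Output is a 10x-style MatrixMarket bundle.
4. **Saturation.** Subsampling the alignment on a 5%…100% grid (step 5) and
   re-quantifying gives estimator values `Y` (fraction of positive cells, or
   mean log2-normalized count) against mean reads per cell `X`, fitted with
   the rational model `Y = aX/(b + X)`: `a` is the plateau, `b` the depth at
   half-maximal performance.

## Worked example

Everything runs on a synthetic fixture, so no download is needed:

```bash
cd45iso simulate --out-dir fixture --n-cells 8 --seed 13 --informative-overlap 1
cd45iso run --bam fixture/reads.sam --gtf fixture/annotation.gtf \
    --genome fixture/genome.fa --gene-id PTPRC_TOY \
    --whitelist fixture/whitelist.txt --min-kmer-frac 1.0 \
    --no-gzip --out-dir matrix
```

which logs

```
INFO cd45iso: extracted 150 reads overlapping chrS:201-4272
INFO cd45iso: assigned weight 53.0 UMIs; 8 cells with any isoform count
INFO cd45iso: wrote matrix bundle to matrix
```

and writes `matrix/matrix.mtx` whose first entries are

```
%%MatrixMarket matrix coordinate real general
%
4 8 12
1 1 2.6666666666666665
2 1 2.6666666666666665
3 1 2.6666666666666665
```

Cell 1 was simulated with 8 CD45RABC molecules: each molecule's weight of 1
splits over {RA, RB, RC}, giving 8/3 ≈ 2.67 per feature — the matrix
reproduces the simulation's truth table exactly. A saturation run on the
same fixture:

```bash
cd45iso saturation --bam fixture/reads.sam --gtf fixture/annotation.gtf \
    --genome fixture/genome.fa --gene-id PTPRC_TOY \
    --whitelist fixture/whitelist.txt --feature RA --min-kmer-frac 1.0 \
    --fractions 0.25,0.5,0.75,1.0 --out-csv sat.csv
# a=0.591625  b=2.61216  rss=0.00177602  converged=True
```

Half the simulated cells carry an RA-containing isoform, so the fraction of
RA-positive cells saturates at 0.5; from only four subsampling points the
fit extrapolates a plateau `a ≈ 0.59` slightly above it, with half-maximal
detection at `b ≈ 2.6` uniquely mapped reads per cell.

The library API mirrors the CLI: `parse_gtf_exons` / `attach_sequences`
build the exon model, `build_reference` + `build_index` the classifier,
`extract_locus_reads` + `quantify_records` the counts, and `fit_rational`
the saturation fit.

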
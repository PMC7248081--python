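# Replicating the full-scale human analysis (optional protocol)

The desk-scale test suite validates the estimator, island scorer and
classifier against simulated ground truth.  Applying the pipeline to real
human WGS data requires external (partly controlled-access) inputs and is
not run here; this protocol documents how to do it and what to expect.

## Inputs

1. **Aligned WGS reads** (BAM), e.g. Covaris-sheared whole-genome samples
   from the 1000 Genomes project phase-3 FTP
   (`ftp://ftp.1000genomes.ebi.ac.uk/vol1/ftp/phase3/data/`), aligned to
   GRCh37.
2. **Reference genome** GRCh37 (FASTA), matching the BAM alignment target.
3. **CpG-island intervals** (BED), e.g. the UCSC cpgIslandExt track for hg19.
4. **Low-complexity mask** (BED) derived from RepeatMasker annotations for
   GRCh37.
5. **Bisulfite methylation maps** for a matched cell type, e.g.
   lymphoblastoid maps from NGSmethDB
   (`https://bioinfo2.ugr.es/NGSmethDB/methylation-maps/`), converted to the
   4-column call TSV (contig, 1-based C position, coverage, methylated count).
6. For the classifier: tumor and matched-normal WGS cohorts (e.g. EGA/ICGC
   cohorts; controlled access) with sample labels.

## Protocol

```bash
# 1. per-dinucleotide cleavage rates for one sample
#    (filtering equivalent to: samtools view -f 35 -F 4 sample.bam {1..22})
cleavescan rates \
    --genome GRCh37.fa --events sample.bam --sam \
    --methylation lymphoblastoid_calls.tsv \
    --mask repeatmasker_low_complexity.bed \
    --out sample.rates.tsv

# 2. island scores per sample (tumor and normal cohorts)
cleavescan islands \
    --genome GRCh37.fa --events sample.bam --sam \
    --islands cpg_islands.bed --mask repeatmasker_low_complexity.bed \
    --out sample.islands.tsv

# 3. feature matrix, jack-knife evaluation, island ranking
cleavescan matrix --scores *.islands.tsv --labels labels.tsv --out matrix.tsv
cleavescan evaluate --matrix matrix.tsv --labels labels.tsv \
    --rounds 100 --seed 1 --out eval.json
cleavescan rank --matrix matrix.tsv --labels labels.tsv -k 20 --out rank.tsv
```

Only the island-score TSVs (step 2) need to be shared between sites; they
contain no sequence-level data, which eases use on controlled-access
cohorts.

## Expected outcomes

* In the 18-class rate table of step 1, r(CmG) should be the largest rate
  of all classes and approximately 1.5 x r(CuG): methylated CpGs cleave
  about 1.5 times more readily than unmethylated ones.
* Tumor cohorts should show predominantly *lower* island CpG cleavage
  rates than matched normals (island demethylation), visible as negative
  signed differences in the `rank` output.
* Jack-knife accuracy of the tumor/normal SVM on well-covered cohorts is
  expected in the ~80-90% range; poorly covered samples (sparse CpG-island
  coverage) degrade it.

Practical caveats: island scores are unstable for islands with few
informative CpG positions or shallow coverage (the `min-cg` threshold and
the matrix missingness filter exist for this reason), and bisulfite maps
must come from the same assembly as the alignments.
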
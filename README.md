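# transnp

Transcriptome SNP discovery and genotyping-assay design for non-model
species, plus the statistical battery used to validate the resulting
markers.

When no reference genome exists, SNPs are mined from de novo assembled
transcriptome contigs: reads from a small multi-site discovery panel are
aligned back to the contigs, candidate variants are called under strict
count rules, filtered for suitability on a multiplexed bead-array
genotyping platform (GoldenGate-style assays need ≥60 bp of clean flank
on each side of the SNP), and finally validated by genotyping hundreds
of individuals. `transnp` implements that whole decision pipeline as a
reusable library and CLI, together with a synthetic-data generator so
every stage can be exercised against known truth without any external
database.

## What it does

- **Demultiplexing** (`transnp.demux`) — assign 10-mer dual-tagged reads
  to individuals/geosites by exact 5′ tag match; clip tags.
- **SNP discovery** (`transnp.snp_discovery`) — call a biallelic
  candidate at a pileup column iff exactly two alleles have ≥2
  supporting reads each and unambiguous depth ≥4 (both thresholds
  configurable); indels are never called, columns with three
  well-supported alleles are dropped. Per-SNP descriptors: depth, MSAF
  (minor sequencing allele frequency = minor reads / depth),
  individuals, geosites.
- **Assay design** (`transnp.assay_design`) — extract the 121-base
  target region (SNP ± 60 bp), compute the flank-quality score
  *Q* (number of mismatch-bearing positions within ±60 bp in the read
  alignment), score targets with a documented surrogate of the vendor
  design score (GC content, flank melting temperature, k-mer uniqueness,
  hairpin propensity; range-matched to [0, 1] so the standard
  thresholds — discard < 0.4, prefer > 0.7 — apply), and rank/select a
  genotyping panel.
- **Comparative annotation** (`transnp.comparative_annotation`) — a
  built-in seed-and-extend local aligner over user-supplied reference
  FASTA; two-route intron–exon boundary prediction with the
  1 / 0 / "no" coding (1 = target region within a single exon in at
  least one comparison); synonymous vs conservative vs non-conservative
  amino-acid effect classification over the five physico-chemical
  classes; mitochondrial-contig flagging; GO-term Fisher/FDR enrichment.
- **Validation statistics** (`transnp.validation_stats`) — genotype QC
  (drop samples with call rate < 0.8, flag unclustered loci), Yates
  continuity-corrected χ² for 2×2 tables (with the correction floored so
  χ² = 0 when |ad − bc| ≤ N/2), Mann–Whitney U with Monte-Carlo
  confidence intervals, paired Wilcoxon signed-rank, binomial logistic
  regression with enter/backward-Wald selection (per-term B, Wald χ²,
  df, p, classification rate at 0.5), and ROC analysis (AUC = U/(n₁n₂),
  DeLong or Hanley–McNeil SE, Youden-optimal cutoff).
- **Synthetic data** (`transnp.synthetic`) — seeded generator of
  contigs, Hardy–Weinberg genotypes across four geosites, tagged reads
  under a long-read (≈206 bp, low error, modest depth) or short-read
  (74 bp, higher error, deep coverage) profile, a companion model-species
  reference (genome with planted introns, transcriptome, proteome from
  the true reading frames), and truth tables for sensitivity /
  false-positive / MSAF-bias evaluation.

## Worked example

A complete run on a 40-contig simulated dataset (seed 42):

```bash
transnp simulate --config sim.yaml --out-dir sim --seed 42
# simulated 40 contigs, 2090 reads -> sim
transnp demux --reads sim/reads.fastq --tags sim/tags.tsv --out-dir demux
# assigned 2090, unassigned 0
transnp discover --pileup sim/pileup.tsv --out snps.tsv
# called 151 candidate SNPs
transnp annotate --snps snps.tsv --contigs sim/contigs.fasta \
    --genome sim/reference_genome.fasta --out snps_ann.tsv
# annotated 151 candidates
transnp design --snps snps_ann.tsv --contigs sim/contigs.fasta \
    --pileup sim/pileup.tsv --panel-size 24 --out panel.tsv
# selected panel of 24 SNPs
```

The resulting panel (one best-ranked SNP per contig first, all targets
present, every score ≥ 0.4, no intron-disrupted candidate):

```
contig_id  position     msaf  q_score  snp_score  ie_code  rank
  ctg0026        83 0.266667        4   0.890833        1     1
  ctg0025       746 0.105263        4   0.788333        1     1
  ctg0031        93 0.086957        4   0.721667        1     1
  ctg0040       431 0.111111        5   0.907917        1     1
  ctg0029       451 0.192308        6   0.772917        1     1
```

Here `position` is 1-based, `msaf` the minor-allele read fraction at
discovery, `q_score` the count of mismatch-bearing flank positions
(lower is cleaner sequence), `snp_score` the surrogate design score and
`ie_code` = 1 the single-exon prediction from the comparative
intron–exon test.

Every CLI run writes a JSON manifest (inputs, seed, version, timestamp)
next to its outputs; deterministic stages re-run bit-identically from
the same manifest.

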
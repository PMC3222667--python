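# Methods

## Setting and model

`transnp` targets marker development in species without a reference
genome: variants are mined from a de novo assembled transcriptome, so
every downstream decision must work from the contigs themselves plus
comparative evidence from related model species. The package covers the
pipeline from barcode demultiplexing through candidate calling, assay
suitability filtering, comparative annotation, and the statistics used
to compare discovery strategies and to model which assays succeed.

Coordinates are 0-based half-open internally and 1-based closed in all
human-readable outputs; converting twice is the identity.

## SNP calling

A pileup column yields a biallelic candidate iff exactly two unambiguous
alleles each have at least `min_allele_reads` (default 2) supporting
reads and the unambiguous depth is at least `min_depth` (default 4).
Rationale for the rigid count rule: with a handful of diploid
individuals per site and appreciable sequencing error, a second allele
seen once is indistinguishable from error, while two independent
observations of each allele at depth ≥4 is the weakest evidence worth
genotyping. Consequences of the definition used here:

- Depth counts A/C/G/T observations only. Ambiguous bases (N) count
  toward nothing except the flank-quality score Q; alignment gaps never
  count as alleles and never disqualify a column (indels are out of
  scope for bead-array assays).
- Columns where three or more alleles reach the read threshold are
  rejected outright rather than reduced to their top two: the
  genotyping chemistry is strictly biallelic and a triallelic signal
  usually indicates paralogy.
- A 50/50 allele split takes the alphabetically first base as major,
  for determinism.
- MSAF = minor reads / depth, in (0, 0.5]. The Individuals/Geosites
  descriptors count distinct labelled sources covering the site with at
  least one read; untagged reads contribute depth but no labels.

The per-100-bp SNP density divides the candidate count by the cumulative
length of SNP-containing contigs (the sequence actually surveyed), not
by the whole assembly; the per-Mbp density divides by total sequence
generated. This is the only reading that makes the two densities of a
discovery summary mutually consistent.

## Assay design

The genotyping chemistry needs a 121-base target (SNP ± 60 bp) entirely
inside the contig; candidates closer than 60 bp to a contig end are
dropped (absence is a value, not an error).

*Q* counts the flank positions within ±60 bp of the SNP at which at
least one aligned read disagrees with the column consensus (plurality
base, ties alphabetical; ambiguous bases always count as disagreeing).
A positions-based count was preferred over a total-mismatch count
because it stays a small integer insensitive to depth, which is what
makes a threshold like "Q > 1" transferable between datasets; a
`mode="bases"` alternative is provided.

The vendor's proprietary design score is replaced by a documented
surrogate: the equally weighted mean of four sub-scores in [0, 1] —
GC-content proximity to [0.35, 0.65]; flank melting temperature
(salt-free `81.5 + 0.41·GC% − 675/N` approximation) proximity to
[75, 85] °C losing 0.1 per degree; canonical 15-mer uniqueness against
the contig set (or within the target when no index is supplied); and
hairpin propensity from the longest self-complementary stem (full
credit below 6 bp, zero at 20 bp). The surrogate is deterministic,
invariant under reverse complement, and range-matched to the vendor
scale so the published thresholds (floor 0.4, preferred 0.7) carry over
unchanged — but its values are not vendor scores and should not be
compared numerically against them. Weights and windows are
configurable.

Panel selection filters (target present, score ≥ floor, not
intron-disrupted unless allowed, optional Q cap) and then ranks within
each contig by an explicit composite: lower Q, preferred-score band,
higher score, greater distance to the nearest other candidate in the
contig, higher depth, with (contig, position) as the final tie-break.
The historical practice this replaces was a visual inspection; the
composite is a documented, reproducible stand-in, and "distance and
clustering of polymorphic sites" is operationalized as
nearest-candidate distance, the only measurable reading. A missing Q
(deep-coverage datasets where it was never computed) sorts as 0 —
absence of mismatch evidence, not evidence of absence; callers who
dislike that can compute Q or set a cap. The panel takes each contig's
best candidate first, then fills globally; selection is a pure function
of its inputs.

## Comparative annotation

The built-in local aligner indexes subjects by exact 13-mers, clusters
seed hits per subject (clusters split at >10 kb gaps so one gene region
stays a single window), and runs affine-gap Smith–Waterman (Biopython's
C engine) on the padded window, both strands, scoring match +2 /
mismatch −3 / gap −5, −2. Hits below score 50 are discarded; with the
seed requirement this drives the shuffled-sequence false-hit rate to
zero in 200 calibration trials. Ties break by (subject, start). An
e-value-like significance is attached for reporting only.

For transcript-vs-genome comparisons a *spliced* preset makes gap
extension nearly free (−0.15, open −6): under these scores random
intronic sequence aligns worse than a gap, so intron-sized subject gaps
are bridged by a single alignment chain. The chain is then split back
into exon-like blocks wherever the subject gap is ≥30 bp; alignment
segments scoring below ~a dozen net matches are ignored when placing
block boundaries, because the dynamic program will interrupt a long gap
at accidental low-identity matches. A SNP's target region is coded
single-exon ("1") when one block covers the ±60 bp window.

Route A applies this directly to contig-vs-genome. Route B finds the
best homolog transcript, maps the SNP through the alignment blocks into
transcript coordinates (outside the aligned region → "no"), and asks
whether the ±60-transcript-bp window (clamped to the transcript) falls
inside a single exon — from the supplied exon map when present,
otherwise by aligning the transcript to its own genome. Codes from all
species and both routes pool with precedence 1 > 0 > "no", and the
species-match count is the number of comparisons with any significant
hit; the count is 0 exactly when the combined code is "no".

Amino-acid effects: the contig is translated in six frames, each
peptide locally aligned (BLOSUM62, −11/−1) against the supplied
proteomes, and the best frame above score 60 fixes the reading frame.
Both allele codons are translated; identical residues are synonymous,
different residues within one of the five physico-chemical classes
(non-polar GAVLIPMC, polar STNQ, negative DE, positive KRH, aromatic
FWY) are conservative, across classes non-conservative; an introduced
stop is non-conservative with a nonsense flag. His is grouped as
positive and Cys/Met as non-polar; the table is configurable since
class membership conventions vary. SNPs outside the aligned coding
region, or contigs without a significant peptide match, are UNKNOWN.

GO enrichment is a per-term two-sided Fisher exact test of test vs
reference contig sets with Benjamini–Hochberg FDR; terms absent from
both sets are skipped.

## Validation statistics

- χ² for 2×2 tables applies the Yates continuity correction by default,
  floored so the statistic is exactly 0 when |ad − bc| ≤ N/2. The
  correction is the default because validation tables in this field are
  routinely reported corrected; an uncorrected mode exists.
- Mann–Whitney U is tie-corrected; its p-value is estimated by label
  permutation (default 1,000,000 permutations, chunked and vectorized)
  with an add-one estimator and a 99% Clopper–Pearson interval for the
  estimate itself. Two-sided by default. Deterministic given a seed.
- The paired Wilcoxon statistic V is the sum of positive-difference
  ranks after dropping zeros; p comes from the exact null for small
  untied samples and the tie-corrected normal approximation otherwise.
- Logistic regression is fitted by maximum likelihood (statsmodels).
  Categorical predictors expand to indicator contrasts with the last
  level as reference. Backward mode removes, per round, the predictor
  with the largest Wald p (multi-level categoricals as a block on their
  joint Wald χ²) while it exceeds the stay threshold, default p = 0.10
  — the common default of the statistical package this emulates, and
  configurable. Constant and collinear columns are dropped with
  warnings; near-separation is flagged rather than hidden. The model
  χ² is the likelihood ratio against the intercept-only fit; the
  classification rate uses the 0.5 probability cutoff.
- ROC analysis computes AUC as the scaled Mann–Whitney statistic
  (trapezoidal equivalence), the AUC standard error by DeLong's
  placement-value estimator by default (Hanley–McNeil available),
  z = (AUC − 0.5)/SE, and the optimal cutoff maximizing Youden
  J = sensitivity + specificity − 1 with "positive" meaning score >
  cutoff and ties resolved toward the smaller cutoff.
- Genotype QC removes samples with call rate < 0.8 and treats
  per-locus clustering quality as an input flag (`cluster_ok`): the
  package never sees raw intensity data, so clustering failures must be
  asserted upstream. Per-locus MAF and observed heterozygosity come
  from straight genotype counting; a locus is polymorphic when both
  alleles are observed among called genotypes.

## Synthetic data generator

The generator emulates the study design the pipeline is meant for: a
discovery panel of individuals drawn from four geosites (round-robin
assignment, so 8 individuals give 2+2+2+2 and 5 give 2+1+1+1), contigs
with log-normal lengths (median 300 bp, clipped to ≥100 bp), a per-site
SNP rate of 1%, allele frequencies from a Beta(1.2, 3) prior (folded),
Hardy–Weinberg genotypes within geosites (optional Balding–Nichols
divergence between geosites, default off), and two named platform
profiles: `longread` (reads ≈206 ± 50 bp, 0.3% substitution error,
~30× depth) and `shortread` (fixed 74 bp, 1% error, ~600× depth),
mirroring the length/error/depth contrast of the two sequencing
strategies it emulates. About 2% of contigs are mitochondrial
(substrings of a synthetic mito genome). Every non-mito contig carries
a coding region (~60%, random sense codons) whose translation forms the
companion proteome; the companion "model species" reference genome is
the contig sequence (optionally diverged) with introns inserted at a
configurable per-base rate (default 0.0015, lengths 100–800 bp), and
the matching transcriptome carries the exact exon map. Reads are
allocated to individuals in equal shares with a rotating remainder, so
per-individual totals are exact; each read samples one haplotype,
substitution errors are applied per base, and the pileup is emitted
from the known placements. Sequencing errors are applied to the insert
only, not to the barcode tags: the generator models tag corruption as a
separate, explicit experiment (the demultiplexing tests corrupt tags
deliberately), keeping "uncorrupted reads demultiplex perfectly" a
testable invariant.

What the generator does **not** model: assembly artifacts (chimeras,
collapsed paralogs), expression-level coverage bias of a non-normalized
cDNA library, base-quality score distributions, indels, and
platform-specific error motifs (e.g. homopolymer errors). Passing
truth-based tests therefore demonstrates the correctness of the
decision logic under clean alignments, not robustness to misassembly —
the dominant real-world failure mode these filters exist to mitigate.

Truth-based evaluation conditions sensitivity on planted SNPs whose
minor (and major) allele class was actually sampled by ≥2 reads — the
calling rule cannot in principle recover anything below that — and
measures MSAF accuracy against the realized panel allele frequency (the
frequency among the sampled individuals' chromosomes), since that, not
the population parameter, is what infinite sequencing depth would
recover.

## Problem sizes and numerical choices

The test suite and acceptance script use deliberately scaled problem
sizes chosen to exercise every code path with comfortable statistical
margins: simulations of 120–200 contigs with 8 individuals over 4
geosites, shallow (≈8×) vs deep (≈60×) error-free profiles for the
depth-contrast analyses, exhaustive enumeration oracles where the space
is small (all pileup columns to depth 6, all 2×2 tables with cells ≤30,
all 576 single-base codon changes), and 100 replicates at n = 2,000 for
logistic-recovery checks. Monte-Carlo defaults (10⁶ permutations)
are reduced in tests to keep them fast; all stochastic procedures take
explicit seeds and are bit-reproducible.

Known limitations: the spliced alignment preset can fail to chain
through a pathological exon structure (a very short exon flanked by two
maximal-length introns), coding a truly single-exon window as
disrupted; the surrogate design score shares only the *structure* of
the vendor score, so absolute values are not comparable across scoring
systems; and the backward-elimination path, like all stepwise
procedures, inherits the usual caveats about post-selection inference.
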
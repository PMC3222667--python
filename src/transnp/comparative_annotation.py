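"""Comparative annotation: intron-exon boundary prediction, amino-acid
effect classification, mitochondrial flagging, and GO-term enrichment.

Intron-exon boundary prediction decides whether a SNP's 121-bp target
region lies within a single exon of a homologous gene, using two routes:

* Route A aligns the SNP-containing contig directly to a reference
  genome. If one exon-like alignment block covers the +/-60 bp window
  the SNP is coded single-exon ("1"); a significant hit without such a
  block implies an intron inside the target ("0"); otherwise "no".
* Route B aligns the contig to a reference transcriptome, maps the SNP
  onto the homolog transcript through the alignment coordinates, and
  asks whether the +/-60 transcript-bp window falls inside one exon of
  that transcript (from a supplied exon map, or from aligning the
  transcript to its own genome).

Codes from all species and routes are combined with precedence
1 > 0 > "no": a single single-exon call wins over any intron call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .align import LocalAligner, LocalHit, spliced_aligner
from .assay_design import TARGET_FLANK
from .io_core import Contig, DataError, IECode, SnpCandidate, get_logger, revcomp

__all__ = [
    "ReferenceSet",
    "EffectClass",
    "EffectCall",
    "AA_CLASSES",
    "ie_route_a",
    "ie_route_b",
    "combine_ie",
    "annotate_ie",
    "classify_codon_change",
    "classify_effect",
    "flag_mitochondrial",
    "go_enrichment",
]

log = get_logger(__name__)


@dataclass
class ReferenceSet:
    """Reference sequences for one model species.

    ``exon_map`` maps transcript id -> ordered, non-overlapping genomic
    intervals (0-based half-open) of its exons; transcript coordinates
    follow the cumulative exon lengths.
    """

    species_id: str
    genome: dict[str, str] = field(default_factory=dict)
    transcriptome: dict[str, str] = field(default_factory=dict)
    proteome: dict[str, str] = field(default_factory=dict)
    exon_map: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tid, intervals in self.exon_map.items():
            prev_end = -1
            for start, end in intervals:
                if end <= start or start < prev_end:
                    raise DataError(
                        f"{self.species_id}/{tid}: exon intervals must be "
                        "ordered and non-overlapping"
                    )
                prev_end = end


# Five physico-chemical amino-acid classes used for conservative vs
# non-conservative replacement calls.
AA_CLASSES: dict[str, str] = {}
for _cls, _residues in {
    "nonpolar": "GAVLIPMC",
    "polar": "STNQ",
    "negative": "DE",
    "positive": "KRH",
    "aromatic": "FWY",
}.items():
    for _aa in _residues:
        AA_CLASSES[_aa] = _cls


class EffectClass(str, Enum):
    SYNONYMOUS = "synonymous"
    NONSYN_CONSERVATIVE = "nonsyn_conservative"
    NONSYN_NONCONSERVATIVE = "nonsyn_nonconservative"
    UNKNOWN = "unknown"


@dataclass
class EffectCall:
    """Predicted amino-acid consequence of a SNP."""

    locus_id: str
    classification: EffectClass
    frame: int | None = None  # 0..2 offset on the aligned strand
    strand: str | None = None
    codon_ref: str | None = None
    codon_alt: str | None = None
    aa_ref: str | None = None
    aa_alt: str | None = None
    nonsense: bool = False


# ---------------------------------------------------------------------------
# Intron-exon boundary prediction
# ---------------------------------------------------------------------------

def _window_in_single_block(hit: LocalHit, start: int, end: int) -> bool:
    return any(qs <= start and qe >= end for qs, qe, _, _ in hit.blocks)


def ie_route_a(
    contig: Contig,
    snp_position: int,
    refset: ReferenceSet,
    aligner: LocalAligner | None = None,
    flank: int = TARGET_FLANK,
) -> IECode:
    """Direct contig-vs-genome test of the SNP target region."""
    if aligner is None:
        aligner = spliced_aligner(refset.genome)
    hit = aligner.best_hit(contig.contig_id, contig.sequence)
    if hit is None:
        return IECode.NO_MATCH
    if _window_in_single_block(hit, snp_position - flank, snp_position + flank + 1):
        return IECode.SINGLE_EXON
    return IECode.INTRON_DISRUPTED


def _map_query_to_subject(hit: LocalHit, qpos: int) -> int | None:
    """Map a forward-query position through the alignment blocks."""
    for qs, qe, ss, se in hit.blocks:
        if qs <= qpos < qe:
            if hit.strand == "+":
                return ss + (qpos - qs)
            return se - 1 - (qpos - qs)
    return None


def _transcript_exon_bounds(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Genomic exon intervals -> cumulative transcript-coordinate spans."""
    out = []
    offset = 0
    for start, end in intervals:
        length = end - start
        out.append((offset, offset + length))
        offset += length
    return out


def ie_route_b(
    contig: Contig,
    snp_position: int,
    refset: ReferenceSet,
    aligner: LocalAligner | None = None,
    genome_aligner: LocalAligner | None = None,
    flank: int = TARGET_FLANK,
) -> IECode:
    """Homolog-transcript route of the intron-exon test."""
    if not refset.transcriptome:
        return IECode.NO_MATCH
    if aligner is None:
        aligner = LocalAligner(refset.transcriptome)
    hit = aligner.best_hit(contig.contig_id, contig.sequence)
    if hit is None:
        return IECode.NO_MATCH
    tpos = _map_query_to_subject(hit, snp_position)
    if tpos is None:
        return IECode.NO_MATCH
    transcript_id = hit.subject_id
    tlen = len(refset.transcriptome[transcript_id])
    wstart = max(0, tpos - flank)
    wend = min(tlen, tpos + flank + 1)
    intervals = refset.exon_map.get(transcript_id)
    if intervals:
        bounds = _transcript_exon_bounds(intervals)
        for lo, hi in bounds:
            if lo <= wstart and hi >= wend:
                return IECode.SINGLE_EXON
        return IECode.INTRON_DISRUPTED
    if not refset.genome:
        # no exon structure available: the transcript itself is the only
        # evidence, treat as single exon
        return IECode.SINGLE_EXON
    if genome_aligner is None:
        genome_aligner = spliced_aligner(refset.genome)
    ghit = genome_aligner.best_hit(transcript_id, refset.transcriptome[transcript_id])
    if ghit is None:
        return IECode.NO_MATCH
    if _window_in_single_block(ghit, wstart, wend):
        return IECode.SINGLE_EXON
    return IECode.INTRON_DISRUPTED


def combine_ie(codes: Iterable[IECode]) -> tuple[IECode, int]:
    """Pool per-species/per-route codes with precedence 1 > 0 > "no".

    Returns the combined code and the number of comparisons with a
    significant match (anything except "no").
    """
    codes = list(codes)
    matches = sum(1 for c in codes if c != IECode.NO_MATCH)
    if any(c == IECode.SINGLE_EXON for c in codes):
        return IECode.SINGLE_EXON, matches
    if any(c == IECode.INTRON_DISRUPTED for c in codes):
        return IECode.INTRON_DISRUPTED, matches
    return IECode.NO_MATCH, matches


def annotate_ie(
    contig: Contig,
    snp: SnpCandidate,
    refsets: Sequence[ReferenceSet],
    aligners: Mapping[str, dict] | None = None,
) -> SnpCandidate:
    """Run both intron-exon routes against every species and combine.

    ``aligners`` may cache per-species ``{"genome": ..., "transcriptome":
    ...}`` :class:`LocalAligner` objects across SNPs/contigs.
    """
    codes = []
    for refset in refsets:
        cache = (aligners or {}).get(refset.species_id, {})
        if refset.genome:
            codes.append(
                ie_route_a(contig, snp.position, refset, cache.get("genome"))
            )
        if refset.transcriptome:
            codes.append(
                ie_route_b(
                    contig,
                    snp.position,
                    refset,
                    cache.get("transcriptome"),
                    cache.get("genome"),
                )
            )
    code, matches = combine_ie(codes)
    snp.ie_code = code
    snp.ie_species_match = matches
    return snp


# ---------------------------------------------------------------------------
# Synonymous / non-synonymous classification
# ---------------------------------------------------------------------------

def classify_codon_change(codon_ref: str, codon_alt: str) -> tuple[EffectClass, bool]:
    """Classify a single-codon substitution; returns (class, nonsense)."""
    aa_ref = str(Seq(codon_ref).translate())
    aa_alt = str(Seq(codon_alt).translate())
    if aa_alt == "*" or aa_ref == "*":
        if aa_ref == aa_alt:
            return EffectClass.SYNONYMOUS, False
        return EffectClass.NONSYN_NONCONSERVATIVE, True
    if aa_ref == aa_alt:
        return EffectClass.SYNONYMOUS, False
    if AA_CLASSES[aa_ref] == AA_CLASSES[aa_alt]:
        return EffectClass.NONSYN_CONSERVATIVE, False
    return EffectClass.NONSYN_NONCONSERVATIVE, False


def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def classify_effect(
    contig: Contig,
    snp: SnpCandidate,
    proteomes: Mapping[str, Mapping[str, str]],
    min_protein_score: float = 60.0,
) -> EffectCall:
    """Infer the reading frame by translated search and classify the SNP.

    The contig is translated in all six frames and each peptide is
    locally aligned (BLOSUM62) against the supplied proteomes; the best
    frame above ``min_protein_score`` provides the reading frame. Both
    allele versions of the codon holding the SNP are translated and the
    residue change classified by the five physico-chemical classes.
    UNKNOWN when no significant peptide match exists or the SNP codon
    falls outside the aligned coding region.
    """
    locus = f"{contig.contig_id}:{snp.position}"
    if snp.target_region is None and not (
        TARGET_FLANK <= snp.position < len(contig) - TARGET_FLANK
    ):
        log.debug("%s: no target region, classify anyway from contig", locus)
    aligner = _protein_aligner()
    best = None  # (score, strand, offset, peptide, qstart, qend)
    for strand in ("+", "-"):
        seq = contig.sequence if strand == "+" else revcomp(contig.sequence)
        for offset in range(3):
            coding = seq[offset : offset + 3 * ((len(seq) - offset) // 3)]
            if len(coding) < 3:
                continue
            peptide = str(Seq(coding).translate())
            clean = peptide.replace("*", "X")
            for species, prots in proteomes.items():
                for prot_id, prot in prots.items():
                    alns = aligner.align(clean, prot)
                    try:
                        aln = alns[0]
                    except (IndexError, OverflowError):
                        continue
                    score = float(aln.score)
                    if score < min_protein_score:
                        continue
                    qsegs = aln.aligned[0]
                    qstart, qend = int(qsegs[0][0]), int(qsegs[-1][1])
                    key = (score, strand, offset)
                    if best is None or score > best[0]:
                        best = (score, strand, offset, qstart, qend)
    if best is None:
        return EffectCall(locus, EffectClass.UNKNOWN)
    _, strand, offset, qstart, qend = best
    n = len(contig)
    if strand == "+":
        pos = snp.position
        major, minor = snp.major_allele, snp.minor_allele
        seq = contig.sequence
    else:
        pos = n - 1 - snp.position
        major = revcomp(snp.major_allele)
        minor = revcomp(snp.minor_allele)
        seq = revcomp(contig.sequence)
    rel = pos - offset
    if rel < 0:
        return EffectCall(locus, EffectClass.UNKNOWN, strand=strand)
    codon_i = rel // 3
    codon_start = offset + 3 * codon_i
    if codon_start + 3 > n:
        return EffectCall(locus, EffectClass.UNKNOWN, strand=strand)
    if not (qstart <= codon_i < qend):
        return EffectCall(locus, EffectClass.UNKNOWN, strand=strand, frame=offset)
    codon_ref = seq[codon_start : codon_start + 3]
    within = pos - codon_start
    if codon_ref[within] != major:
        # consensus carries the major allele by construction; if not,
        # classify relative to what the contig actually holds
        major = codon_ref[within]
    codon_alt = codon_ref[:within] + minor + codon_ref[within + 1 :]
    classification, nonsense = classify_codon_change(codon_ref, codon_alt)
    return EffectCall(
        locus_id=locus,
        classification=classification,
        frame=offset,
        strand=strand,
        codon_ref=codon_ref,
        codon_alt=codon_alt,
        aa_ref=str(Seq(codon_ref).translate()),
        aa_alt=str(Seq(codon_alt).translate()),
        nonsense=nonsense,
    )


# ---------------------------------------------------------------------------
# Mitochondrial flagging and GO enrichment
# ---------------------------------------------------------------------------

def flag_mitochondrial(
    contigs: Sequence[Contig],
    mito_reference: Mapping[str, str] | str,
    min_score: float = 80.0,
) -> dict[str, bool]:
    """Flag contigs whose best hit to the mitochondrial reference passes.

    Sets ``is_mitochondrial`` in place and returns the flag map. Flagged
    contigs should be excluded from nuclear panels and statistics.
    """
    if isinstance(mito_reference, str):
        mito_reference = {"mito": mito_reference}
    aligner = LocalAligner(mito_reference, min_score=min_score)
    flags = {}
    for contig in contigs:
        hit = aligner.best_hit(contig.contig_id, contig.sequence)
        contig.is_mitochondrial = hit is not None
        flags[contig.contig_id] = contig.is_mitochondrial
    return flags


def go_enrichment(
    test_annotations: Mapping[str, set] | pd.DataFrame,
    reference_annotations: Mapping[str, set] | pd.DataFrame,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-term Fisher exact enrichment of test vs reference contig sets.

    Inputs map contig id -> set of terms (or long DataFrames with
    ``contig_id``/``term`` columns). For each term present in either
    set, a 2x2 table (test vs reference x has-term vs not) is tested
    two-sided; p-values are Benjamini-Hochberg corrected and terms with
    ``fdr < fdr_threshold`` are marked enriched.
    """

    def _to_map(ann) -> dict[str, set]:
        if isinstance(ann, pd.DataFrame):
            return {
                cid: set(grp["term"]) for cid, grp in ann.groupby("contig_id")
            }
        return {k: set(v) for k, v in ann.items()}

    test = _to_map(test_annotations)
    ref = _to_map(reference_annotations)
    n_test, n_ref = len(test), len(ref)
    terms = sorted(set().union(*test.values(), *ref.values())) if (test or ref) else []
    rows = []
    for term in terms:
        a = sum(1 for t in test.values() if term in t)
        c = sum(1 for t in ref.values() if term in t)
        if a == 0 and c == 0:
            continue
        b, d = n_test - a, n_ref - c
        odds, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append((term, a, n_test, c, n_ref, odds, p))
    df = pd.DataFrame(
        rows,
        columns=["term", "test_with", "test_n", "ref_with", "ref_n", "odds", "p"],
    )
    if len(df):
        df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
        df["enriched"] = df["fdr"] < fdr_threshold
    else:
        df["fdr"] = pd.Series(dtype=float)
        df["enriched"] = pd.Series(dtype=bool)
    return df.sort_values("p").reset_index(drop=True)
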
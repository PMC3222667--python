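"""Seed-and-extend local nucleotide aligner over user-supplied references.

Comparative annotation needs thousands of contig-vs-reference lookups
without any network database. The aligner indexes subject sequences by
exact k-mers, clusters seed matches into candidate subject regions, and
runs a local affine-gap alignment (Smith-Waterman, via Biopython's C
pairwise engine) on the padded window around each region, on both
strands. Scoring defaults follow the common megablast-style scheme
(match +2, mismatch -3, gap open 5, gap extend 2).

Hits below ``min_score`` are discarded; a crude extreme-value e-value is
attached for reporting. Alignment blocks are reported with large subject
gaps (candidate introns) split out, so callers can ask whether a single
gap-free-ish block covers a query window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from Bio import Align

from .io_core import revcomp

__all__ = ["LocalHit", "LocalAligner", "spliced_aligner"]


@dataclass
class LocalHit:
    """Best local alignment of a query against a subject set.

    Coordinates are 0-based half-open. For minus-strand hits the query
    coordinates refer to the original (forward) query orientation.
    ``blocks`` are (qstart, qend, sstart, send) alignment segments after
    merging gaps shorter than the intron threshold; a block is the
    largest exon-like piece of the alignment.
    """

    query_id: str
    subject_id: str
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    strand: str
    score: float
    evalue: float
    blocks: list[tuple[int, int, int, int]] = field(default_factory=list)


class LocalAligner:
    """K-mer seeded local aligner against an in-memory subject set."""

    def __init__(
        self,
        subjects: Mapping[str, str],
        k: int = 13,
        match: float = 2.0,
        mismatch: float = -3.0,
        open_gap: float = -5.0,
        extend_gap: float = -2.0,
        min_score: float = 50.0,
        min_intron: int = 30,
        max_regions: int = 8,
        pad: int = 400,
        max_join: int = 10_000,
    ):
        self.subjects = {name: seq.upper() for name, seq in subjects.items()}
        self.k = k
        self.min_score = min_score
        self.min_intron = min_intron
        self.max_regions = max_regions
        self.pad = pad
        self.max_join = max_join
        self.total_subject_len = sum(len(s) for s in self.subjects.values())
        self._lambda = 0.55  # crude extreme-value scale for the e-value
        self.aligner = Align.PairwiseAligner()
        self.aligner.mode = "local"
        self.aligner.match_score = match
        self.aligner.mismatch_score = mismatch
        self.aligner.open_gap_score = open_gap
        self.aligner.extend_gap_score = extend_gap
        self._index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in self.subjects.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                self._index.setdefault(kmer, []).append((name, i))

    # ------------------------------------------------------------------
    def _seed_regions(self, qseq: str) -> list[tuple[str, int, int]]:
        """Candidate (subject, window_start, window_end) regions by seeds.

        Seed positions on each subject are clustered; a gap larger than
        ``max_join`` bases starts a new cluster, so one exon-spanning
        gene region stays a single candidate window.
        """
        hits: dict[str, list[int]] = {}
        k = self.k
        for qpos in range(len(qseq) - k + 1):
            for name, spos in self._index.get(qseq[qpos : qpos + k], ()):
                hits.setdefault(name, []).append(spos)
        if not hits:
            return []
        regions = []  # (count, name, lo, hi)
        for name, positions in hits.items():
            positions.sort()
            start = prev = positions[0]
            count = 1
            for spos in positions[1:]:
                if spos - prev > self.max_join:
                    regions.append((count, name, start, prev))
                    start = spos
                    count = 0
                prev = spos
                count += 1
            regions.append((count, name, start, prev))
        regions.sort(key=lambda r: (-r[0], r[1], r[2]))
        out = []
        for _, name, lo, hi in regions[: self.max_regions]:
            start = max(0, lo - len(qseq) - self.pad)
            end = min(len(self.subjects[name]), hi + len(qseq) + self.pad)
            out.append((name, start, end))
        return out

    def _blocks(
        self,
        aligned: np.ndarray,
        offset: int,
        qseq: str,
        subject: str,
        min_anchor_score: float = 24.0,
    ) -> list[tuple[int, int, int, int]]:
        """Merge aligned segments across small gaps; split at intron-sized ones.

        Weak segments (score below ``min_anchor_score``, i.e. fewer than
        about a dozen net matching bases) are ignored when deciding block
        boundaries: the dynamic program happily interrupts a long
        (intron-sized) gap at accidental low-identity matches, which
        would otherwise disguise the gap as a run of small ones.
        """
        qsegs, ssegs = aligned
        pairs = [
            ((int(qs), int(qe)), (int(ss) + offset, int(se) + offset))
            for (qs, qe), (ss, se) in zip(qsegs, ssegs)
        ]

        def _seg_score(pair) -> float:
            (qs, qe), (ss, se) = pair
            matches = sum(
                1 for a, b in zip(qseq[qs:qe], subject[ss:se]) if a == b
            )
            mism = (qe - qs) - matches
            return self.aligner.match_score * matches + self.aligner.mismatch_score * mism

        anchors = [p for p in pairs if _seg_score(p) >= min_anchor_score]
        if not anchors:
            anchors = pairs
        blocks: list[list[int]] = []
        for (qs, qe), (ss, se) in anchors:
            if blocks:
                prev = blocks[-1]
                qgap = qs - prev[1]
                sgap = ss - prev[3]
                if qgap < self.min_intron and sgap < self.min_intron:
                    prev[1], prev[3] = qe, se
                    continue
            blocks.append([qs, qe, ss, se])
        return [tuple(b) for b in blocks]

    def best_hit(self, query_id: str, query: str) -> LocalHit | None:
        """Highest-scoring local hit across subjects and strands, or None.

        Ties are broken deterministically by (subject_id, subject_start).
        """
        query = query.upper()
        best: LocalHit | None = None
        if not self.subjects:
            return None
        for strand in ("+", "-"):
            qseq = query if strand == "+" else revcomp(query)
            for name, wstart, wend in self._seed_regions(qseq):
                window = self.subjects[name][wstart:wend]
                alignments = self.aligner.align(qseq, window)
                try:
                    aln = alignments[0]
                except IndexError:
                    continue
                score = float(aln.score)
                if score < self.min_score:
                    continue
                blocks = self._blocks(aln.aligned, wstart, qseq, self.subjects[name])
                qstart = int(blocks[0][0])
                qend = int(blocks[-1][1])
                if strand == "-":
                    # map back to forward-query coordinates
                    n = len(query)
                    blocks = [
                        (n - qe, n - qs, ss, se) for qs, qe, ss, se in reversed(blocks)
                    ]
                    qstart, qend = n - qend, n - qstart
                hit = LocalHit(
                    query_id=query_id,
                    subject_id=name,
                    query_start=qstart,
                    query_end=qend,
                    subject_start=int(blocks[0][2]),
                    subject_end=int(blocks[-1][3]),
                    strand=strand,
                    score=score,
                    evalue=self._evalue(score, len(query)),
                    blocks=blocks,
                )
                if (
                    best is None
                    or hit.score > best.score
                    or (
                        hit.score == best.score
                        and (hit.subject_id, hit.subject_start)
                        < (best.subject_id, best.subject_start)
                    )
                ):
                    best = hit
        return best

    def _evalue(self, score: float, query_len: int) -> float:
        mn = max(1, query_len * self.total_subject_len)
        return mn * math.exp(-self._lambda * score)


def spliced_aligner(subjects: Mapping[str, str], **kwargs) -> LocalAligner:
    """Aligner tuned for transcript-vs-genome comparisons.

    Gap extension is made cheap so intron-sized subject gaps are bridged
    by a single alignment chain (random intronic sequence scores worse
    than a gap under match +2 / mismatch -3); the intron-sized gaps are
    then split back out into exon-like blocks by ``min_intron``.
    """
    kwargs.setdefault("open_gap", -6.0)
    kwargs.setdefault("extend_gap", -0.15)
    return LocalAligner(subjects, **kwargs)
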
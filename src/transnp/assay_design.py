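"""Assay-suitability filtering and scoring for candidate SNPs.

A multiplexed bead-array genotyping assay needs at least 60 bp of clean
flanking sequence on each side of a SNP (a 121-base target region), a
template suitability score, and a target free of nearby sequence-quality
defects. This module extracts targets, computes the flank-quality score
Q (the count of mismatch-bearing positions within +/-60 bp of the SNP in
the read alignment), scores targets with a documented surrogate of the
proprietary vendor design score, and ranks/selects a genotyping panel.

The surrogate design score is the weighted mean of four sub-scores in
[0, 1] covering the same template properties the vendor tool screens:
GC content, flank melting temperature, k-mer uniqueness, and hairpin
(self-complementarity) propensity. It is range-matched to the vendor
scale so the published thresholds (discard < 0.4, prefer > 0.7) apply
unchanged, but the numeric values are not vendor scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_core import (
    CALL_BASES,
    ConfigError,
    Contig,
    DataError,
    IECode,
    PileupColumn,
    SnpCandidate,
    get_logger,
    revcomp,
)

__all__ = [
    "DesignCriteria",
    "extract_target",
    "compute_q",
    "DesignScorer",
    "surrogate_design_score",
    "select_panel",
    "TARGET_FLANK",
]

log = get_logger(__name__)

#: Minimum flank on either side of a SNP required by the genotyping assay.
TARGET_FLANK = 60


@dataclass
class DesignCriteria:
    """Thresholds applied when selecting a genotyping panel."""

    flank_bp: int = TARGET_FLANK
    score_floor: float = 0.4
    score_preferred: float = 0.7
    q_max: int | None = None
    allow_ie_intron: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.score_floor <= self.score_preferred <= 1.0:
            raise ConfigError("need 0 <= score_floor <= score_preferred <= 1")
        if self.flank_bp < 1:
            raise ConfigError("flank_bp must be >= 1")


def extract_target(contig: Contig, position: int, flank: int = TARGET_FLANK) -> str | None:
    """Return the (2*flank+1)-base target region around a SNP, or None.

    None (not an error) when either flank extends past a contig end.
    """
    if not 0 <= position < len(contig):
        raise DataError(f"position {position} outside contig {contig.contig_id}")
    if position < flank or position + flank >= len(contig):
        return None
    return contig.sequence[position - flank : position + flank + 1]


def compute_q(
    columns: Sequence[PileupColumn],
    position: int,
    window: int = TARGET_FLANK,
    mode: str = "positions",
) -> int:
    """Count mismatch evidence in the flanks of a SNP position.

    ``mode="positions"`` (default): number of flank positions within
    ``window`` of the SNP at which at least one aligned read base differs
    from the column consensus (plurality base, ties broken
    alphabetically; ambiguous bases always count as differing).
    ``mode="bases"``: total count of mismatching bases instead.
    """
    if mode not in ("positions", "bases"):
        raise ValueError(f"unknown Q mode {mode!r}")
    q = 0
    for col in columns:
        if col.position == position or abs(col.position - position) > window:
            continue
        counts = col.base_counts()
        best = max(counts.values())
        if best == 0:
            # only ambiguous observations: every base is a defect
            mismatches = len(col.observations)
        else:
            consensus = min(b for b in CALL_BASES if counts[b] == best)
            mismatches = sum(1 for _, b, _, _ in col.observations if b != consensus)
        if mode == "positions":
            q += 1 if mismatches > 0 else 0
        else:
            q += mismatches
    return q


def _gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def _wallace_tm(seq: str) -> float:
    """Salt-free long-oligo melting temperature approximation (deg C)."""
    gc_pct = 100.0 * _gc_fraction(seq)
    return 81.5 + 0.41 * gc_pct - 675.0 / len(seq)


def _canonical_kmer(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def _longest_stem(seq: str, min_stem: int) -> int:
    """Longest substring whose reverse complement also occurs in seq.

    A stem of length L means the target can fold back on itself pairing
    L consecutive bases. Computed by longest common substring between
    the sequence and its reverse complement (dynamic programming).
    """
    rc = revcomp(seq)
    n = len(seq)
    prev = np.zeros(n + 1, dtype=np.int32)
    best = 0
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    b = np.frombuffer(rc.encode(), dtype=np.uint8)
    for i in range(1, n + 1):
        cur = np.zeros(n + 1, dtype=np.int32)
        match = a[i - 1] == b
        cur[1:][match] = prev[:-1][match] + 1
        m = int(cur.max())
        if m > best:
            best = m
        prev = cur
    return best if best >= min_stem else 0


class DesignScorer:
    """Deterministic surrogate assay-design score over 121-base targets.

    Sub-scores, each in [0, 1]:

    * ``gc``: 1 inside the GC window [0.35, 0.65], decaying linearly to
      0 at GC 0 or 1.
    * ``tm``: mean flank proximity to the melting-temperature window
      [75, 85] deg C (salt-free GC/length approximation), losing 0.1 per
      degree outside the window.
    * ``uniqueness``: 1 minus the fraction of the target's canonical
      15-mers that occur more than once across the contig set (or, with
      no contig index, within the target itself).
    * ``hairpin``: 1 for stems shorter than 6 bp, decaying linearly to 0
      at stems of 20 bp or more.

    Default weights are equal (0.25 each).
    """

    def __init__(
        self,
        contigs: Iterable[Contig] | None = None,
        k: int = 15,
        weights: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
        gc_window: tuple[float, float] = (0.35, 0.65),
        tm_window: tuple[float, float] = (75.0, 85.0),
        tm_scale: float = 10.0,
        min_stem: int = 6,
        max_stem: int = 20,
        max_ambiguous: int = 2,
        flank: int = TARGET_FLANK,
    ):
        if len(weights) != 4 or not math.isclose(sum(weights), 1.0, abs_tol=1e-9):
            raise ConfigError("weights must be four values summing to 1")
        self.k = k
        self.weights = tuple(float(w) for w in weights)
        self.gc_window = gc_window
        self.tm_window = tm_window
        self.tm_scale = tm_scale
        self.min_stem = min_stem
        self.max_stem = max_stem
        self.max_ambiguous = max_ambiguous
        self.flank = flank
        self.kmer_counts: dict[str, int] | None = None
        if contigs is not None:
            counts: dict[str, int] = {}
            for contig in contigs:
                seq = contig.sequence
                for i in range(len(seq) - k + 1):
                    kmer = seq[i : i + k]
                    if "N" in kmer:
                        continue
                    key = _canonical_kmer(kmer)
                    counts[key] = counts.get(key, 0) + 1
            self.kmer_counts = counts

    def _window_proximity(self, value: float, lo: float, hi: float, scale: float) -> float:
        if lo <= value <= hi:
            return 1.0
        dist = lo - value if value < lo else value - hi
        return max(0.0, 1.0 - dist / scale)

    def sub_scores(self, target: str) -> dict[str, float]:
        if target is None:
            raise DataError("target region absent; filter upstream")
        if target.count("N") > self.max_ambiguous:
            raise DataError("too many ambiguous bases in target")
        gc = self._window_proximity(
            _gc_fraction(target), *self.gc_window, scale=self.gc_window[0]
        )
        left, right = target[: self.flank], target[-self.flank :]
        tm = 0.5 * (
            self._window_proximity(_wallace_tm(left), *self.tm_window, self.tm_scale)
            + self._window_proximity(_wallace_tm(right), *self.tm_window, self.tm_scale)
        )
        kmers = [
            target[i : i + self.k]
            for i in range(len(target) - self.k + 1)
            if "N" not in target[i : i + self.k]
        ]
        if not kmers:
            uniq = 0.0
        elif self.kmer_counts is not None:
            repeated = sum(
                1 for km in kmers if self.kmer_counts.get(_canonical_kmer(km), 0) > 1
            )
            uniq = 1.0 - repeated / len(kmers)
        else:
            local: dict[str, int] = {}
            for km in kmers:
                key = _canonical_kmer(km)
                local[key] = local.get(key, 0) + 1
            repeated = sum(1 for km in kmers if local[_canonical_kmer(km)] > 1)
            uniq = 1.0 - repeated / len(kmers)
        stem = _longest_stem(target, self.min_stem)
        if stem == 0:
            hairpin = 1.0
        else:
            hairpin = max(
                0.0,
                1.0 - (stem - self.min_stem + 1) / (self.max_stem - self.min_stem + 1),
            )
        return {"gc": gc, "tm": tm, "uniqueness": uniq, "hairpin": hairpin}

    def score(self, target: str) -> float:
        subs = self.sub_scores(target)
        w = self.weights
        return (
            w[0] * subs["gc"]
            + w[1] * subs["tm"]
            + w[2] * subs["uniqueness"]
            + w[3] * subs["hairpin"]
        )


def surrogate_design_score(target: str, contigs: Iterable[Contig] | None = None) -> float:
    """Score one target with default :class:`DesignScorer` settings."""
    return DesignScorer(contigs).score(target)


def _composite_key(
    cand: SnpCandidate,
    nearest: float,
    preferred: float,
) -> tuple:
    # lower Q first; missing Q carries no mismatch evidence and sorts as 0
    q = cand.q_score if cand.q_score is not None else 0
    score = cand.snp_score if cand.snp_score is not None else 0.0
    return (
        q,
        0 if score > preferred else 1,
        -score,
        -nearest,
        -(cand.depth),
        cand.contig_id,
        cand.position,
    )


def select_panel(
    candidates: Sequence[SnpCandidate],
    criteria: DesignCriteria,
    panel_size: int,
) -> list[SnpCandidate]:
    """Filter, rank within contigs, and select a genotyping panel.

    Candidates without a full target region, below the score floor, or
    predicted intron-disrupted (unless allowed) are dropped, as are
    candidates above ``q_max`` when set. Within each contig, Rank is
    assigned by ascending composite key (lower Q, preferred-score band,
    higher score, greater distance to the nearest other candidate SNP in
    the contig, higher depth). The panel takes each contig's best-ranked
    candidate first, then fills by the global composite up to
    ``panel_size``. Pure function of its inputs: repeated calls give
    identical panels.
    """
    # distance to nearest other candidate uses all input candidates
    by_contig_positions: dict[str, list[int]] = {}
    for c in candidates:
        by_contig_positions.setdefault(c.contig_id, []).append(c.position)

    def nearest_distance(c: SnpCandidate) -> float:
        others = [p for p in by_contig_positions[c.contig_id] if p != c.position]
        if not others:
            return math.inf
        return min(abs(c.position - p) for p in others)

    survivors = []
    for c in candidates:
        if c.target_region is None:
            continue
        if c.snp_score is None or c.snp_score < criteria.score_floor:
            continue
        if c.ie_code == IECode.INTRON_DISRUPTED and not criteria.allow_ie_intron:
            continue
        if criteria.q_max is not None and (c.q_score or 0) > criteria.q_max:
            continue
        survivors.append(c)

    keyed = {
        id(c): _composite_key(c, nearest_distance(c), criteria.score_preferred)
        for c in survivors
    }
    by_contig: dict[str, list[SnpCandidate]] = {}
    for c in survivors:
        by_contig.setdefault(c.contig_id, []).append(c)
    for contig_cands in by_contig.values():
        contig_cands.sort(key=lambda c: keyed[id(c)])
        for rank, c in enumerate(contig_cands, start=1):
            c.rank = rank

    if panel_size > len(survivors):
        log.warning(
            "panel_size %d exceeds %d surviving candidates; returning all",
            panel_size,
            len(survivors),
        )
    first_round = sorted(
        (cands[0] for cands in by_contig.values()), key=lambda c: keyed[id(c)]
    )
    panel: list[SnpCandidate] = first_round[:panel_size]
    if len(panel) < panel_size:
        chosen = {id(c) for c in panel}
        rest = sorted(
            (c for c in survivors if id(c) not in chosen), key=lambda c: keyed[id(c)]
        )
        panel.extend(rest[: panel_size - len(panel)])
    return panel
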
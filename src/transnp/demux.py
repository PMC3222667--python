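"""Barcode demultiplexing for dual-tagged multiplex libraries.

Each sample is labelled with a 10-mer oligonucleotide ligated at both
ends of the insert. A read is assigned to an individual when its 5'
prefix exactly matches a table tag; the 3' tag (the reverse complement
of the 5' tag), when present, is clipped but never checked. Reads with
no recognizable 5' tag are left untouched and reported as unassigned.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .io_core import DataError, Read, get_logger, revcomp

__all__ = ["TagTable", "DemuxResult", "demultiplex"]

log = get_logger(__name__)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass
class TagTable:
    """Map from barcode tag sequence to (individual_id, geosite_id)."""

    tags: dict[str, tuple[str, str]]
    min_hamming: int = 3

    def __post_init__(self) -> None:
        if not self.tags:
            raise DataError("empty tag table")
        lengths = {len(t) for t in self.tags}
        if len(lengths) != 1:
            raise DataError(f"tags of mixed lengths {sorted(lengths)}")
        seqs = list(self.tags)
        for i, a in enumerate(seqs):
            for b in seqs[i + 1 :]:
                d = _hamming(a, b)
                if d < self.min_hamming:
                    raise DataError(
                        f"tags {a} and {b} at Hamming distance {d} "
                        f"< required minimum {self.min_hamming}"
                    )

    @property
    def tag_length(self) -> int:
        return len(next(iter(self.tags)))

    @classmethod
    def from_tsv(cls, path: str | Path, min_hamming: int = 3) -> "TagTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"tag", "individual_id", "geosite_id"}
        if not required <= set(df.columns):
            raise DataError(f"{path}: tag table needs columns {sorted(required)}")
        tags = {
            row.tag: (row.individual_id, row.geosite_id)
            for row in df.itertuples(index=False)
        }
        if len(tags) != len(df):
            raise DataError(f"{path}: duplicate tags")
        return cls(tags, min_hamming=min_hamming)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            [(t, ind, geo) for t, (ind, geo) in self.tags.items()],
            columns=["tag", "individual_id", "geosite_id"],
        ).to_csv(path, sep="\t", index=False)


@dataclass
class DemuxResult:
    assigned: list[Read]
    unassigned: list[Read]
    summary: Counter = field(default_factory=Counter)


def demultiplex(
    reads: list[Read],
    tags: TagTable,
    mode: str = "exact",
    max_mismatches: int = 0,
) -> DemuxResult:
    """Assign tagged reads to individuals and clip their barcodes.

    ``mode="exact"`` (default) requires a literal 5' prefix match;
    ``mode="mismatch"`` tolerates up to ``max_mismatches`` substitutions
    provided the best tag is unique at that distance. Assigned reads get
    ``individual_id``/``geosite_id`` set and the 5' tag removed (plus the
    3' tag when the suffix equals the reverse complement of the assigned
    tag); unassigned reads are returned unchanged.
    """
    if mode not in ("exact", "mismatch"):
        raise ValueError(f"unknown demultiplex mode {mode!r}")
    tlen = tags.tag_length
    assigned: list[Read] = []
    unassigned: list[Read] = []
    summary: Counter = Counter()
    for read in reads:
        if len(read.sequence) < tlen:
            unassigned.append(read)
            summary["unassigned"] += 1
            continue
        prefix = read.sequence[:tlen]
        hit = tags.tags.get(prefix)
        tag = prefix if hit is not None else None
        if hit is None and mode == "mismatch" and max_mismatches > 0:
            best = [
                t for t in tags.tags if _hamming(t, prefix) <= max_mismatches
            ]
            if len(best) == 1:
                tag = best[0]
                hit = tags.tags[tag]
        if hit is None:
            unassigned.append(read)
            summary["unassigned"] += 1
            continue
        individual, geosite = hit
        insert = read.sequence[tlen:]
        qual = list(read.quality[tlen:]) if read.quality is not None else None
        if insert.endswith(revcomp(tag)) and len(insert) > tlen:
            insert = insert[:-tlen]
            if qual is not None:
                qual = qual[:-tlen]
        assigned.append(
            Read(
                read.read_id,
                insert,
                quality=qual,
                individual_id=individual,
                geosite_id=geosite,
            )
        )
        summary[individual] += 1
    log.info(
        "demultiplex: %d assigned, %d unassigned of %d reads",
        len(assigned),
        len(unassigned),
        len(reads),
    )
    return DemuxResult(assigned, unassigned, summary)
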
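"""Core domain types, file readers/writers, configuration and logging.

The toolkit works on assembled transcript contigs, per-contig read
alignments in a simple long-form pileup table, candidate SNP descriptor
tables, and genotype call matrices from a multiplexed genotyping assay.

Coordinate convention: positions are 0-based, half-open everywhere in
memory; every human-readable output (SNP tables) uses 1-based, fully
closed positions. :func:`to_one_based` / :func:`to_zero_based` convert.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Platform",
    "IECode",
    "Read",
    "Contig",
    "PileupColumn",
    "SnpCandidate",
    "GenotypeMatrix",
    "ValidationOutcome",
    "PileupFormatError",
    "DataError",
    "ConfigError",
    "DEFAULT_GEOSITES",
    "PILEUP_COLUMNS",
    "SNP_TABLE_COLUMNS",
    "read_pileup",
    "write_pileup",
    "pileup_to_columns",
    "columns_to_frame",
    "read_snp_table",
    "write_snp_table",
    "snp_table_frame",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "load_config",
    "get_logger",
    "to_one_based",
    "to_zero_based",
    "revcomp",
]

#: Geographic sampling sites of the default discovery-panel design.
DEFAULT_GEOSITES = ("AEGS", "TYRS", "NTHS", "ATIB")

VALID_READ_BASES = frozenset("ACGTN")
VALID_PILEUP_BASES = frozenset("ACGTN-")
CALL_BASES = ("A", "C", "G", "T")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class DataError(ValueError):
    """Malformed or inconsistent input data."""


class PileupFormatError(DataError):
    """Pileup file violates the long-form TSV dialect."""


class ConfigError(ValueError):
    """Invalid parameter combination."""


def get_logger(name: str = "transnp") -> logging.Logger:
    """Structured logger writing to stderr (configured once)."""
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


log = get_logger(__name__)


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_one_based(position: int) -> int:
    """Internal 0-based position -> 1-based output position."""
    return position + 1


def to_zero_based(position: int) -> int:
    """1-based input position -> internal 0-based position."""
    return position - 1


class Platform(str, Enum):
    """Sequencing platform profile a contig was assembled from."""

    LONGREAD = "LONGREAD"
    SHORTREAD = "SHORTREAD"
    OTHER = "OTHER"


class IECode(str, Enum):
    """Outcome of the comparative intron-exon boundary test.

    ``SINGLE_EXON`` ("1"): at least one comparison placed the SNP and its
    full flanking window on a single exon. ``INTRON_DISRUPTED`` ("0"): a
    significant match exists but an intron is predicted inside the target
    region. ``NO_MATCH`` ("no"): no significant match in any reference.
    """

    SINGLE_EXON = "1"
    INTRON_DISRUPTED = "0"
    NO_MATCH = "no"


@dataclass
class Read:
    """A sequencing read, optionally tagged with its source individual."""

    read_id: str
    sequence: str
    quality: Sequence[int] | None = None
    individual_id: str | None = None
    geosite_id: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise DataError(f"read {self.read_id}: empty sequence")
        if not set(self.sequence) <= VALID_READ_BASES:
            bad = sorted(set(self.sequence) - VALID_READ_BASES)
            raise DataError(f"read {self.read_id}: invalid bases {bad}")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise DataError(f"read {self.read_id}: quality length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Contig:
    """Assembled transcript consensus sequence."""

    contig_id: str
    sequence: str
    platform: Platform = Platform.OTHER
    is_mitochondrial: bool = False

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not set(self.sequence) <= VALID_READ_BASES:
            bad = sorted(set(self.sequence) - VALID_READ_BASES)
            raise DataError(f"contig {self.contig_id}: invalid bases {bad}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PileupColumn:
    """All read observations covering one contig position.

    ``observations`` holds ``(read_id, base, individual_id, geosite_id)``
    tuples; ``individual_id``/``geosite_id`` may be ``None`` for untagged
    reads, which still count toward depth but never toward the
    individuals/geosites descriptors.
    """

    contig_id: str
    position: int
    observations: list[tuple[str, str, str | None, str | None]] = field(
        default_factory=list
    )

    @property
    def depth(self) -> int:
        """Number of unambiguous (A/C/G/T) observations."""
        return sum(1 for _, b, _, _ in self.observations if b in CALL_BASES)

    def base_counts(self) -> dict[str, int]:
        counts = {b: 0 for b in CALL_BASES}
        for _, b, _, _ in self.observations:
            if b in counts:
                counts[b] += 1
        return counts


@dataclass
class SnpCandidate:
    """A biallelic candidate SNP with its descriptor variables.

    msaf is the minor sequencing allele frequency (minor reads / depth),
    q_score the count of mismatch-bearing flank positions, snp_score the
    assay-design suitability score in [0, 1], ie_code the intron-exon
    test outcome and rank the within-contig order of choice.
    """

    contig_id: str
    position: int
    major_allele: str
    minor_allele: str
    major_count: int
    minor_count: int
    depth: int
    msaf: float
    individuals: int = 0
    geosites: int = 0
    target_region: str | None = None
    q_score: int | None = None
    snp_score: float | None = None
    ie_code: IECode | None = None
    ie_species_match: int = 0
    rank: int | None = None

    def __post_init__(self) -> None:
        if self.minor_count > self.major_count:
            raise DataError("minor_count exceeds major_count")
        if self.depth < self.major_count + self.minor_count:
            raise DataError("depth below allele count total")
        if not 0.0 < self.msaf <= 0.5:
            raise DataError(f"msaf {self.msaf} outside (0, 0.5]")


class GenotypeMatrix:
    """Loci x samples grid of biallelic genotype calls.

    Calls are ``AA``/``AB``/``BB`` with missing values as NA. Each locus
    carries a ``cluster_ok`` flag describing whether the assay produced
    interpretable genotype clusters.
    """

    def __init__(self, calls: pd.DataFrame, cluster_ok: pd.Series | None = None):
        valid = {"AA", "AB", "BB"}
        values = set(calls.stack().dropna().unique())
        if not values <= valid:
            raise DataError(f"invalid genotype calls: {sorted(values - valid)}")
        self.calls = calls
        if cluster_ok is None:
            cluster_ok = pd.Series(True, index=calls.index)
        self.cluster_ok = cluster_ok.reindex(calls.index).fillna(True).astype(bool)

    @property
    def loci(self) -> pd.Index:
        return self.calls.index

    @property
    def samples(self) -> pd.Index:
        return self.calls.columns

    def call_rates(self) -> pd.Series:
        """Fraction of non-missing calls per sample."""
        return self.calls.notna().mean(axis=0)

    @classmethod
    def from_csv(cls, path: str | Path, cluster_ok_col: str = "cluster_ok") -> "GenotypeMatrix":
        df = pd.read_csv(path, index_col=0)
        df = df.where(df.notna() & (df != "NA"))
        cluster = None
        if cluster_ok_col in df.columns:
            cluster = df.pop(cluster_ok_col).map(
                {"True": True, "False": False, True: True, False: False, 1: True, 0: False}
            )
        return cls(df, cluster)

    def to_csv(self, path: str | Path) -> None:
        out = self.calls.copy()
        out["cluster_ok"] = self.cluster_ok
        out.to_csv(path, na_rep="NA")


@dataclass
class ValidationOutcome:
    """Per-locus outcome of the genotyping validation assay."""

    locus_id: str
    snp_assay_conversion: int  # 0 failed, 1 successful
    snp_genotype: int | None = None  # 0 monomorphic, 1 polymorphic; None if failed
    maf: float | None = None
    ho: float | None = None

    def __post_init__(self) -> None:
        if self.snp_assay_conversion == 0 and self.snp_genotype is not None:
            raise DataError("snp_genotype must be absent for failed assays")
        if self.maf is not None and self.maf > 0.5 + 1e-12:
            raise DataError(f"maf {self.maf} > 0.5")


# ---------------------------------------------------------------------------
# Pileup dialect
# ---------------------------------------------------------------------------

PILEUP_COLUMNS = [
    "contig_id",
    "pos0",
    "read_id",
    "base",
    "individual_id",
    "geosite_id",
]


def read_pileup(path: str | Path) -> pd.DataFrame:
    """Read the long-form pileup TSV dialect.

    Columns: contig_id, pos0 (0-based), read_id, base, individual_id,
    geosite_id (empty string = unknown). Rows are returned sorted by
    (contig_id, pos0). Malformed rows raise :class:`PileupFormatError`
    with 1-based line numbers; duplicate (contig, position, read) triples
    and unknown base symbols are hard errors.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep="\t",
        header=0,
        dtype=str,
        keep_default_na=False,
    )
    if df.empty and list(df.columns) != PILEUP_COLUMNS:
        return pd.DataFrame(columns=PILEUP_COLUMNS).astype({"pos0": int})
    if list(df.columns) != PILEUP_COLUMNS:
        raise PileupFormatError(
            f"{path}: expected columns {PILEUP_COLUMNS}, found {list(df.columns)}"
        )
    bad_base = ~df["base"].isin(sorted(VALID_PILEUP_BASES))
    if bad_base.any():
        lines = (df.index[bad_base] + 2).tolist()[:10]
        raise PileupFormatError(f"{path}: unknown base symbol at lines {lines}")
    try:
        df["pos0"] = df["pos0"].astype(int)
    except ValueError as exc:
        raise PileupFormatError(f"{path}: non-integer position: {exc}") from exc
    if (df["pos0"] < 0).any():
        lines = (df.index[df["pos0"] < 0] + 2).tolist()[:10]
        raise PileupFormatError(f"{path}: negative position at lines {lines}")
    dup = df.duplicated(subset=["contig_id", "pos0", "read_id"], keep=False)
    if dup.any():
        lines = (df.index[dup] + 2).tolist()[:10]
        raise PileupFormatError(
            f"{path}: duplicate (contig, position, read) triple at lines {lines}"
        )
    df = df.replace({"individual_id": {"": None}, "geosite_id": {"": None}})
    return df.sort_values(["contig_id", "pos0"], kind="mergesort").reset_index(drop=True)


def write_pileup(pileup: pd.DataFrame | Iterable[PileupColumn], path: str | Path) -> None:
    """Write a pileup DataFrame or column list in the TSV dialect."""
    if not isinstance(pileup, pd.DataFrame):
        pileup = columns_to_frame(pileup)
    out = pileup[PILEUP_COLUMNS].copy()
    out["individual_id"] = out["individual_id"].fillna("")
    out["geosite_id"] = out["geosite_id"].fillna("")
    out.to_csv(path, sep="\t", index=False)


def pileup_to_columns(df: pd.DataFrame) -> list[PileupColumn]:
    """Group a pileup frame into :class:`PileupColumn` objects, sorted."""
    columns: list[PileupColumn] = []
    if df.empty:
        return columns
    for (contig, pos), grp in df.groupby(["contig_id", "pos0"], sort=True):
        obs = list(
            zip(
                grp["read_id"],
                grp["base"],
                [x if pd.notna(x) else None for x in grp["individual_id"]],
                [x if pd.notna(x) else None for x in grp["geosite_id"]],
            )
        )
        columns.append(PileupColumn(contig, int(pos), obs))
    return columns


def columns_to_frame(columns: Iterable[PileupColumn]) -> pd.DataFrame:
    rows = [
        (c.contig_id, c.position, rid, base, ind, geo)
        for c in columns
        for rid, base, ind, geo in c.observations
    ]
    return pd.DataFrame(rows, columns=PILEUP_COLUMNS)


# ---------------------------------------------------------------------------
# SNP descriptor table
# ---------------------------------------------------------------------------

SNP_TABLE_COLUMNS = [
    "contig_id",
    "position",  # 1-based in the file
    "major_allele",
    "minor_allele",
    "major_count",
    "minor_count",
    "depth",
    "msaf",
    "individuals",
    "geosites",
    "snp_score",
    "q_score",
    "ie_code",
    "ie_species_match",
    "rank",
    "target_region",
]


def snp_table_frame(candidates: Sequence[SnpCandidate]) -> pd.DataFrame:
    """Tabulate candidates with 1-based positions and stable column order."""
    rows = []
    for c in candidates:
        rows.append(
            {
                "contig_id": c.contig_id,
                "position": to_one_based(c.position),
                "major_allele": c.major_allele,
                "minor_allele": c.minor_allele,
                "major_count": c.major_count,
                "minor_count": c.minor_count,
                "depth": c.depth,
                "msaf": c.msaf,
                "individuals": c.individuals,
                "geosites": c.geosites,
                "snp_score": c.snp_score,
                "q_score": c.q_score,
                "ie_code": c.ie_code.value if c.ie_code is not None else None,
                "ie_species_match": c.ie_species_match,
                "rank": c.rank,
                "target_region": c.target_region,
            }
        )
    return pd.DataFrame(rows, columns=SNP_TABLE_COLUMNS)


def write_snp_table(candidates: Sequence[SnpCandidate], path: str | Path) -> None:
    """Write candidates as a descriptor TSV (header always present)."""
    snp_table_frame(candidates).to_csv(path, sep="\t", index=False)


def _opt_int(value) -> int | None:
    return None if pd.isna(value) else int(value)


def _opt_float(value) -> float | None:
    return None if pd.isna(value) else float(value)


def read_snp_table(path: str | Path) -> list[SnpCandidate]:
    """Read a descriptor TSV back into candidates (positions re-0-based)."""
    df = pd.read_csv(path, sep="\t", dtype={"ie_code": str})
    out = []
    for row in df.itertuples(index=False):
        ie = None
        if isinstance(row.ie_code, str) and row.ie_code:
            ie = IECode(row.ie_code)
        target = row.target_region if isinstance(row.target_region, str) else None
        out.append(
            SnpCandidate(
                contig_id=row.contig_id,
                position=to_zero_based(int(row.position)),
                major_allele=row.major_allele,
                minor_allele=row.minor_allele,
                major_count=int(row.major_count),
                minor_count=int(row.minor_count),
                depth=int(row.depth),
                msaf=float(row.msaf),
                individuals=int(row.individuals),
                geosites=int(row.geosites),
                target_region=target,
                q_score=_opt_int(row.q_score),
                snp_score=_opt_float(row.snp_score),
                ie_code=ie,
                ie_species_match=int(row.ie_species_match),
                rank=_opt_int(row.rank),
            )
        )
    return out


# ---------------------------------------------------------------------------
# FASTA / FASTQ / config
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, platform: Platform = Platform.OTHER) -> list[Contig]:
    return [
        Contig(rec.id, str(rec.seq).upper(), platform=platform)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(sequences: Mapping[str, str] | Sequence[Contig], path: str | Path) -> None:
    if isinstance(sequences, Mapping):
        records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    else:
        records = [
            SeqRecord(Seq(c.sequence), id=c.contig_id, description="") for c in sequences
        ]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path) -> list[Read]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            Read(
                rec.id,
                str(rec.seq).upper(),
                quality=rec.letter_annotations.get("phred_quality"),
            )
        )
    return reads


def write_fastq(reads: Sequence[Read], path: str | Path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        qual = r.quality if r.quality is not None else [40] * len(r.sequence)
        rec.letter_annotations["phred_quality"] = list(qual)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def load_config(path: str | Path) -> dict:
    """Load a YAML key-value configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: configuration must be a mapping")
    return cfg
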
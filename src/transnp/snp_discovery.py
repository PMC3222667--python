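"""Candidate SNP calling from read pileups and discovery summaries.

A column is called as a candidate SNP when exactly two unambiguous
alleles each have at least ``min_allele_reads`` supporting reads and the
unambiguous depth is at least ``min_depth``. Gap observations never
count as alleles and never disqualify a column; columns where three or
more alleles reach the read threshold are rejected as multiallelic
(the downstream genotyping chemistry is strictly biallelic). Indels are
never called.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_core import (
    CALL_BASES,
    ConfigError,
    Contig,
    DataError,
    GenotypeMatrix,
    PileupColumn,
    SnpCandidate,
    ValidationOutcome,
)

__all__ = [
    "call_snps",
    "DiscoverySummary",
    "summarize_discovery",
    "snp_density_per_100bp",
    "compute_locus_stats",
]


def _candidate_from_counts(
    contig_id: str,
    position: int,
    counts: dict[str, int],
    individuals: int,
    geosites: int,
    min_depth: int,
    min_allele_reads: int,
) -> SnpCandidate | None:
    depth = sum(counts.values())
    alleles = [b for b in CALL_BASES if counts[b] >= min_allele_reads]
    if len(alleles) != 2 or depth < min_depth:
        return None
    a, b = alleles
    # tie at msaf 0.5 broken lexicographically: first base is major
    if counts[a] > counts[b] or (counts[a] == counts[b] and a < b):
        major, minor = a, b
    else:
        major, minor = b, a
    return SnpCandidate(
        contig_id=contig_id,
        position=position,
        major_allele=major,
        minor_allele=minor,
        major_count=counts[major],
        minor_count=counts[minor],
        depth=depth,
        msaf=counts[minor] / depth,
        individuals=individuals,
        geosites=geosites,
    )


def call_snps(
    pileup: Sequence[PileupColumn] | pd.DataFrame,
    min_depth: int = 4,
    min_allele_reads: int = 2,
) -> list[SnpCandidate]:
    """Call biallelic candidate SNPs from pileup columns.

    Accepts either a list of :class:`PileupColumn` or a long-form pileup
    DataFrame (possibly spanning several contigs). Depth counts only
    A/C/G/T observations; individuals/geosites count distinct labelled
    sources contributing at least one read covering the site.
    """
    if 2 * min_allele_reads > min_depth:
        raise ConfigError(
            f"min_allele_reads*2 = {2 * min_allele_reads} exceeds min_depth {min_depth}"
        )
    if isinstance(pileup, pd.DataFrame):
        return _call_snps_frame(pileup, min_depth, min_allele_reads)
    out: list[SnpCandidate] = []
    for col in pileup:
        obs = [(r, b, i, g) for r, b, i, g in col.observations if b in CALL_BASES]
        counts = {b: 0 for b in CALL_BASES}
        inds, geos = set(), set()
        for _, b, ind, geo in obs:
            counts[b] += 1
            if ind is not None:
                inds.add(ind)
            if geo is not None:
                geos.add(geo)
        cand = _candidate_from_counts(
            col.contig_id, col.position, counts, len(inds), len(geos),
            min_depth, min_allele_reads,
        )
        if cand is not None:
            out.append(cand)
    out.sort(key=lambda c: (c.contig_id, c.position))
    return out


def _call_snps_frame(
    df: pd.DataFrame, min_depth: int, min_allele_reads: int
) -> list[SnpCandidate]:
    """Vectorized calling over a long-form pileup frame."""
    if df.empty:
        return []
    df = df[df["base"].isin(CALL_BASES)]
    if df.empty:
        return []
    counts = (
        df.groupby(["contig_id", "pos0", "base"], observed=True)
        .size()
        .unstack("base", fill_value=0)
        .reindex(columns=list(CALL_BASES), fill_value=0)
    )
    arr = counts.to_numpy()
    depth = arr.sum(axis=1)
    n_alleles = (arr >= min_allele_reads).sum(axis=1)
    keep = (n_alleles == 2) & (depth >= min_depth)
    if not keep.any():
        return []
    sites = counts.index[keep]
    site_df = df.set_index(["contig_id", "pos0"]).loc[sites]
    grouped = site_df.groupby(level=[0, 1], observed=True)
    n_ind = grouped["individual_id"].nunique(dropna=True)
    n_geo = grouped["geosite_id"].nunique(dropna=True)
    out = []
    for (contig, pos), row in counts.loc[sites].iterrows():
        cand = _candidate_from_counts(
            contig,
            int(pos),
            {b: int(row[b]) for b in CALL_BASES},
            int(n_ind.get((contig, pos), 0)),
            int(n_geo.get((contig, pos), 0)),
            min_depth,
            min_allele_reads,
        )
        if cand is not None:
            out.append(cand)
    out.sort(key=lambda c: (c.contig_id, c.position))
    return out


@dataclass
class DiscoverySummary:
    """Dataset-level summary of a SNP discovery run."""

    n_contigs: int
    n_snp_contigs: int
    n_candidates: int
    mean_contig_length: float
    mean_depth_at_snp: float
    snps_per_100bp: float
    snps_per_mbp: float | None
    snps_per_contig_histogram: dict[int, int]


def snp_density_per_100bp(n_candidates: int, total_snp_contig_bp: float) -> float:
    """SNPs per 100 bp of SNP-containing contig sequence surveyed."""
    if total_snp_contig_bp <= 0:
        raise DataError("zero-length density denominator")
    return 100.0 * n_candidates / total_snp_contig_bp


def summarize_discovery(
    contigs: Sequence[Contig],
    candidates: Sequence[SnpCandidate],
    total_sequenced_mbp: float | None = None,
) -> DiscoverySummary:
    """Summarize discovery output.

    The per-100-bp density is computed over the cumulative length of
    SNP-containing contigs only (the surveyed transcriptome); the
    per-Mbp density divides by the total amount of sequence generated.
    """
    lengths = {c.contig_id: len(c) for c in contigs}
    unknown = {c.contig_id for c in candidates} - set(lengths)
    if unknown:
        raise DataError(f"candidates reference unknown contigs {sorted(unknown)[:5]}")
    per_contig = pd.Series([c.contig_id for c in candidates]).value_counts()
    snp_contigs = list(per_contig.index)
    snp_bp = float(sum(lengths[c] for c in snp_contigs))
    if candidates:
        density_100bp = snp_density_per_100bp(len(candidates), snp_bp)
        mean_len = snp_bp / len(snp_contigs)
        mean_depth = float(np.mean([c.depth for c in candidates]))
    else:
        density_100bp = 0.0
        mean_len = float(np.mean([len(c) for c in contigs])) if contigs else 0.0
        mean_depth = 0.0
    per_mbp: float | None = None
    if total_sequenced_mbp is not None:
        if total_sequenced_mbp <= 0:
            raise DataError("total_sequenced_mbp must be positive")
        per_mbp = len(candidates) / total_sequenced_mbp
    hist = per_contig.value_counts().sort_index()
    return DiscoverySummary(
        n_contigs=len(contigs),
        n_snp_contigs=len(snp_contigs),
        n_candidates=len(candidates),
        mean_contig_length=mean_len,
        mean_depth_at_snp=mean_depth,
        snps_per_100bp=density_100bp,
        snps_per_mbp=per_mbp,
        snps_per_contig_histogram={int(k): int(v) for k, v in hist.items()},
    )


def compute_locus_stats(matrix: GenotypeMatrix) -> list[ValidationOutcome]:
    """Per-locus conversion, polymorphism, MAF and Ho from genotype calls.

    A locus converts when its assay clustered (``cluster_ok``) and at
    least one sample was called. For converted loci, MAF is the minor
    allele frequency among called genotypes and Ho the heterozygote
    fraction; a locus is polymorphic when both alleles are observed.
    """
    out: list[ValidationOutcome] = []
    for locus in matrix.loci:
        calls = matrix.calls.loc[locus].dropna()
        if not matrix.cluster_ok.loc[locus] or len(calls) == 0:
            out.append(ValidationOutcome(str(locus), 0))
            continue
        n_aa = int((calls == "AA").sum())
        n_ab = int((calls == "AB").sum())
        n_bb = int((calls == "BB").sum())
        n = n_aa + n_ab + n_bb
        freq_b = (2 * n_bb + n_ab) / (2 * n)
        maf = min(freq_b, 1.0 - freq_b)
        ho = n_ab / n
        polymorphic = int(maf > 0 or n_ab > 0)
        out.append(ValidationOutcome(str(locus), 1, polymorphic, maf, ho))
    return out
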
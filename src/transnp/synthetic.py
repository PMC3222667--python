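"""Synthetic data generator: transcriptomes, genotypes, tagged reads and
truth tables emulating a two-platform discovery experiment.

The generator emulates the structure of a multi-site discovery panel:
individuals drawn from four geographic sites, a non-normalized muscle
transcriptome assembled into contigs, and reads sampled under one of two
platform profiles — a long-read profile (reads around 206 bp, low error,
modest depth) and a short-read profile (74 bp reads, higher error, deep
coverage). SNPs are planted per site under a Beta allele-frequency
prior, genotypes drawn under Hardy-Weinberg within geosites, and a
companion "model species" reference (genome with planted introns,
transcriptome, proteome from the true reading frames) is derived from
the contigs so that every downstream stage can be tested against known
truth.

All randomness flows from a mandatory seed through one generator, so a
given configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .demux import TagTable
from .io_core import (
    DEFAULT_GEOSITES,
    ConfigError,
    Contig,
    Platform,
    Read,
    SnpCandidate,
    write_fasta,
    write_fastq,
    write_pileup,
)
from .comparative_annotation import ReferenceSet

__all__ = [
    "PlatformProfile",
    "LONGREAD_PROFILE",
    "SHORTREAD_PROFILE",
    "SimConfig",
    "TruthTable",
    "SimulatedDataset",
    "simulate_dataset",
    "TruthComparison",
    "truth_compare",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


@dataclass(frozen=True)
class PlatformProfile:
    """Read length / error / depth targets of a sequencing platform."""

    name: str
    read_length_mean: float
    read_length_sd: float
    error_rate: float
    mean_depth: float


#: Long-read pyrosequencing-style profile: ~206 bp reads, 0.3% error,
#: tens-fold depth.
LONGREAD_PROFILE = PlatformProfile("longread", 206.0, 50.0, 0.003, 30.0)
#: Short-read profile: fixed 74 bp reads, 1% error, very deep coverage.
SHORTREAD_PROFILE = PlatformProfile("shortread", 74.0, 0.0, 0.01, 600.0)


@dataclass
class SimConfig:
    """Configuration of one simulated discovery experiment."""

    seed: int
    n_contigs: int = 200
    contig_length_median: float = 300.0
    contig_length_sigma: float = 0.5
    contig_min_length: int = 100
    contig_max_length: int = 5000
    n_individuals: int = 8
    geosites: Sequence[str] = DEFAULT_GEOSITES
    snp_rate: float = 0.01
    maf_alpha: float = 1.2
    maf_beta: float = 3.0
    profile: PlatformProfile = LONGREAD_PROFILE
    barcode: bool = True
    mito_fraction: float = 0.02
    intron_rate: float = 0.0015
    intron_length_min: int = 100
    intron_length_max: int = 800
    fst: float = 0.0
    divergence: float = 0.0
    cds_fraction: float = 0.6
    tag_length: int = 10

    def __post_init__(self) -> None:
        for name in ("snp_rate", "mito_fraction", "intron_rate", "fst", "divergence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} = {v} outside [0, 1]")
        if self.profile.mean_depth <= 0:
            raise ConfigError("profile mean depth must be positive")
        if self.n_individuals < 1 or self.n_contigs < 1:
            raise ConfigError("need at least one individual and one contig")


@dataclass
class TruthTable:
    """Ground truth of a simulated dataset.

    ``snps`` lists planted SNPs with population and realized panel minor
    allele frequencies plus pre-error sampled read counts per allele;
    ``genotypes`` holds per-individual alternate-allele counts (0/1/2);
    ``contigs`` the mitochondrial flags and true coding frames;
    ``introns`` the reference-genome insertion points (contig
    coordinates); ``read_counts`` the per-individual read totals.
    """

    snps: pd.DataFrame
    genotypes: pd.DataFrame
    contigs: pd.DataFrame
    introns: pd.DataFrame
    read_counts: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.snps.to_csv(outdir / "truth_snps.tsv", sep="\t", index=False)
        self.genotypes.to_csv(outdir / "truth_genotypes.tsv", sep="\t")
        self.contigs.to_csv(outdir / "truth_contigs.tsv", sep="\t", index=False)
        self.introns.to_csv(outdir / "truth_introns.tsv", sep="\t", index=False)
        self.read_counts.to_csv(outdir / "truth_read_counts.tsv", sep="\t", index=False)


@dataclass
class SimulatedDataset:
    """In-memory bundle produced by :func:`simulate_dataset`."""

    config: SimConfig
    contigs: list[Contig]
    reads: list[Read]
    pileup: pd.DataFrame
    reference: ReferenceSet
    truth: TruthTable
    tag_table: TagTable | None = None

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.contigs, outdir / "contigs.fasta")
        write_fastq(self.reads, outdir / "reads.fastq")
        write_pileup(self.pileup, outdir / "pileup.tsv")
        write_fasta(self.reference.genome, outdir / "reference_genome.fasta")
        write_fasta(self.reference.transcriptome, outdir / "reference_transcriptome.fasta")
        write_fasta(self.reference.proteome, outdir / "reference_proteome.fasta")
        if self.tag_table is not None:
            self.tag_table.to_tsv(outdir / "tags.tsv")
        self.truth.write(outdir)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _make_tags(rng: np.random.Generator, n: int, length: int, min_dist: int = 5) -> list[str]:
    tags: list[str] = []
    while len(tags) < n:
        cand = _random_seq(rng, length)
        if all(sum(a != b for a, b in zip(cand, t)) >= min_dist for t in tags):
            tags.append(cand)
    return tags


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    """Substitute bases at the given per-base rate (uint8 code array)."""
    if rate <= 0:
        return seq
    seq = seq.copy()
    mask = rng.random(len(seq)) < rate
    n = int(mask.sum())
    if n:
        shift = rng.integers(1, 4, size=n)
        idx = np.searchsorted(_BASES, seq[mask])
        seq[mask] = _BASES[(idx + shift) % 4]
    return seq


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate contigs, genotypes, reads, pileup, references and truth."""
    rng = np.random.default_rng(config.seed)
    geosites = list(config.geosites)
    individuals = [f"I{i + 1:02d}" for i in range(config.n_individuals)]
    ind_geo = {ind: geosites[i % len(geosites)] for i, ind in enumerate(individuals)}

    n_mito = int(round(config.mito_fraction * config.n_contigs))
    mito_genome = _random_seq(rng, 16000)

    lengths = np.exp(
        rng.normal(np.log(config.contig_length_median), config.contig_length_sigma,
                   size=config.n_contigs)
    )
    lengths = np.clip(np.round(lengths), config.contig_min_length,
                      config.contig_max_length).astype(int)

    contigs: list[Contig] = []
    contig_rows = []
    snp_rows = []
    geno_rows = []
    platform = (
        Platform.LONGREAD if config.profile.name == "longread"
        else Platform.SHORTREAD if config.profile.name == "shortread"
        else Platform.OTHER
    )
    snp_registry: dict[str, dict] = {}
    for i in range(config.n_contigs):
        cid = f"ctg{i + 1:04d}"
        length = int(lengths[i])
        is_mito = i < n_mito
        if is_mito:
            start = int(rng.integers(0, len(mito_genome) - length))
            seq = mito_genome[start : start + length]
            cds_start = cds_end = -1
        else:
            seq_arr = rng.choice(_BASES, size=length)
            cds_len = 3 * int(length * config.cds_fraction // 3)
            cds_start = int(rng.integers(0, length - cds_len + 1)) if cds_len else 0
            cds_end = cds_start + cds_len
            if cds_len:
                codons = rng.choice(len(_CODONS), size=cds_len // 3)
                cds = "".join(_CODONS[j] for j in codons)
                seq = (
                    seq_arr[:cds_start].tobytes().decode()
                    + cds
                    + seq_arr[cds_end:].tobytes().decode()
                )
            else:
                seq = seq_arr.tobytes().decode()
        contigs.append(Contig(cid, seq, platform=platform, is_mitochondrial=is_mito))
        contig_rows.append((cid, length, is_mito, cds_start, cds_end))

        if is_mito:
            continue
        snp_mask = rng.random(length) < config.snp_rate
        positions = np.flatnonzero(snp_mask)
        for pos in positions:
            ref = seq[pos]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            p_alt = float(rng.beta(config.maf_alpha, config.maf_beta))
            if config.fst > 0:
                f = config.fst
                site_p = {
                    g: float(
                        rng.beta(
                            max(p_alt * (1 - f) / f, 1e-3),
                            max((1 - p_alt) * (1 - f) / f, 1e-3),
                        )
                    )
                    for g in geosites
                }
            else:
                site_p = {g: p_alt for g in geosites}
            genos = {
                ind: int(rng.binomial(2, site_p[ind_geo[ind]]))
                for ind in individuals
            }
            alt_total = sum(genos.values())
            freq = alt_total / (2 * len(individuals))
            snp_registry.setdefault(cid, {})[int(pos)] = {
                "ref": ref,
                "alt": alt,
                "genotypes": genos,
                "pop_maf": min(p_alt, 1 - p_alt),
                "panel_maf": min(freq, 1 - freq),
                "alt_reads": 0,
                "ref_reads": 0,
            }
            geno_rows.append({"contig_id": cid, "pos0": int(pos), **genos})

    # ------------------------------------------------------------------
    # Reads and pileup
    # ------------------------------------------------------------------
    profile = config.profile
    tag_table = None
    tags = {}
    if config.barcode:
        tag_seqs = _make_tags(rng, config.n_individuals, config.tag_length)
        tags = {ind: tag_seqs[j] for j, ind in enumerate(individuals)}
        tag_table = TagTable(
            {tags[ind]: (ind, ind_geo[ind]) for ind in individuals}, min_hamming=5
        )

    reads: list[Read] = []
    pileup_contig, pileup_pos, pileup_read, pileup_base = [], [], [], []
    pileup_ind, pileup_geo = [], []
    read_counts = {ind: 0 for ind in individuals}
    n_ind = len(individuals)

    for i, contig in enumerate(contigs):
        cid = contig.contig_id
        length = len(contig)
        ref_arr = np.frombuffer(contig.sequence.encode(), dtype=np.uint8)
        contig_snps = snp_registry.get(cid, {})
        snp_pos = np.array(sorted(contig_snps), dtype=int)
        # per-individual haplotypes (two per individual)
        haplotypes = {}
        for ind in individuals:
            h0, h1 = ref_arr.copy(), ref_arr.copy()
            for pos in snp_pos:
                info = contig_snps[int(pos)]
                g = info["genotypes"][ind]
                carries = [False, False]
                if g == 2:
                    carries = [True, True]
                elif g == 1:
                    which = int(rng.integers(2))
                    carries[which] = True
                if carries[0]:
                    h0[pos] = ord(info["alt"])
                if carries[1]:
                    h1[pos] = ord(info["alt"])
            haplotypes[ind] = (h0, h1)

        total_reads = max(1, int(round(profile.mean_depth * length / profile.read_length_mean)))
        base_n, rem = divmod(total_reads, n_ind)
        rotation = i % n_ind
        per_ind = {
            ind: base_n + (1 if (j - rotation) % n_ind < rem else 0)
            for j, ind in enumerate(individuals)
        }
        for ind in individuals:
            geo = ind_geo[ind]
            n_reads = per_ind[ind]
            read_counts[ind] += n_reads
            for r in range(n_reads):
                if profile.read_length_sd > 0:
                    rl = int(round(rng.normal(profile.read_length_mean,
                                              profile.read_length_sd)))
                else:
                    rl = int(profile.read_length_mean)
                rl = max(30, min(rl, length))
                start = int(rng.integers(0, length - rl + 1))
                hap = int(rng.integers(2))
                template = haplotypes[ind][hap][start : start + rl]
                # pre-error sampled allele bookkeeping
                if len(snp_pos):
                    inside = snp_pos[(snp_pos >= start) & (snp_pos < start + rl)]
                    for pos in inside:
                        info = contig_snps[int(pos)]
                        if chr(template[pos - start]) == info["alt"]:
                            info["alt_reads"] += 1
                        else:
                            info["ref_reads"] += 1
                observed = _mutate(rng, template, profile.error_rate)
                seq = observed.tobytes().decode()
                read_id = f"{cid}:{ind}:{r}"
                raw = seq
                if config.barcode:
                    tag = tags[ind]
                    raw = tag + seq + str(Seq(tag).reverse_complement())
                reads.append(Read(read_id, raw))
                pileup_contig.append(np.full(rl, i, dtype=np.int32))
                pileup_pos.append(np.arange(start, start + rl, dtype=np.int32))
                pileup_read.extend([read_id] * rl)
                pileup_base.append(observed)
                pileup_ind.extend([ind] * rl)
                pileup_geo.extend([geo] * rl)

    contig_ids = [c.contig_id for c in contigs]
    if pileup_contig:
        codes = np.concatenate(pileup_contig)
        pileup = pd.DataFrame(
            {
                "contig_id": pd.Categorical.from_codes(codes, categories=contig_ids).astype(str),
                "pos0": np.concatenate(pileup_pos),
                "read_id": pileup_read,
                "base": np.array(
                    list(np.concatenate(pileup_base).tobytes().decode())
                ),
                "individual_id": pileup_ind,
                "geosite_id": pileup_geo,
            }
        )
        pileup = pileup.sort_values(["contig_id", "pos0"], kind="mergesort").reset_index(
            drop=True
        )
    else:
        pileup = pd.DataFrame(
            columns=["contig_id", "pos0", "read_id", "base", "individual_id", "geosite_id"]
        )

    # ------------------------------------------------------------------
    # Companion model-species reference
    # ------------------------------------------------------------------
    genome, transcriptome, proteome = {}, {}, {}
    exon_map = {}
    intron_rows = []
    for contig, (cid, length, is_mito, cds_start, cds_end) in zip(contigs, contig_rows):
        if is_mito:
            continue
        hom = _mutate(
            rng, np.frombuffer(contig.sequence.encode(), dtype=np.uint8),
            config.divergence,
        )
        hom_seq = hom.tobytes().decode()
        cut_mask = rng.random(max(length - 1, 0)) < config.intron_rate
        cuts = (np.flatnonzero(cut_mask) + 1).tolist()
        pieces = []
        exons = []
        gpos = 0
        prev = 0
        for cut in cuts + [length]:
            exon = hom_seq[prev:cut]
            pieces.append(exon)
            exons.append((gpos, gpos + len(exon)))
            gpos += len(exon)
            if cut < length:
                ilen = int(
                    rng.integers(config.intron_length_min, config.intron_length_max + 1)
                )
                pieces.append(_random_seq(rng, ilen))
                intron_rows.append((cid, int(cut), ilen))
                gpos += ilen
            prev = cut
        genome[f"g_{cid}"] = "".join(pieces)
        transcriptome[f"t_{cid}"] = hom_seq
        exon_map[f"t_{cid}"] = [(s, e) for s, e in exons]
        if cds_end > cds_start:
            pep = str(Seq(hom_seq[cds_start:cds_end]).translate()).replace("*", "X")
            proteome[f"p_{cid}"] = pep
    reference = ReferenceSet(
        species_id="simref",
        genome=genome,
        transcriptome=transcriptome,
        proteome=proteome,
        exon_map=exon_map,
    )
    # mitochondrial reference for flagging
    reference.genome["mito_reference"] = mito_genome

    snp_rows = []
    for cid, positions in snp_registry.items():
        for pos, info in sorted(positions.items()):
            snp_rows.append(
                (
                    cid,
                    pos,
                    info["ref"],
                    info["alt"],
                    info["pop_maf"],
                    info["panel_maf"],
                    info["alt_reads"],
                    info["ref_reads"],
                )
            )
    truth = TruthTable(
        snps=pd.DataFrame(
            snp_rows,
            columns=[
                "contig_id",
                "pos0",
                "ref",
                "alt",
                "pop_maf",
                "panel_maf",
                "alt_reads",
                "ref_reads",
            ],
        ),
        genotypes=pd.DataFrame(geno_rows).set_index(["contig_id", "pos0"])
        if geno_rows
        else pd.DataFrame(),
        contigs=pd.DataFrame(
            contig_rows,
            columns=["contig_id", "length", "is_mitochondrial", "cds_start", "cds_end"],
        ),
        introns=pd.DataFrame(intron_rows, columns=["contig_id", "pos0", "length"]),
        read_counts=pd.DataFrame(
            sorted(read_counts.items()), columns=["individual_id", "n_reads"]
        ),
    )
    return SimulatedDataset(
        config=config,
        contigs=contigs,
        reads=reads,
        pileup=pileup,
        reference=reference,
        truth=truth,
        tag_table=tag_table,
    )


@dataclass
class TruthComparison:
    """Calling performance against planted truth."""

    sensitivity: float | None
    false_positives: int
    msaf_bias: float | None
    msaf_abs_errors: np.ndarray = field(default_factory=lambda: np.array([]))
    n_eligible: int = 0


def truth_compare(
    called: Sequence[SnpCandidate],
    truth: TruthTable,
    min_minor_reads: int = 2,
) -> TruthComparison:
    """Compare called candidates with the planted truth.

    Sensitivity is computed over planted SNPs whose minor allele class
    was sampled by at least ``min_minor_reads`` reads (and the major by
    the same margin) — SNPs the count rules could possibly call. Every
    called site not planted counts as a false positive. The MSAF bias is
    the mean of (msaf - realized panel minor allele frequency) over
    called planted sites.
    """
    planted = {
        (r.contig_id, int(r.pos0)): r for r in truth.snps.itertuples(index=False)
    }
    eligible = {
        key
        for key, r in planted.items()
        if min(r.alt_reads, r.ref_reads) >= min_minor_reads
    }
    called_keys = {(c.contig_id, c.position) for c in called}
    sensitivity = (
        len(called_keys & eligible) / len(eligible) if eligible else None
    )
    false_positives = len(called_keys - set(planted))
    errors = []
    for c in called:
        rec = planted.get((c.contig_id, c.position))
        if rec is not None:
            errors.append(c.msaf - rec.panel_maf)
    errors = np.asarray(errors, dtype=float)
    bias = float(errors.mean()) if len(errors) else None
    return TruthComparison(
        sensitivity=sensitivity,
        false_positives=false_positives,
        msaf_bias=bias,
        msaf_abs_errors=np.abs(errors),
        n_eligible=len(eligible),
    )
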
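"""Local alignment, intron-exon routes, effect classification, GO tests."""

from __future__ import annotations

import pytest

from transnp.align import LocalAligner
from transnp.comparative_annotation import (
    EffectClass,
    ReferenceSet,
    classify_codon_change,
    classify_effect,
    combine_ie,
    flag_mitochondrial,
    go_enrichment,
    ie_route_a,
    ie_route_b,
)
from transnp.io_core import Contig, IECode, SnpCandidate, revcomp
from Bio.Seq import Seq

from conftest import random_seq
from oracles import (
    all_single_base_codon_changes,
    effect_oracle,
    smith_waterman_score,
)


class TestLocalAligner:
    def test_exact_substring_full_span_hit(self, rng):
        subject = random_seq(rng, 600)
        query = subject[150:350]
        aligner = LocalAligner({"s1": subject})
        hit = aligner.best_hit("q", query)
        assert hit is not None
        assert hit.score == 2.0 * len(query)
        assert (hit.query_start, hit.query_end) == (0, 200)
        assert (hit.subject_start, hit.subject_end) == (150, 350)

    def test_reverse_strand_hit_found(self, rng):
        subject = random_seq(rng, 500)
        query = revcomp(subject[100:300])
        hit = LocalAligner({"s1": subject}).best_hit("q", query)
        assert hit is not None
        assert hit.strand == "-"
        assert (hit.subject_start, hit.subject_end) == (100, 300)

    def test_unrelated_random_sequences_give_no_hit(self, rng):
        """Shuffled-sequence false-hit calibration at the default cutoff."""
        misses = 0
        trials = 200
        for _ in range(trials):
            subject = random_seq(rng, 2000)
            query = random_seq(rng, 300)
            if LocalAligner({"s1": subject}).best_hit("q", query) is None:
                misses += 1
        assert misses == trials

    def test_score_agrees_with_dynamic_programming_oracle(self, rng):
        """Seed-and-extend equals full Smith-Waterman on short pairs."""
        for _ in range(6):
            core = random_seq(rng, 90)
            query = random_seq(rng, 40) + core + random_seq(rng, 40)
            mutated = list(core)
            for pos in rng.choice(len(core), size=5, replace=False):
                mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
            subject = random_seq(rng, 30) + "".join(mutated) + random_seq(rng, 30)
            aligner = LocalAligner({"s": subject}, min_score=10)
            hit = aligner.best_hit("q", query)
            fwd = smith_waterman_score(query, subject)
            rev = smith_waterman_score(revcomp(query), subject)
            assert hit is not None
            assert hit.score == pytest.approx(max(fwd, rev))

    def test_empty_subject_set_gives_none(self):
        assert LocalAligner({}).best_hit("q", "ACGT" * 30) is None


class TestIntronExonRoutes:
    def _fixture(self, rng, intron_at=None, intron_len=500):
        contig = Contig("ctg", random_seq(rng, 400))
        genome_seq = contig.sequence
        if intron_at is not None:
            genome_seq = (
                contig.sequence[:intron_at]
                + random_seq(rng, intron_len)
                + contig.sequence[intron_at:]
            )
        ref = ReferenceSet("sp1", genome={"chr1": genome_seq})
        return contig, ref

    def test_genome_equals_contig_single_exon(self, rng):
        contig, ref = self._fixture(rng)
        for pos in (60, 200, 339):
            assert ie_route_a(contig, pos, ref) == IECode.SINGLE_EXON

    def test_insert_downstream_of_snp_disrupts(self, rng):
        contig, ref = self._fixture(rng, intron_at=210)  # 10 bp downstream of SNP
        assert ie_route_a(contig, 200, ref) == IECode.INTRON_DISRUPTED

    def test_insert_outside_window_does_not_disrupt(self, rng):
        contig, ref = self._fixture(rng, intron_at=300)
        assert ie_route_a(contig, 200, ref) == IECode.SINGLE_EXON

    def test_unrelated_genome_no_match(self, rng):
        contig = Contig("ctg", random_seq(rng, 400))
        ref = ReferenceSet("sp1", genome={"chr1": random_seq(rng, 3000)})
        assert ie_route_a(contig, 200, ref) == IECode.NO_MATCH

    def test_route_b_single_exon_transcript(self, rng):
        contig = Contig("ctg", random_seq(rng, 400))
        ref = ReferenceSet(
            "sp1",
            transcriptome={"t1": contig.sequence},
            exon_map={"t1": [(0, 400)]},
        )
        assert ie_route_b(contig, 200, ref) == IECode.SINGLE_EXON

    def test_route_b_exon_boundary_near_snp_disrupts(self, rng):
        contig = Contig("ctg", random_seq(rng, 400))
        # homolog transcript with an exon boundary 20 bp from the SNP
        ref = ReferenceSet(
            "sp1",
            transcriptome={"t1": contig.sequence},
            exon_map={"t1": [(0, 220), (700, 880)]},
        )
        assert ie_route_b(contig, 200, ref) == IECode.INTRON_DISRUPTED

    def test_route_b_no_homolog(self, rng):
        contig = Contig("ctg", random_seq(rng, 400))
        ref = ReferenceSet("sp1", transcriptome={"t1": random_seq(rng, 900)})
        assert ie_route_b(contig, 200, ref) == IECode.NO_MATCH

    def test_route_b_snp_outside_aligned_region(self, rng):
        contig = Contig("ctg", random_seq(rng, 400))
        # homolog covers only the first 150 bases of the contig
        ref = ReferenceSet(
            "sp1",
            transcriptome={"t1": contig.sequence[:150] + random_seq(rng, 300)},
        )
        assert ie_route_b(contig, 300, ref) == IECode.NO_MATCH


class TestCombineIE:
    def test_mixed_codes_single_exon_wins(self):
        code, matches = combine_ie(
            [IECode.SINGLE_EXON, IECode.INTRON_DISRUPTED, IECode.NO_MATCH]
        )
        assert code == IECode.SINGLE_EXON
        assert matches == 2

    def test_all_no_match(self):
        code, matches = combine_ie([IECode.NO_MATCH] * 5)
        assert code == IECode.NO_MATCH
        assert matches == 0

    def test_matches_precedence_oracle_on_all_code_sets(self):
        from itertools import product

        for codes in product(list(IECode), repeat=3):
            code, matches = combine_ie(codes)
            if IECode.SINGLE_EXON in codes:
                expected = IECode.SINGLE_EXON
            elif IECode.INTRON_DISRUPTED in codes:
                expected = IECode.INTRON_DISRUPTED
            else:
                expected = IECode.NO_MATCH
            assert code == expected
            assert matches == sum(1 for c in codes if c != IECode.NO_MATCH)
            assert (matches == 0) == (code == IECode.NO_MATCH)


class TestEffectClassification:
    def test_gly_codon_third_position_synonymous(self):
        cls, nonsense = classify_codon_change("GGA", "GGG")
        assert cls == EffectClass.SYNONYMOUS
        assert not nonsense

    def test_lys_to_glu_nonconservative(self):
        cls, _ = classify_codon_change("AAA", "GAA")
        assert cls == EffectClass.NONSYN_NONCONSERVATIVE

    def test_introduced_stop_is_flagged_nonsense(self):
        cls, nonsense = classify_codon_change("TAC", "TAA")
        assert cls == EffectClass.NONSYN_NONCONSERVATIVE
        assert nonsense

    def test_all_576_single_base_codon_changes_match_oracle(self):
        for ref, alt in all_single_base_codon_changes():
            cls, _ = classify_codon_change(ref, alt)
            assert cls.value == effect_oracle(ref, alt), (ref, alt)

    def _coding_fixture(self, rng, n_codons=80):
        from oracles import GENETIC_CODE

        codons = [c for c in GENETIC_CODE if GENETIC_CODE[c] != "*"]
        cds = "".join(rng.choice(codons) for _ in range(n_codons))
        utr5, utr3 = random_seq(rng, 17), random_seq(rng, 23)
        contig = Contig("ctg", utr5 + cds + utr3)
        protein = str(Seq(cds).translate())
        return contig, len(utr5), cds, protein

    def test_frame_inferred_and_classification_correct(self, rng):
        contig, cds_start, cds, protein = self._coding_fixture(rng)
        proteomes = {"sp": {"p1": protein}}
        pos = cds_start + 100  # inside codon 33, offset 1
        ref_base = contig.sequence[pos]
        alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref_base]
        snp = SnpCandidate("ctg", pos, ref_base, alt, 6, 3, 9, 1 / 3,
                           target_region="x")
        call = classify_effect(contig, snp, proteomes)
        ci = (pos - cds_start) // 3
        codon = cds[3 * ci : 3 * ci + 3]
        within = (pos - cds_start) % 3
        alt_codon = codon[:within] + alt + codon[within + 1 :]
        assert call.codon_ref == codon
        assert call.codon_alt == alt_codon
        assert call.classification.value == effect_oracle(codon, alt_codon)

    def test_strand_consistency_under_reverse_complement(self, rng):
        contig, cds_start, cds, protein = self._coding_fixture(rng)
        proteomes = {"sp": {"p1": protein}}
        pos = cds_start + 61
        ref_base = contig.sequence[pos]
        alt = {"A": "C", "C": "A", "G": "T", "T": "G"}[ref_base]
        snp = SnpCandidate("ctg", pos, ref_base, alt, 6, 3, 9, 1 / 3,
                           target_region="x")
        fwd = classify_effect(contig, snp, proteomes)
        rc_contig = Contig("ctg", revcomp(contig.sequence))
        rc_pos = len(contig) - 1 - pos
        rc_snp = SnpCandidate("ctg", rc_pos, revcomp(ref_base), revcomp(alt),
                              6, 3, 9, 1 / 3, target_region="x")
        rev = classify_effect(rc_contig, rc_snp, proteomes)
        assert rev.strand == "-"
        assert rev.classification == fwd.classification

    def test_no_peptide_match_gives_unknown(self, rng):
        contig = Contig("ctg", random_seq(rng, 300))
        snp = SnpCandidate("ctg", 150, contig.sequence[150],
                           "A" if contig.sequence[150] != "A" else "C",
                           6, 3, 9, 1 / 3, target_region="x")
        call = classify_effect(contig, snp, {"sp": {"p1": "MW" * 100}})
        assert call.classification == EffectClass.UNKNOWN


class TestMitoFlagging:
    def test_substring_flagged_random_unflagged(self, rng):
        mito = random_seq(rng, 5000)
        contigs = [
            Contig("m1", mito[1000:1400]),
            Contig("n1", random_seq(rng, 400)),
        ]
        flags = flag_mitochondrial(contigs, mito)
        assert flags == {"m1": True, "n1": False}
        assert contigs[0].is_mitochondrial and not contigs[1].is_mitochondrial


class TestGoEnrichment:
    def test_identical_term_frequencies_give_p_one(self):
        test = {f"c{i}": {"GO:1"} if i < 5 else {"GO:2"} for i in range(10)}
        ref = {f"r{i}": {"GO:1"} if i < 5 else {"GO:2"} for i in range(10)}
        out = go_enrichment(test, ref)
        assert (out["p"] == 1.0).all()

    def test_fisher_p_equals_hypergeometric_closed_form(self):
        from scipy.stats import hypergeom

        test = {f"c{i}": ({"GO:x"} if i < 8 else {"GO:y"}) for i in range(10)}
        ref = {f"r{i}": ({"GO:x"} if i < 2 else {"GO:y"}) for i in range(10)}
        out = go_enrichment(test, ref).set_index("term")
        # two-sided Fisher p: sum of hypergeometric outcomes no more likely
        rv = hypergeom(20, 10, 10)  # N, successes (GO:x total), draws (test)
        p0 = rv.pmf(8)
        expected = sum(rv.pmf(k) for k in range(11) if rv.pmf(k) <= p0 + 1e-12)
        assert out.loc["GO:x", "p"] == pytest.approx(expected)

    def test_label_permutation_breaks_enrichment(self, rng):
        """Permuting contig labels destroys a strong planted enrichment."""
        annotations = {}
        for i in range(60):
            annotations[f"c{i}"] = {"GO:sig"} if i < 30 else {"GO:bg"}
        test_ids = [f"c{i}" for i in range(25)]  # heavily enriched for GO:sig
        ref_ids = list(annotations)
        enriched = go_enrichment(
            {k: annotations[k] for k in test_ids},
            {k: annotations[k] for k in ref_ids},
        )
        assert enriched["enriched"].any()
        broken = 0
        trials = 20
        for _ in range(trials):
            perm = rng.permutation(ref_ids)
            mapping = dict(zip(ref_ids, perm))
            out = go_enrichment(
                {k: annotations[mapping[k]] for k in test_ids},
                {k: annotations[mapping[k]] for k in ref_ids},
            )
            if not out["enriched"].any():
                broken += 1
        assert broken >= trials - 1

    def test_term_absent_from_both_sets_skipped(self):
        out = go_enrichment({"c1": {"GO:1"}}, {"r1": {"GO:1"}})
        assert set(out["term"]) == {"GO:1"}
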
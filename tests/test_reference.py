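import numpy as np
import pytest

from _oracles import (
    best_global_alignment_bruteforce,
    blosum62_score_fn,
    longest_orf_bruteforce,
)
from conftest import make_matrix
from ribopolya.reference import (
    BlastHit,
    GateThresholds,
    NovelTranscriptEvidence,
    TranscriptRecord,
    accept_novel_transcript,
    assign_symbol,
    best_protein_hit,
    drop_unexpressed,
    filter_by_biotype,
    filter_by_tsl,
    global_alignment_score,
    global_identity,
    longest_orf,
)


class TestDropUnexpressed:
    def test_all_zero_row_dropped(self, rng):
        values = np.vstack([np.zeros(12), rng.uniform(0.001, 5, size=(3, 12))])
        mat = make_matrix(values, genes=["dead", "a", "b", "c"])
        retained, dropped = drop_unexpressed(mat)
        assert dropped == ["dead"] and set(retained) == {"a", "b", "c"}

    def test_single_tiny_value_retained(self):
        mat = make_matrix([[0.0, 0.001, 0.0]], genes=["g"])
        retained, dropped = drop_unexpressed(mat)
        assert retained == ["g"] and dropped == []

    def test_partition_matches_any_scan_oracle(self, rng):
        values = rng.uniform(0, 1, size=(60, 8)) * (rng.uniform(size=(60, 8)) > 0.7)
        mat = make_matrix(values)
        retained, dropped = drop_unexpressed(mat)
        for i, gene in enumerate(mat.feature_ids):
            assert (gene in retained) == any(values[i] > 0)
        assert len(retained) + len(dropped) == 60

    def test_idempotent(self, rng):
        values = rng.uniform(0, 1, size=(20, 4)) * (rng.uniform(size=(20, 4)) > 0.5)
        mat = make_matrix(values)
        retained, _ = drop_unexpressed(mat)
        sub = make_matrix(mat.values.loc[retained].to_numpy(), genes=retained)
        retained2, dropped2 = drop_unexpressed(sub)
        assert retained2 == retained and dropped2 == []


def record(biotype="protein_coding", tsl=1, n_exons=2, rid="t"):
    return TranscriptRecord(id=rid, gene_id="g", biotype=biotype, tsl=tsl, n_exons=n_exons)


class TestAnnotationFilters:
    def test_biotype_subset_and_partition(self):
        recs = [record("protein_coding", rid="a"), record("pseudogene", rid="b"),
                record("lincRNA", rid="c")]
        kept = filter_by_biotype(recs, {"protein_coding"})
        assert [r.id for r in kept] == ["a"]
        everything = filter_by_biotype(recs, {r.biotype for r in recs})
        assert everything == recs
        complement = filter_by_biotype(recs, {"pseudogene", "lincRNA"})
        assert len(kept) + len(complement) == len(recs)

    @pytest.mark.parametrize(
        "tsl,n_exons,kept",
        [(3, 4, True), (None, 1, False), (4, 4, False), (1, 1, False), (2, 2, True)],
    )
    def test_tsl_and_multiexonic_boundaries(self, tsl, n_exons, kept):
        out = filter_by_tsl([record(tsl=tsl, n_exons=n_exons)])
        assert bool(out) == kept

    def test_single_exon_kept_when_not_required(self):
        out = filter_by_tsl([record(tsl=1, n_exons=1)], require_multiexonic=False)
        assert len(out) == 1


class TestLongestOrf:
    def test_hand_countable(self):
        orf = longest_orf("ATGAAATAA")
        assert (orf.aa_length, orf.frame, orf.start, orf.end) == (2, 0, 0, 9)

    def test_no_atg_returns_none(self):
        assert longest_orf("CCCCCCTAACCC") is None

    def test_unterminated_orf_not_reported(self):
        assert longest_orf("ATGAAAAAA") is None

    def test_n_codon_breaks_orf(self):
        # ATG AAN AAA TAA: the N codon invalidates the first ATG's frame run
        assert longest_orf("ATGAANAAATAA") is None
        # but a clean ATG after the N is fine
        orf = longest_orf("AANATGAAATAA")
        assert orf.aa_length == 2

    def test_six_frame_finds_reverse_orf(self):
        fwd = "ATGAAATAA"
        rc = fwd.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        assert longest_orf(rc) is None
        orf = longest_orf(rc, strand_specific=False)
        assert orf is not None and orf.strand == "-" and orf.aa_length == 2

    def test_matches_exhaustive_scan_on_random_sequences(self, rng):
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGTN"), p=[0.24, 0.24, 0.24, 0.24, 0.04],
                                     size=400))
            expected = longest_orf_bruteforce(seq)
            got = longest_orf(seq)
            if expected is None:
                assert got is None
            else:
                assert got is not None and got.aa_length == expected


def hit(acc="P1", identity=60.0, length=100, evalue=1e-30, pe=1, fragment=False,
        symbol="SYM"):
    return BlastHit(acc, symbol, identity, length, evalue, pe, fragment)


class TestBestProteinHit:
    def test_longest_alignment_wins(self):
        best = best_protein_hit([hit(acc="a", identity=60, length=100),
                                 hit(acc="b", identity=55, length=120)])
        assert best.subject_acc == "b"

    def test_identity_just_below_cutoff_excluded(self):
        assert best_protein_hit([hit(identity=49.9)]) is None
        assert best_protein_hit([hit(identity=50.0)]) is not None

    def test_pe_code_and_fragment_exclusions(self):
        assert best_protein_hit([hit(pe=3)]) is None
        assert best_protein_hit([hit(fragment=True)]) is None
        assert best_protein_hit([hit(evalue=1e-20)]) is None

    def test_ties_break_by_identity_then_accession(self):
        best = best_protein_hit([hit(acc="z", identity=70, length=100),
                                 hit(acc="a", identity=60, length=100)])
        assert best.subject_acc == "z"
        best = best_protein_hit([hit(acc="z", identity=60, length=100),
                                 hit(acc="a", identity=60, length=100)])
        assert best.subject_acc == "a"


class TestGlobalIdentity:
    def test_identical_peptides_100(self):
        pep = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSG"
        assert global_identity(pep, pep) == 100.0

    def test_single_gap_identity(self):
        # best alignment of AAAA vs AAA: 3 matches over 4 columns
        assert global_identity("AAAA", "AAA") == 75.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_identity("", "AAA")

    def test_symmetric(self, rng):
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(5):
            a = "".join(rng.choice(aas, size=8))
            b = "".join(rng.choice(aas, size=10))
            assert global_identity(a, b) == pytest.approx(global_identity(b, a))

    def test_matches_exhaustive_enumeration_short_peptides(self, rng):
        score_fn = blosum62_score_fn()
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(30):
            a = "".join(rng.choice(aas, size=rng.integers(1, 7)))
            b = "".join(rng.choice(aas, size=rng.integers(1, 7)))
            exp_score, exp_ident = best_global_alignment_bruteforce(a, b, score_fn)
            assert global_alignment_score(a, b) == pytest.approx(exp_score)
            assert global_identity(a, b) == pytest.approx(exp_ident)


def passing_evidence(cid="c1", **overrides):
    ev = NovelTranscriptEvidence(
        candidate_id=cid,
        orf_length_aa=150,
        best_pfam_evalue=1e-7,
        blast_hits=[hit()],
        needle_identity=72.0,
        cpat_coding_prob=0.9,
    )
    for key, val in overrides.items():
        setattr(ev, key, val)
    return ev


class TestAcceptNovelTranscript:
    def test_all_gates_pass(self):
        rep = accept_novel_transcript(passing_evidence())
        assert rep.accepted and rep.reasons == []

    def test_coding_probability_boundary_is_inclusive(self):
        assert accept_novel_transcript(passing_evidence(cpat_coding_prob=0.364)).accepted
        rep = accept_novel_transcript(passing_evidence(cpat_coding_prob=0.36))
        assert rep.reasons == ["LOW_CODING_PROB"]

    def test_multiple_failures_all_reported(self):
        rep = accept_novel_transcript(
            passing_evidence(orf_length_aa=99, best_pfam_evalue=None)
        )
        assert rep.reasons == ["ORF_SHORT", "NO_PFAM"]

    def test_blast_reason_distinguishes_no_hit_from_low_identity(self):
        rep = accept_novel_transcript(passing_evidence(blast_hits=[]))
        assert "NO_BLAST_HIT" in rep.reasons
        rep = accept_novel_transcript(passing_evidence(blast_hits=[hit(identity=30)]))
        assert "LOW_IDENTITY_BLAST" in rep.reasons

    def test_missing_evidence_fails_conservatively(self):
        rep = accept_novel_transcript(NovelTranscriptEvidence(candidate_id="c"))
        assert set(rep.reasons) == {
            "ORF_SHORT", "NO_PFAM", "NO_BLAST_HIT", "LOW_IDENTITY_NEEDLE",
            "LOW_CODING_PROB",
        }

    def test_monotone_in_each_evidence_dimension(self):
        # improving any single field never flips accepted -> rejected
        base = passing_evidence()
        improvements = dict(
            orf_length_aa=base.orf_length_aa + 50,
            best_pfam_evalue=base.best_pfam_evalue / 10,
            needle_identity=min(100.0, base.needle_identity + 10),
            cpat_coding_prob=min(1.0, base.cpat_coding_prob + 0.05),
        )
        assert accept_novel_transcript(base).accepted
        for key, better in improvements.items():
            assert accept_novel_transcript(passing_evidence(**{key: better})).accepted


class TestAssignSymbol:
    def test_new_symbol_kept(self):
        assert assign_symbol("ABC1", {"TP53", "MYC"}, "cand") == "ABC1"

    def test_existing_symbol_or_synonym_gets_placeholder(self):
        known = {"TP53", "P53"}  # caller pre-expands synonyms
        assert assign_symbol("TP53", known, "cand7") == "NOVEL_cand7"
        assert assign_symbol("P53", known, "cand7") == "NOVEL_cand7"

    def test_empty_symbol_gets_placeholder(self):
        assert assign_symbol("", set(), "x") == "NOVEL_x"
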
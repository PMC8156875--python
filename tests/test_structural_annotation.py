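"""Anchored alignment, indel annotation, gene integrity, ORF statistics."""

import numpy as np
import pytest

from ervscribe import structural_annotation as st
from ervscribe import synthetic_data as sd
from ervscribe.reference import HML7_FEATURES, ReferenceModel


def _delete(seq, start, end):
    """Remove a 1-based inclusive interval."""
    return seq[: start - 1] + seq[end:]


def _leftmost(seq, start, end):
    """Left-most equivalent placement of a deletion (independent oracle).

    Deleting [start, end] and [start-1, end-1] yield the same sequence when
    the base before the deletion equals its last base; annotation reports
    the left-most member of that equivalence class.
    """
    while start > 1 and seq[start - 2] == seq[end - 1]:
        start -= 1
        end -= 1
    return start, end


@pytest.fixture(scope="module")
def clean_reference():
    """HML7-layout reference whose genes are stop-free in every frame.

    Genes are GCT repeats (Ala; no stop in any frame), so engineered stops
    and frameshifts are the only signal the ORF scan can pick up.
    """
    rng = np.random.default_rng(55)
    seq = list(sd.random_sequence(9546, rng, 0.6, cpg_depletion=0.25))
    for gene in ("gag", "pro", "pol", "env"):
        s, e = HML7_FEATURES[gene]
        for i in range(s - 1, e):
            seq[i] = "GCT"[(i - (s - 1)) % 3]
    seq = "".join(seq)
    ltr = seq[:897]
    seq = ltr + seq[897:8649] + ltr
    return ReferenceModel(sequence=seq, features=HML7_FEATURES, name="clean_ref")


class TestAnchorAndIndels:
    def test_reference_vs_itself_zero_indels(self, ancestor):
        anc = st.anchor_to_reference(ancestor.sequence, ancestor, "self")
        assert st.annotate_indels(anc) == []
        assert anc.qry_aligned == ancestor.sequence

    def test_internal_deletion_annotated_as_single_event(self, ancestor):
        query = _delete(ancestor.sequence, 1760, 3970)
        anc = st.anchor_to_reference(query, ancestor, "del1")
        dels = [i for i in st.annotate_indels(anc) if i.kind == "deletion"]
        assert len(dels) == 1
        assert (dels[0].ref_start, dels[0].ref_end) == _leftmost(ancestor.sequence, 1760, 3970)
        assert dels[0].length == 2211

    def test_ltr_deletion_595_617_has_length_23(self, ancestor):
        query = _delete(ancestor.sequence, 595, 617)
        anc = st.anchor_to_reference(query, ancestor, "del2")
        dels = [i for i in st.annotate_indels(anc) if i.kind == "deletion"]
        assert len(dels) == 1
        assert dels[0].length == 23
        assert (dels[0].ref_start, dels[0].ref_end) == _leftmost(ancestor.sequence, 595, 617)

    def test_indel_roundtrip_reconstructs_query(self, ancestor):
        query = _delete(_delete(ancestor.sequence, 7484, 7684), 595, 617)
        query = query[:5000] + "ACGTAC" + query[5000:]  # plus one insertion
        anc = st.anchor_to_reference(query, ancestor, "rt")
        assert st.apply_indels(ancestor.sequence, st.annotate_indels(anc)) == query

    def test_truncation_marked_terminal(self, ancestor):
        query = ancestor.sequence[897:]
        anc = st.anchor_to_reference(query, ancestor, "trunc")
        dels = [i for i in st.annotate_indels(anc) if i.kind == "deletion"]
        assert any(d.terminal and d.ref_start == 1 for d in dels)

    def test_identity_gate_refuses_divergent_input(self, ancestor):
        noise = sd.random_sequence(9546, np.random.default_rng(6))
        with pytest.raises(ValueError):
            st.anchor_to_reference(noise, ancestor, "noise", min_identity=90.0)


class TestRecurrentDeletions:
    @staticmethod
    def _del(locus, s, e):
        return st.IndelAnnotation(locus, "deletion", s, e, e - s + 1)

    def test_nine_shared_deletions_form_one_cluster(self):
        dels = [self._del(f"L{i}", 1760, 3970) for i in range(9)]
        clusters = st.recurrent_deletions(dels)
        assert len(clusters) == 1
        assert clusters[0]["support"] == 9
        assert (clusters[0]["ref_start"], clusters[0]["ref_end"]) == (1760, 3970)

    def test_disjoint_deletions_do_not_cluster(self):
        dels = [self._del("A", 100, 200), self._del("B", 500, 600), self._del("C", 900, 950)]
        assert st.recurrent_deletions(dels, min_loci=2) == []

    def test_half_overlap_below_tolerance_stays_separate(self):
        dels = [self._del(c, s, s + 99) for c, s in (("A", 1), ("B", 51), ("C", 101))]
        assert st.recurrent_deletions(dels, min_loci=2, overlap_tolerance=0.8) == []


class TestGeneIntegrity:
    def test_full_length_locus_is_complete(self, ancestor):
        anc = st.anchor_to_reference(ancestor.sequence, ancestor, "full")
        result = st.gene_integrity(anc, ancestor)
        assert result["structural_class"] == "complete"
        assert all(v == pytest.approx(1.0) for v in result["coverage"].values())

    def test_missing_5prime_ltr_detected(self, ancestor):
        anc = st.anchor_to_reference(ancestor.sequence[897:], ancestor, "noltr5")
        result = st.gene_integrity(anc, ancestor)
        assert not result["ltr5_present"]
        assert result["ltr3_present"]

    def test_two_thirds_5prime_loss_is_defective(self, ancestor):
        anc = st.anchor_to_reference(ancestor.sequence[6364:], ancestor, "short")
        result = st.gene_integrity(anc, ancestor)
        assert result["structural_class"] == "defective"


class TestOrfScan:
    def test_engineered_stop_counted_without_frameshift(self, clean_reference):
        ref = clean_reference
        s, _ = ref.features["gag"]
        seq = list(ref.sequence)
        seq[s - 1 + 30 : s - 1 + 33] = "TAA"  # codon boundary inside gag
        anc = st.anchor_to_reference("".join(seq), ref, "stop1")
        report = st.orf_scan(anc, ref)
        assert report.genes["gag"].internal_stop_count == 1
        assert report.genes["gag"].frameshift_count == 0

    def test_one_bp_deletion_in_pol_is_frameshift(self, clean_reference):
        ref = clean_reference
        s, _ = ref.features["pol"]
        query = _delete(ref.sequence, s + 100, s + 100)
        anc = st.anchor_to_reference(query, ref, "fs1")
        report = st.orf_scan(anc, ref)
        assert report.genes["pol"].frameshift_count == 1

    def test_reference_layout_reproduces_group_shift_pattern(self, ancestor):
        # gag-pro readthrough (0), pro-pol -1 frameshift
        anc = st.anchor_to_reference(ancestor.sequence, ancestor, "ref")
        report = st.orf_scan(anc, ancestor)
        assert report.gag_pro_shift == 0
        assert report.pro_pol_shift == -1

    def test_unmutated_reference_has_no_frameshifts(self, ancestor):
        anc = st.anchor_to_reference(ancestor.sequence, ancestor, "ref")
        report = st.orf_scan(anc, ancestor)
        assert all(g.frameshift_count == 0 for g in report.genes.values())

    def test_absent_gene_fields_undefined(self, ancestor):
        # keep only the 3' quarter: gag fully deleted
        anc = st.anchor_to_reference(ancestor.sequence[7000:], ancestor, "tail")
        report = st.orf_scan(anc, ancestor)
        assert report.genes["gag"].internal_stop_count is None
        assert report.gag_pro_shift is None


class TestCompositionAndMotifs:
    @pytest.mark.parametrize("seq,at", [("AATT", 100.0), ("ACGT", 50.0)])
    def test_composition_hand_cases(self, seq, at):
        assert st.composition(seq)["AT_percent"] == pytest.approx(at)

    def test_fractions_sum_to_one_and_ns_excluded(self):
        frac = st.composition("ACGTNNN")
        assert sum(frac[b] for b in "ACGT") == pytest.approx(1.0)

    def test_all_n_rejected(self):
        with pytest.raises(ValueError):
            st.composition("NNNN")

    def test_generated_element_at_near_sixty_percent(self, ancestor):
        assert st.composition(ancestor.sequence)["AT_percent"] == pytest.approx(60.0, abs=2.0)

    def test_single_cchc_knuckle(self):
        peptide = "AAA" + "C" + "AA" + "C" + "AAAA" + "H" + "AAAA" + "C" + "AAA"
        assert st.zinc_finger_scan(peptide, is_protein=True)[0] == 1

    def test_two_tandem_knuckles(self):
        knuckle = "C" + "AA" + "C" + "AAAA" + "H" + "AAAA" + "C"
        assert st.zinc_finger_scan(knuckle + "GG" + knuckle, is_protein=True)[0] == 2

    def test_no_cysteines_no_hits(self):
        assert st.zinc_finger_scan("AAAAHAAAA", is_protein=True)[0] == 0

    def test_nucleotide_input_translated_in_frame(self):
        peptide = "CAACAAAAHAAAAC"
        codons = {"C": "TGC", "A": "GCT", "H": "CAC"}
        nt = "".join(codons[a] for a in peptide)
        assert st.zinc_finger_scan(nt)[0] == 1


class TestReferenceProjection:
    def test_projected_rows_have_reference_length(self, ancestor):
        query = _delete(ancestor.sequence, 1760, 3970)
        anc = st.anchor_to_reference(query, ancestor, "proj")
        msa = st.project_to_reference_msa([anc], ancestor)
        assert set(map(len, msa.values())) == {len(ancestor)}
        a, b = _leftmost(ancestor.sequence, 1760, 3970)
        assert msa["proj"][a - 1 : b] == "-" * 2211
        assert msa[ancestor.name] == ancestor.sequence
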
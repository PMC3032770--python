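"""Translation, truncated-stop completion, RSCU and composition statistics."""

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from mitocistron.codons import (
    CodonUsageTable,
    FrameError,
    PrematureStopError,
    at_composition,
    codon_usage,
    complete_truncated_stop,
    invertebrate_mito_code,
    position_bias_chi2,
    translate_cds,
)

CODE = invertebrate_mito_code()


class TestGeneticCode:
    def test_nonstandard_assignments(self):
        assert CODE.aa("AGA") == "S" and CODE.aa("AGG") == "S"
        assert CODE.aa("ATA") == "M"
        assert CODE.aa("TGA") == "W"
        assert CODE.aa("TAA") == "*" and CODE.aa("TAG") == "*"

    def test_start_codon_set(self):
        assert CODE.start_codons == {"ATG", "ATA", "ATT", "ATC", "TTG", "GTG", "CGA"}

    def test_matches_biopython_table5_on_all_sense_codons(self):
        from Bio.Data import CodonTable

        t5 = CodonTable.unambiguous_dna_by_id[5]
        for codon, aa in t5.forward_table.items():
            assert CODE.aa(codon) == aa


class TestTranslation:
    def test_att_initiator_renders_methionine(self):
        assert translate_cds("ATTATATTTTAA", CODE, is_annotated_start=True) == "MMF"

    def test_cga_start_is_m_only_when_annotated(self):
        seq = "CGATTTTAA"
        assert translate_cds(seq, CODE, is_annotated_start=True).startswith("M")
        assert translate_cds(seq, CODE).startswith("R")

    def test_standard_codons_with_trailing_stop_dropped(self):
        assert translate_cds("ATGTTTTAA", CODE) == "MF"

    def test_internal_stop_names_position(self):
        with pytest.raises(PrematureStopError, match="codon 2"):
            translate_cds("ATGTAATTTTAA", CODE)

    def test_frame_error(self):
        with pytest.raises(FrameError):
            translate_cds("ATGTT", CODE)

    def test_polyA_completion_before_translation(self):
        # genomic CDS ends in a bare T; polyadenylation completes TAA
        assert translate_cds("ATGTTTT", CODE, polyA_completed=True) == "MF"

    @given(st.lists(st.sampled_from(sorted(CODE.table)), min_size=1, max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_agrees_with_biopython_on_stop_free_cds(self, codons):
        seq = "".join(codons)
        assert translate_cds(seq, CODE) == str(Seq(seq).translate(table=5))


class TestStopCompletion:
    def test_bare_t_with_a_tail_completes_taa(self):
        res = complete_truncated_stop("ATGTTTT", "AAAAA")
        assert res.status == "completed" and res.cds.endswith("TAA") and res.added == 2

    def test_full_stop_is_unchanged(self):
        res = complete_truncated_stop("ATGTAA", "CCCC")
        assert res.status == "already_complete" and res.cds == "ATGTAA"

    def test_ta_truncation_needs_one_a(self):
        res = complete_truncated_stop("ATGTTTTA", "AAA")
        assert res.status == "completed" and res.cds == "ATGTTTTAA"

    def test_tail_without_a_is_not_completable(self):
        res = complete_truncated_stop("ATGTTTT", "CCCC")
        assert res.status == "not_completable" and res.cds == "ATGTTTT"

    @given(st.text(alphabet="ACGT", min_size=3, max_size=40), st.text(alphabet="ACGT", max_size=10))
    @settings(max_examples=100, deadline=None)
    def test_never_changes_existing_bases(self, cds, tail):
        res = complete_truncated_stop(cds, tail)
        assert res.cds.startswith(cds)
        assert len(res.cds) - len(cds) == res.added <= 2


class TestCodonUsage:
    # published leucine counts (six-codon family under the mito code)
    LEU = {"TTA": 426, "TTG": 9, "CTT": 26, "CTC": 2, "CTA": 23, "CTG": 0}

    def test_rscu_of_uua_from_published_leucine_counts(self):
        table = CodonUsageTable.from_counts(self.LEU)
        assert round(table.rscu_of("UUA"), 2) == 5.26

    def test_rscu_of_uuu_from_published_phe_counts(self):
        table = CodonUsageTable.from_counts({"TTT": 315, "TTC": 31})
        assert round(table.rscu_of("UUU"), 2) == 1.82

    def test_uniform_family_gives_rscu_one(self):
        table = CodonUsageTable.from_counts({c: 7 for c in self.LEU})
        for c in self.LEU:
            assert table.rscu_of(c) == pytest.approx(1.0)

    def test_stop_codons_form_their_own_family(self):
        table = CodonUsageTable.from_counts({"TAA": 10, "TAG": 1})
        assert round(table.rscu_of("UAA"), 2) == 1.82
        assert round(table.rscu_of("UAG"), 2) == 0.18

    def test_serine_family_has_eight_codons(self):
        fams = CODE.families()
        assert sorted(fams["S"]) == ["AGA", "AGC", "AGG", "AGT", "TCA", "TCC", "TCG", "TCT"]
        assert len(fams["L"]) == 6

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_family_rscu_sums_to_family_size(self, seed):
        rng = np.random.default_rng(seed)
        counts = {c: int(rng.integers(0, 50)) for c in CodonUsageTable._all_codons()}
        table = CodonUsageTable.from_counts(counts)
        rscu = table.rscu
        for aa, codons in table.families.items():
            if sum(table.counts[c] for c in codons) > 0:
                assert sum(rscu[c] for c in codons) == pytest.approx(len(codons))

    def test_counts_include_stops_and_total_is_length_over_three(self):
        cds_list = ["ATGTTTTAA", "ATTAAATAG"]
        table = codon_usage(cds_list, CODE)
        assert table.total == sum(len(c) for c in cds_list) // 3
        assert table.count_of("TAA") == 1 and table.count_of("TAG") == 1

    def test_ambiguous_codons_are_excluded_and_counted(self):
        table = codon_usage(["ATGNNNTAA"], CODE)
        assert table.total == 2 and table.n_skipped == 1

    def test_frame_error_reported_per_cds(self):
        with pytest.raises(FrameError, match="#2"):
            codon_usage(["ATGTAA", "ATGTA"], CODE)


class TestComposition:
    def test_pure_at_sequence(self):
        assert at_composition("ATAT").at_fraction == 1.0

    def test_third_position_fraction_from_counts(self):
        # 3218 of 3422 third positions A/T -> 0.940
        assert round(3218 / 3422, 3) == 0.940

    def test_positional_breakdown_on_constructed_cds(self):
        # codons ATx: position 1 all A, position 2 all T, position 3 half G
        stats = at_composition(["ATAATG"])
        assert stats.at_by_codon_position == pytest.approx((1.0, 1.0, 0.5))
        assert stats.n_codons == 2

    def test_n_residues_excluded(self):
        stats = at_composition("ATNN")
        assert stats.at_fraction == 1.0 and stats.n_residues == 2

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            at_composition("")

    def test_synthetic_genome_hits_at_target_within_3sd(self, synth_genome):
        n = synth_genome.length
        p = 0.80
        at = sum(synth_genome.residues.count(b) for b in "AT") / n
        # background binomial spread; PCG positional model averages ~0.79
        assert abs(at - p) <= 3 * np.sqrt(p * (1 - p) / n) + 0.02


class TestPositionBiasChi2:
    def test_equal_proportions_give_zero(self):
        chi2, p = position_bias_chi2(50, 100, 50, 100)
        assert chi2 == 0 and p == pytest.approx(1.0)

    def test_matches_scipy_contingency_without_correction(self):
        a, n1, c, n2 = 3218, 3422, 2498, 3422
        chi2, p = position_bias_chi2(a, n1, c, n2)
        table = [[a, n1 - a], [c, n2 - c]]
        ref = chi2_contingency(table, correction=False)
        assert chi2 == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_doubling_counts_doubles_statistic(self):
        chi2, _ = position_bias_chi2(30, 100, 50, 100)
        chi2x2, _ = position_bias_chi2(60, 200, 100, 200)
        assert chi2x2 == pytest.approx(2 * chi2)

    def test_zero_marginal_is_undefined(self):
        with pytest.raises(ValueError):
            position_bias_chi2(0, 100, 0, 100)
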
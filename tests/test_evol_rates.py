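import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

import oracles
from wrkyevol.evol_rates import (
    SENSE_CODONS, CodonAlignment, apply_rate_filters, back_translate,
    codon_pair_differences, codon_sites, jukes_cantor, kaks_for_cds_pair,
    nei_gojobori, summarize_rates, translate_cds,
)

sense_codon = st.sampled_from(SENSE_CODONS)


def _aln(codons_a, codons_b):
    return CodonAlignment("a", "b", tuple(zip(codons_a, codons_b)))


class TestCountingPrimitives:
    @given(sense_codon)
    def test_site_counts_match_first_principles(self, codon):
        syn, nonsyn = oracles.syn_nonsyn_sites(codon)
        got = codon_sites(codon)
        assert got[0] == pytest.approx(float(syn), abs=1e-12)
        assert got[1] == pytest.approx(float(nonsyn), abs=1e-12)
        assert got[0] + got[1] == pytest.approx(3.0)

    @given(sense_codon, sense_codon)
    def test_pathway_counts_match_recursive_enumeration(self, c1, c2):
        sd_o, nd_o = oracles.pathway_differences(c1, c2)
        sd, nd = codon_pair_differences(c1, c2)
        assert sd == pytest.approx(float(sd_o), abs=1e-12)
        assert nd == pytest.approx(float(nd_o), abs=1e-12)

    @given(sense_codon, sense_codon)
    def test_pathway_counts_symmetric(self, c1, c2):
        assert codon_pair_differences(c1, c2) == codon_pair_differences(c2, c1)

    def test_synonymous_single_difference(self):
        # AAA -> AAG is Lys -> Lys
        assert codon_pair_differences("AAA", "AAG") == (1.0, 0.0)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            codon_sites("TAA")


class TestNeiGojobori:
    def test_identical_sequences_have_undefined_ratio(self):
        est = nei_gojobori(_aln(["ATG", "AAA"], ["ATG", "AAA"]))
        assert est.ka == 0.0 and est.ks == 0.0
        assert math.isnan(est.ratio)
        assert est.filter == "undefined" and est.selection == "NA"

    def test_single_synonymous_difference(self):
        # AAA -> AAG (Lys -> Lys): one synonymous difference, nothing else
        est = nei_gojobori(_aln(["ATG", "AAA"], ["ATG", "AAG"]))
        assert est.sd == 1.0 and est.nd == 0.0
        assert est.ka == 0.0
        # with enough synonymous context the rate itself is defined
        est2 = nei_gojobori(_aln(["AAA"] * 20 + ["CTG"] * 20,
                                 ["AAG"] + ["AAA"] * 19 + ["CTG"] * 20))
        assert est2.ks > 0 and est2.ka == 0.0

    def test_site_conservation_exact(self, rng):
        codons_a = list(rng.choice(SENSE_CODONS, 80))
        codons_b = list(rng.choice(SENSE_CODONS, 80))
        est = nei_gojobori(_aln(codons_a, codons_b))
        assert est.n_sites + est.s_sites == pytest.approx(3 * est.codons_compared)

    def test_symmetry(self, rng):
        from wrkyevol.synthetic_data import evolve_pair, reverse_translate

        prot = "".join(rng.choice(list("ADEFGIKLMNPQRSTVY"), 120))
        a, b, _ = evolve_pair(reverse_translate(prot, rng, 0.5), 0.5, 0.4, rng)
        ca = [a[i : i + 3] for i in range(0, len(a), 3)]
        cb = [b[i : i + 3] for i in range(0, len(b), 3)]
        e1 = nei_gojobori(_aln(ca, cb))
        e2 = nei_gojobori(_aln(cb, ca))
        assert e1.ka == pytest.approx(e2.ka)
        assert e1.ks == pytest.approx(e2.ks)
        assert (e1.sd, e1.nd) == (e2.sd, e2.nd)

    def test_gap_and_n_columns_skipped_and_counted(self):
        aln = _aln(["ATG", "---", "AAN", "AAA"], ["ATG", "CCC", "AAA", "AAG"])
        est = nei_gojobori(aln)
        assert est.codons_compared == 2
        assert est.codons_skipped == 2

    def test_no_comparable_codons_is_hard_error(self):
        with pytest.raises(ValueError):
            nei_gojobori(_aln(["---"], ["ATG"]))

    def test_selection_classes(self):
        purifying = nei_gojobori(
            _aln(["AAA", "CTG"] * 30 + ["AAA"], ["AAG", "CTG"] * 30 + ["AAA"])
        )
        assert purifying.selection == "purifying"
        assert purifying.ratio < 1


class TestJukesCantor:
    def test_zero(self):
        assert jukes_cantor(0.0) == 0.0

    def test_ceiling_is_nan(self):
        assert math.isnan(jukes_cantor(0.75))
        assert math.isnan(jukes_cantor(0.9))

    def test_correction_exceeds_raw_proportion(self):
        assert jukes_cantor(0.3) > 0.3


class TestBackTranslate:
    def test_direct_mapping(self):
        aln = back_translate("MK", "MK", "ATGAAA", "ATGAAG")
        assert aln.columns == (("ATG", "ATG"), ("AAA", "AAG"))

    def test_gap_maps_to_gap_codon(self):
        aln = back_translate("M-K", "MQK", "ATGAAA", "ATGCAAAAG")
        assert aln.columns[1] == ("---", "CAA")

    def test_trailing_stop_trimmed(self):
        aln = back_translate("MK", "MK", "ATGAAATAA", "ATGAAG")
        assert len(aln) == 2

    def test_translation_mismatch_names_gene_and_position(self):
        with pytest.raises(ValueError, match="b.*position 2"):
            back_translate("MK", "MK", "ATGAAA", "ATGTTA", id_a="a", id_b="b")

    def test_length_mismatch_is_hard_error(self):
        with pytest.raises(ValueError, match="length"):
            back_translate("MK", "MK", "ATGAAAAAA", "ATGAAG")

    def test_internal_stop_is_hard_error(self):
        with pytest.raises(ValueError, match="stop"):
            back_translate("M*K", "MQK", "ATGTAAAAA", "ATGCAAAAG")


class TestFiltersAndSummary:
    def _est(self, ks, ka=0.05):
        aln = _aln(["AAA"], ["AAG"])
        est = nei_gojobori(aln)
        est.ks, est.ka, est.ratio, est.filter = ks, ka, ka / ks, "retained"
        est.selection = "purifying"
        return est

    def test_paper_thresholds(self):
        ests = [self._est(ks) for ks in (0.005, 0.02, 0.19, 2.9, 3.2)]
        retained, report = apply_rate_filters(ests)
        assert [e.ks for e in retained] == [0.02, 0.19, 2.9]
        assert set(report["status"]) == {"excluded_low", "excluded_high"}
        assert sorted(report["ks"]) == [0.005, 3.2]

    def test_ka_nearly_zero_noted(self):
        (_, report) = apply_rate_filters([self._est(0.005, ka=1e-9)])
        assert report.iloc[0]["note"] == "Ka nearly 0"

    def test_summary_direction_and_single_pair_na(self):
        import pandas as pd

        table = pd.DataFrame({
            "relation": ["ortholog"] * 3 + ["paralog"] * 3,
            "ka": [0.1, 0.12, 0.11, 0.05, 0.06, 0.055],
            "ks": [0.4, 0.41, 0.39, 0.2, 0.21, 0.19],
            "ratio": [0.25, 0.29, 0.28, 0.25, 0.29, 0.29],
        })
        summary = summarize_rates(table).set_index("relation")
        assert summary.loc["ortholog", "mean_ks"] > summary.loc["paralog", "mean_ks"]
        assert summary["p_ks"].iloc[0] < 0.2
        single = pd.DataFrame({
            "relation": ["ortholog", "paralog"],
            "ka": [0.1, 0.05], "ks": [0.4, 0.2], "ratio": [0.25, 0.25],
        })
        s2 = summarize_rates(single)
        assert math.isnan(s2["p_ks"].iloc[0])
        assert s2.set_index("relation").loc["paralog", "mean_ks"] == 0.2


class TestFullPath:
    def test_translate_cds(self):
        assert translate_cds("ATGAAATAA") == "MK"
        with pytest.raises(ValueError):
            translate_cds("ATGA")

    def test_cds_pair_estimate_matches_direct_alignment(self, rng):
        from wrkyevol.synthetic_data import evolve_pair, reverse_translate

        prot = "".join(rng.choice(list("ADEFGIKLMNPQRSTVYWCH"), 150))
        anc = reverse_translate(prot, rng, 0.5)
        a, b, truth = evolve_pair(anc, 0.3, 0.3, rng)
        est = kaks_for_cds_pair(a, b)
        # no indels were simulated, so the protein-guided alignment must
        # reproduce the evolver's own oracle-counted divergence
        assert est.ks == pytest.approx(truth["realized_ks"], abs=1e-9)
        assert est.ka == pytest.approx(truth["realized_ka"], abs=1e-9)
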
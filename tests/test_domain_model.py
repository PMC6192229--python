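import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import heptapeptide_windows
from wrkyevol.domain_model import (
    ReferenceSet, annotate_proteins, assign_group, assign_subgroup,
    census_variants, find_heptapeptide_seeds, find_zinc_finger,
    table1_report, validate_and_assemble, excluded_report,
)
from wrkyevol.io_formats import ProteinRecord
from wrkyevol.synthetic_data import DOMAIN_TEMPLATES, reference_set

C2H2 = "C" + "A" * 4 + "C" + "A" * 22 + "HAH"
C2HC = "C" + "A" * 7 + "C" + "A" * 23 + "HAC"


class TestHeptapeptideSeeds:
    def test_exact_match(self):
        assert find_heptapeptide_seeds("AAWRKYGQKAA") == [(2, "WRKYGQK")]

    def test_known_variant_within_budget(self):
        assert find_heptapeptide_seeds("AAWRKYGKKAA", 2) == [(2, "WRKYGKK")]

    def test_w_anchor_is_mandatory(self):
        # even a single substitution at the W kills the seed
        assert find_heptapeptide_seeds("AAARKYGQKAA") == []

    def test_budget_zero_rejects_variants(self):
        assert find_heptapeptide_seeds("AAWRKYGKKAA", 0) == []

    def test_overlap_resolved_by_fewest_mismatches(self):
        # two W-anchored windows overlap; the exact one must win
        seq = "WRWRKYGQKAA"
        seeds = find_heptapeptide_seeds(seq, 2)
        assert seeds == [(2, "WRKYGQK")]

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=7, max_size=60),
           st.integers(0, 2))
    def test_matches_brute_force_windows(self, seq, budget):
        """Every reported seed is a candidate window, and the best
        candidate (fewest mismatches, then leftmost) always survives."""
        seeds = find_heptapeptide_seeds(seq, budget)
        windows = dict(heptapeptide_windows(seq, budget))
        for off, hepta in seeds:
            assert off in windows
            assert seq[off : off + 7] == hepta
        if windows:
            best = min(windows.items(), key=lambda kv: (kv[1], kv[0]))
            assert best[0] in [off for off, _ in seeds]


class TestZincFinger:
    def test_c2h2_by_construction(self):
        hit = find_zinc_finger("AAA" + C2H2 + "AAA", 0)
        assert hit.zf_type == "C2H2"
        assert hit.spacers == (4, 22)
        assert hit.span == (3, 3 + len(C2H2))

    def test_c2hc_by_construction(self):
        hit = find_zinc_finger(C2HC, 0)
        assert (hit.zf_type, hit.spacers) == ("C2HC", (7, 23))

    def test_absent_without_cysteine(self):
        assert find_zinc_finger("A" * 200, 0) is None

    def test_search_window_is_respected(self):
        seq = "A" * 150 + C2H2
        assert find_zinc_finger(seq, 0, window=120) is None
        assert find_zinc_finger(seq, 0, window=200) is not None


class TestAssembleAndClassify:
    def _protein(self, seq, pid="p1", species="sp1"):
        return ProteinRecord(pid, seq, species=species)

    def test_seed_plus_zinc_finger_is_valid_domain(self):
        prot = self._protein("AA" + "WRKYGQK" + "AAAA" + C2H2 + "AA")
        (dom,) = validate_and_assemble(prot)
        assert dom.valid and dom.zf_type == "C2H2"
        assert dom.span == (2, 2 + 7 + 4 + len(C2H2))

    def test_seed_without_zinc_finger_is_invalid_and_excluded(self):
        prot = self._protein("AA" + "WRKYGQK" + "A" * 30)
        (dom,) = validate_and_assemble(prot)
        assert not dom.valid
        ann = assign_group(prot, [dom])
        assert ann.group == "unclassified"
        report = excluded_report([ann])
        assert report.iloc[0]["reason"] == "no zinc finger"

    def test_two_seeds_sharing_one_zinc_finger(self):
        # second heptapeptide sits between the first and the only ZF:
        # the first (N-terminal) seed claims it, the second goes invalid
        seq = "WRKYGQK" + "AA" + "WRKYGQK" + "AAAA" + C2H2
        prot = self._protein(seq)
        d1, d2 = validate_and_assemble(prot)
        assert d1.valid and not d2.valid

    @pytest.mark.parametrize(
        "domains, expected",
        [
            (["WRKYGQK" + "AA" + C2H2] * 2, "I"),
            (["WRKYGQK" + "AA" + C2H2], "II"),
            (["WRKYGQK" + "AA" + C2HC], "III"),
            (["WRKYGQK" + "AA" + C2H2] * 3, "multi_domain"),
            ([], "unclassified"),
        ],
    )
    def test_group_by_domain_count_and_zf_type(self, domains, expected):
        seq = "AAAA" + ("A" * 10).join(domains) + "AAAA" if domains else "AAAA"
        prot = self._protein(seq)
        ann = assign_group(prot, validate_and_assemble(prot))
        assert ann.group == expected
        if expected == "I":
            assert ann.terminal_labels == ("N", "C")

    @given(pre=st.integers(0, 30), post=st.integers(0, 30))
    def test_scan_invariant_to_flanks(self, pre, post):
        core = "WRKYGQK" + "AAAA" + C2H2
        prot = self._protein("D" * pre + core + "E" * post)
        doms = validate_and_assemble(prot)
        assert len(doms) == 1
        assert doms[0].valid
        assert doms[0].hepta_start == pre


class TestCensusVariants:
    def _domains(self, heptas):
        prots = [
            ProteinRecord(f"p{i}", "AA" + h + "AAAA" + C2H2)
            for i, h in enumerate(heptas)
        ]
        return [d for p in prots for d in validate_and_assemble(p)]

    def test_position_counts_and_variant_tally(self):
        counts, tally = census_variants(self._domains(["WRKYGQK", "WRKYGKK"]))
        assert counts.loc[6, "Q"] == 1
        assert counts.loc[6, "K"] == 1
        assert dict(tally) == {"WRKYGKK": 1}

    def test_all_canonical_gives_empty_tally(self):
        _, tally = census_variants(self._domains(["WRKYGQK"] * 3))
        assert not tally

    def test_position_two_variant_recorded(self):
        counts, tally = census_variants(self._domains(["WKKYGQK"]))
        assert counts.loc[2, "K"] == 1
        assert dict(tally) == {"WKKYGQK": 1}

    def test_per_position_totals_equal_domain_count(self):
        counts, _ = census_variants(
            self._domains(["WRKYGQK", "WRKYGKK", "WKKYGQK"])
        )
        assert (counts.sum(axis=1) == 3).all()


class TestSubgroupAssignment:
    def test_identical_to_reference_scores_one(self):
        refs = reference_set()
        label, score, tie = assign_subgroup(DOMAIN_TEMPLATES["IIa"], refs)
        assert (label, tie) == ("IIa", False)
        assert score == pytest.approx(1.0)

    def test_tie_broken_alphabetically_and_flagged(self):
        refs = ReferenceSet({"IIb": ["WRKYGQKAAAA"], "IIc": ["WRKYGQKAAAA"]})
        label, _, tie = assign_subgroup("WRKYGQKAAAA", refs)
        assert label == "IIb"
        assert tie

    def test_score_below_floor_goes_to_mixed_clade(self):
        refs = reference_set()
        label, score, _ = assign_subgroup("PLMNSTDEFIKLA", refs, floor=0.5)
        assert label == "IIm"
        assert score < 0.5

    def test_empty_reference_set_is_hard_error(self):
        with pytest.raises(ValueError):
            ReferenceSet({})
        with pytest.raises(ValueError):
            ReferenceSet({"IIa": []})


class TestTable1Report:
    def test_one_species_three_groups(self):
        prots = [
            ProteinRecord("a", "A" + ("WRKYGQK" + "AA" + C2H2) * 2, species="sp1"),
            ProteinRecord("b", "A" + "WRKYGQK" + "AA" + C2H2, species="sp1"),
            ProteinRecord("c", "A" + "WRKYGQK" + "AA" + C2HC, species="sp1"),
        ]
        table = table1_report(annotate_proteins(prots))
        row = table.loc["sp1"]
        assert (row["I"], row["II"], row["III"], row["total"]) == (1, 1, 1, 3)

    def test_empty_input(self):
        table = table1_report([])
        assert table.empty

    def test_planted_composition_recovered(self, default_cohort):
        anns = annotate_proteins(default_cohort.proteins, default_cohort.references)
        table = table1_report(anns)
        labels = default_cohort.labels
        for species in table.index:
            sub = labels[(labels["species"] == species) & ~labels["is_decoy"]]
            for group in ("I", "II", "III", "multi_domain"):
                assert table.loc[species, group] == (sub["group"] == group).sum()

    def test_valid_domains_satisfy_spacer_constraints(self, default_cohort):
        anns = annotate_proteins(default_cohort.proteins)
        for ann in anns:
            for dom in ann.domains:
                if not dom.valid:
                    continue
                x1, x2 = dom.zf_spacers
                if dom.zf_type == "C2H2":
                    assert x1 in (4, 5) and x2 in (22, 23)
                else:
                    assert (x1, x2) == (7, 23)
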
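"""Seed-pattern derivation, UTR scanning, site import, conservation rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mirderep import (MatureMiRNA, TargetSite, classify_site_conservation,
                      conservation_rule, gene_site_summary,
                      import_site_predictions, scan_utr, seed_patterns)
from mirderep.errors import FormatError
from mirderep.sites import MELANOGASTER_PANEL, reverse_complement

from oracles import naive_scan

dna = st.text(alphabet="ACGT", min_size=0, max_size=200)
rna8 = st.text(alphabet="ACGU", min_size=8, max_size=25)


class TestSeedPatterns:
    def test_mir124_patterns(self, mirna):
        pats = seed_patterns(mirna)
        assert pats["seed7"] == "GTGCCTT"  # revcomp of positions 2-8, AAGGCAC
        assert pats["seed6"] == "TGCCTT"  # revcomp of positions 2-7, AAGGCA

    def test_seed6_is_suffix_of_seed7(self, mirna):
        pats = seed_patterns(mirna)
        assert pats["seed7"].endswith(pats["seed6"])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            MatureMiRNA("x", "UAAGG")

    def test_bad_alphabet_rejected(self):
        with pytest.raises(ValueError):
            MatureMiRNA("x", "UAAGGCACXX")

    @given(seq=rna8)
    def test_reverse_complement_involution(self, seq):
        """Reverse-complementing a target pattern recovers the seed window."""
        mir = MatureMiRNA("h", seq)
        pats = seed_patterns(mir)
        assert reverse_complement(pats["seed7"]) == mir.seed7.replace("U", "T")
        assert reverse_complement(pats["seed6"]) == mir.seed6.replace("U", "T")


class TestScanUtr:
    def test_seed7_match(self, mirna):
        sites = scan_utr("g", "AAAGTGCCTTAAA", mirna)
        assert [(s.start, s.site_class) for s in sites] == [(3, "seed7")]

    def test_seed6_match(self, mirna):
        sites = scan_utr("g", "AAATGCCTTAAA", mirna)
        assert [(s.start, s.site_class) for s in sites] == [(3, "seed6")]

    def test_no_match(self, mirna):
        assert scan_utr("g", "ACACACACA", mirna) == []

    def test_empty_sequence(self, mirna):
        assert scan_utr("g", "", mirna) == []

    def test_n_never_matches(self, mirna):
        assert scan_utr("g", "AAAGTGNCTTAAA", mirna) == []

    def test_bad_characters_rejected(self, mirna):
        with pytest.raises(FormatError):
            scan_utr("g", "ACGTX", mirna)

    def test_seed7_not_double_reported_as_seed6(self, mirna):
        # the contained seed6 window of a seed7 match is suppressed
        sites = scan_utr("g", "GTGCCTT", mirna)
        assert [s.site_class for s in sites] == ["seed7"]

    def test_matches_naive_oracle_on_random_utrs(self, mirna):
        pats = seed_patterns(mirna)
        rng = np.random.default_rng(2024)
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGT"), size=500))
            got = [(s.start, s.site_class) for s in scan_utr("g", seq, mirna)]
            assert got == naive_scan(seq, pats["seed7"], pats["seed6"])

    @given(seq=dna)
    def test_class_exclusivity(self, seq, mirna):
        sites = scan_utr("g", seq, mirna)
        starts7 = [s.start for s in sites if s.site_class == "seed7"]
        for s in sites:
            if s.site_class == "seed6":
                assert all(not t <= s.start <= t + 1 for t in starts7)


class TestImportPredictions:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "start", "end",
                                           "site_type", "score"])

    def test_favorable_noncanonical_retained(self):
        sites = import_site_predictions(
            self.frame([("gX", 10, 17, "noncanonical", -0.25)]))
        assert len(sites) == 1 and sites[0].site_class == "noncanonical"

    def test_unfavorable_noncanonical_dropped(self):
        sites = import_site_predictions(
            self.frame([("gX", 10, 17, "noncanonical", -0.05)]))
        assert sites == []

    def test_empty_table(self):
        assert import_site_predictions(self.frame([])) == []

    def test_missing_columns(self):
        with pytest.raises(FormatError):
            import_site_predictions(pd.DataFrame({"gene_id": ["g"]}))

    def test_noncanonical_without_score_dropped(self, caplog):
        sites = import_site_predictions(
            self.frame([("gX", 10, 17, "noncanonical", np.nan)]))
        assert sites == []

    def test_one_based_coordinates_normalized(self):
        sites = import_site_predictions(
            self.frame([("gX", 11, 17, "seed7", np.nan)]), coords="1based-closed")
        assert (sites[0].start, sites[0].end) == (10, 17)

    def test_canonical_rows_pass_through(self):
        sites = import_site_predictions(
            self.frame([("gX", 0, 6, "seed6", np.nan)]))
        assert sites[0].site_class == "seed6" and sites[0].source == "imported"


def _aln_for_pattern(identical: set[str], site_seq="GTGCCTT", flank="AAA"):
    ref = flank + site_seq + flank
    rows = {"dmel": ref}
    mutated = flank + ("T" + site_seq[1:] if site_seq[0] != "T"
                       else "A" + site_seq[1:]) + flank
    for sp in MELANOGASTER_PANEL:
        rows[sp] = ref if sp in identical else mutated
    return rows


class TestConservation:
    site = TargetSite("g", 3, 10, "seed7")

    def test_exhaustive_64_patterns(self):
        """Every identity pattern of the 6-species panel follows the rule."""
        rule = conservation_rule("methods_5of6")
        for mask in range(64):
            identical = {sp for j, sp in enumerate(MELANOGASTER_PANEL)
                         if mask >> j & 1}
            expected = "well" if len(identical) >= 5 and "dpse" in identical \
                else "poor"
            got = classify_site_conservation(self.site,
                                             _aln_for_pattern(identical), rule)
            assert got == expected, identical

    def test_five_with_mandatory_is_well(self):
        aln = _aln_for_pattern({"dsec", "dsim", "dyak", "dere", "dpse"})
        assert classify_site_conservation(self.site, aln) == "well"

    def test_all_six_is_well(self):
        aln = _aln_for_pattern(set(MELANOGASTER_PANEL))
        assert classify_site_conservation(self.site, aln) == "well"

    def test_five_without_mandatory_is_poor(self):
        aln = _aln_for_pattern({"dsec", "dsim", "dyak", "dere", "dana"})
        assert classify_site_conservation(self.site, aln) == "poor"

    def test_gap_counts_as_non_identical(self):
        aln = _aln_for_pattern(set(MELANOGASTER_PANEL))
        aln["dpse"] = aln["dpse"][:5] + "-" + aln["dpse"][6:]
        assert classify_site_conservation(self.site, aln) == "poor"

    def test_missing_alignment_unassessed(self):
        assert classify_site_conservation(self.site, None) == "unassessed"
        assert classify_site_conservation(self.site, {}) == "unassessed"

    def test_outgroup_rule(self):
        rule = conservation_rule("outgroup_fig_s8")
        ref = "AAAGTGCCTTAAA"
        aln = {"dmel": ref, "dvir": ref}
        assert classify_site_conservation(self.site, aln, rule) == "well"
        aln = {"dmel": ref, "dvir": ref.replace("GTG", "GAG")}
        assert classify_site_conservation(self.site, aln, rule) == "poor"

    def test_unknown_rule(self):
        with pytest.raises(ValueError):
            conservation_rule("nope")


class TestGeneSummary:
    def test_precedence_seed7_over_seed6(self):
        sites = [TargetSite("g", 0, 6, "seed6"), TargetSite("g", 10, 17, "seed7")]
        summary = gene_site_summary(sites)
        assert summary.loc["g", "site_class"] == "seed7"

    def test_noncanonical_only(self):
        sites = [TargetSite("g", 0, 7, "noncanonical", score=-0.2,
                            source="imported")]
        assert gene_site_summary(sites).loc["g", "site_class"] == "noncanonical"

    def test_no_sites_absent(self):
        assert gene_site_summary([]).empty

    def test_best_conservation_wins(self):
        sites = [TargetSite("g", 0, 6, "seed6", conservation="poor"),
                 TargetSite("g", 10, 17, "seed7", conservation="well")]
        assert gene_site_summary(sites).loc["g", "conservation"] == "well"
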
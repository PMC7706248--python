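"""CAPS assay design: site scanning, digestion patterns, observed frequencies."""

import numpy as np
import pytest

from poolvar.caps import (IUPAC, GenotypeCounts, RestrictionEnzyme,
                          compare_predicted_observed, digest, find_sites,
                          observed_frequency, site_change)
from poolvar.datasets import (closest_caller_tally, load_enzymes,
                              load_validation_table, recompute_observed)
from poolvar.variants import VariantKey

NOTI = RestrictionEnzyme("NotI", "GCGGCCGC")
FOKI = RestrictionEnzyme("FokI", "GGATG")


def sliding_window_sites(seq: str, site: str) -> list[int]:
    """Brute-force both-strand scan, independent of the implementation."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R",
            "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
            "D": "H", "H": "D", "N": "N"}
    rc = "".join(comp[b] for b in reversed(site))
    hits = set()
    for pat in (site, rc):
        for i in range(len(seq) - len(pat) + 1):
            if all(seq[i + k] in IUPAC[p] for k, p in enumerate(pat)):
                hits.add(i + 1)
    return sorted(hits)


class TestFindSites:
    def test_noti_example(self):
        assert find_sites("AAGCGGCCGCTT", NOTI) == [3]

    def test_palindromic_site_counted_once(self):
        assert NOTI.palindromic
        assert len(find_sites("AAGCGGCCGCTT", NOTI)) == 1

    def test_absent_pattern_empty(self):
        assert find_sites("AAAAAAAAAA", NOTI) == []

    def test_non_palindromic_found_on_both_strands(self):
        # FokI GGATG; reverse complement CATCC
        assert find_sites("TTGGATGTT", FOKI) == [3]
        assert find_sites("TTCATCCTT", FOKI) == [3]

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError):
            find_sites("ACGTN", NOTI)

    def test_short_recognition_rejected(self):
        with pytest.raises(ValueError):
            RestrictionEnzyme("bad", "ACG")

    def test_matches_sliding_window_oracle(self, rng):
        enzymes = list(load_enzymes().values())
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=200))
            for enz in enzymes:
                assert find_sites(seq, enz) == sliding_window_sites(seq, enz.site)


class TestDigest:
    def test_uncut_single_fragment(self):
        pat = digest("AAAAAAAAAA", NOTI)
        assert pat.fragments == (10,)

    def test_fragments_sum_to_length(self, rng):
        enzymes = list(load_enzymes().values())
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            for enz in enzymes:
                assert digest(seq, enz).total == 300

    def test_constructed_cut_position(self):
        seq = "A" * 20 + "GCGGCCGC" + "A" * 20
        pat = digest(seq, NOTI)
        assert pat.fragments == (20, 28)


class TestSiteChange:
    def test_snv_creating_site_is_gain(self):
        seq = "TT" + "GCGGCCGA" + "TT"
        key = VariantKey("amp1", 10, "A", "C")  # ...GCGGCCGA -> GCGGCCGC
        change, ref_pat, alt_pat = site_change(seq, key, NOTI)
        assert change == "gain"
        assert len(alt_pat.fragments) == len(ref_pat.fragments) + 1

    def test_snv_destroying_site_is_loss(self):
        seq = "TT" + "GCGGCCGC" + "TT"
        key = VariantKey("amp1", 10, "C", "A")
        change, *_ = site_change(seq, key, NOTI)
        assert change == "loss"

    def test_distant_variant_no_change(self):
        seq = "A" * 50 + "GCGGCCGC" + "A" * 50
        key = VariantKey("amp1", 2, "A", "T")
        change, ref_pat, alt_pat = site_change(seq, key, NOTI)
        assert change == "none"
        assert ref_pat.fragments == alt_pat.fragments

    def test_length_conservation_600bp(self, rng):
        # one created cut near position 200 of a 600 bp amplicon
        seq = list(rng.choice(list("AT"), size=600))  # AT-only: no GC sites
        seq[199:207] = list("GCGGCCGA")
        seq = "".join(seq)
        key = VariantKey("amp1", 207, "A", "C")
        change, ref_pat, alt_pat = site_change(seq, key, NOTI)
        assert change == "gain"
        assert len(alt_pat.fragments) == 2
        assert sum(alt_pat.fragments) == 600 == sum(ref_pat.fragments)

    def test_indel_rescans_shifted_sequence(self):
        # deleting one base fuses GCGG|CCGC halves split by an extra A
        seq = "TT" + "GCGG" + "A" + "CCGC" + "TT"
        key = VariantKey("amp1", 6, "GA", "G")
        change, *_ = site_change(seq, key, NOTI)
        assert change == "gain"

    def test_reference_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            site_change("AAAA" * 5, VariantKey("amp1", 1, "C", "T"), NOTI)


class TestObservedFrequency:
    @pytest.mark.parametrize(
        "rr,ra,aa,expected",
        [
            (20, 5, 0, 0.10),       # 5 of 50 chromosomes
            (0, 0, 10, 1.0),        # fixation
            (11, 5, 0, 0.15625),    # 5/32
        ],
    )
    def test_formula(self, rr, ra, aa, expected):
        assert observed_frequency(GenotypeCounts(rr, ra, aa)) == \
            pytest.approx(expected)

    def test_two_decimal_reporting(self):
        f = observed_frequency(GenotypeCounts(11, 5, 0), rounded=True)
        assert f == 0.16

    def test_bounds_and_iff_conditions(self, rng):
        for _ in range(50):
            rr, ra, aa = (int(x) for x in rng.integers(0, 20, size=3))
            if rr + ra + aa == 0:
                continue
            f = observed_frequency(GenotypeCounts(rr, ra, aa))
            assert 0 <= f <= 1
            assert (f == 0) == (ra == 0 and aa == 0)
            assert (f == 1) == (rr == 0 and ra == 0)

    def test_adding_heterozygote_pulls_frequency_toward_half(self):
        # strictly increases whenever the current frequency is below 1/2
        for rr in range(2, 10):
            base = observed_frequency(GenotypeCounts(rr, 2, 1))
            more = observed_frequency(GenotypeCounts(rr, 3, 1))
            assert base < 0.5
            assert more > base

    def test_no_plants_rejected(self):
        with pytest.raises(ValueError):
            observed_frequency(GenotypeCounts(0, 0, 0))


class TestPredictedVsObserved:
    def test_published_assay_row_closest_caller(self):
        closest, dev = compare_predicted_observed(
            {"gatk": 0.88, "snver": 0.587, "crisp": 0.819}, 0.79)
        assert closest == ["crisp"]
        assert dev["crisp"] == pytest.approx(0.029)

    def test_tie_reports_all(self):
        closest, _ = compare_predicted_observed({"a": 0.5, "b": 0.5}, 0.4)
        assert sorted(closest) == ["a", "b"]

    def test_single_caller(self):
        closest, _ = compare_predicted_observed({"only": 0.2}, 0.9)
        assert closest == ["only"]


class TestValidationTable:
    def test_recomputed_frequencies_match_published(self):
        df = recompute_observed()
        known = df.dropna(subset=["n_homalt"])
        assert len(known) == 15
        assert np.allclose(known["vaf_obs_rounded"], known["vaf_obs"])

    def test_closest_caller_tally(self):
        tally = closest_caller_tally()
        assert tally["gatk"] == 7
        assert tally["snver"] == 2
        assert tally["crisp"] == 4

    def test_full_precision_example(self):
        df = recompute_observed()
        row = df[(df["gene"] == "PBF") & (df["pos"] == 810)
                 & (df["accession"] == "F11")].iloc[0]
        assert row["vaf_obs_recomputed"] == pytest.approx(5 / 32)
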
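import random

import pytest

from allelescope.restriction import digest, find_sites, probe_fragments, rflp_compare
from tests.conftest import random_seq


def naive_site_scan(seq: str, word: str) -> list[int]:
    return [i + 1 for i in range(len(seq) - len(word) + 1)
            if seq[i:i + len(word)] == word]


class TestFindSites:
    def test_single_and_tandem_occurrences(self):
        assert find_sites("AAGGCCTT", "GGCC") == [3]
        assert find_sites("GGCCGGCC", "GGCC") == [1, 5]

    def test_overlapping_occurrences_counted(self):
        assert find_sites("AAAA", "AA") == [1, 2, 3]

    def test_empty_pattern_rejected(self):
        with pytest.raises(ValueError):
            find_sites("ACGT", "")

    def test_n_never_matches(self):
        assert find_sites("GGNCC", "GGCC") == []

    def test_agrees_with_naive_window_scan(self, rng):
        for _ in range(200):
            seq = random_seq(rng, rng.randint(20, 400))
            word = random_seq(rng, rng.randint(2, 5))
            assert find_sites(seq, word) == naive_site_scan(seq, word)


class TestDigest:
    def test_single_blunt_cut(self):
        dig = digest("AAGGCCTT", "GGCC", 2)
        assert dig.fragment_lengths == (4, 4)

    def test_no_sites_yields_whole_sequence(self):
        dig = digest("ATATATAT", "GGCC", 2)
        assert dig.fragment_lengths == (8,)
        assert dig.site_positions == ()

    def test_fragment_lengths_always_sum_to_sequence_length(self, rng):
        for _ in range(300):
            seq = random_seq(rng, rng.randint(10, 500))
            dig = digest(seq, "GGCC", 2)
            assert sum(dig.fragment_lengths) == len(seq)
            assert len(dig.fragments) == len(
                {s + 1 for s in dig.site_positions if 0 < s + 1 < len(seq)}) + 1

    def test_agrees_with_reference_enzymology(self, rng):
        """HaeIII from the curated enzyme database is the independent oracle."""
        from Bio.Restriction import HaeIII
        from Bio.Seq import Seq

        for _ in range(50):
            seq = random_seq(rng, rng.randint(50, 800))
            ours = digest(seq, "GGCC", 2)
            theirs = sorted(HaeIII.search(Seq(seq)))  # 1-based first base after cut
            expected_cuts = sorted(s + 1 for s in ours.site_positions
                                   if 0 < s + 1 < len(seq))
            assert [c - 1 for c in theirs] == expected_cuts

    def test_removing_one_internal_site_merges_two_adjacent_fragments(self, rng):
        for _ in range(100):
            seq = random_seq(rng, 300)
            dig = digest(seq, "GGCC", 2)
            internal = [s for s in dig.site_positions if 4 < s < len(seq) - 4]
            # sites overlapping another site would not vanish cleanly
            isolated = [s for s in internal
                        if all(abs(s - t) >= 4 for t in dig.site_positions if t != s)]
            if not isolated:
                continue
            s = isolated[0]
            mutated = seq[:s - 1] + "T" + seq[s:]   # G -> T kills the word
            dig2 = digest(mutated, "GGCC", 2)
            if len(dig2.site_positions) != len(dig.site_positions) - 1:
                continue   # mutation may create a different word elsewhere
            assert len(dig2.fragments) == len(dig.fragments) - 1
            k = dig.site_positions.index(s)
            merged = dig.fragment_lengths[k] + dig.fragment_lengths[k + 1]
            assert merged in dig2.fragment_lengths


class TestProbeFragments:
    def test_contained_probe_returns_one_fragment(self):
        dig = digest("AAGGCCTT", "GGCC", 2)
        frags = probe_fragments(dig, (2, 3))
        assert [(f.start, f.end) for f in frags] == [(1, 4)]

    def test_probe_spanning_cut_returns_both_fragments(self):
        dig = digest("AAGGCCTT", "GGCC", 2)
        frags = probe_fragments(dig, (3, 6))
        assert [(f.start, f.end) for f in frags] == [(1, 4), (5, 8)]

    def test_interval_outside_sequence_rejected(self):
        dig = digest("AAGGCCTT", "GGCC", 2)
        with pytest.raises(ValueError):
            probe_fragments(dig, (5, 99))


class TestRflpOnPackagedPair:
    def test_reference_shows_five_sites_and_1097_bp_probe_fragment(self, pair):
        dig = digest(pair.reference)
        assert len(dig.site_positions) == 5
        frags = probe_fragments(dig, pair.probe_interval_ref)
        assert [f.length for f in frags] == [1097]

    def test_derived_allele_probe_fragment_lengthens_to_1594_bp(self, pair):
        dig = digest(pair.derived)
        assert len(dig.site_positions) == 4
        frags = probe_fragments(dig, pair.probe_interval_derived)
        assert [f.length for f in frags] == [1594]

    def test_site_loss_attributed_to_intron3_c_to_t(self, pair, merged_catalog):
        rep = rflp_compare(pair.reference, pair.derived,
                           probe_interval_a=pair.probe_interval_ref,
                           probe_interval_b=pair.probe_interval_derived,
                           catalog=merged_catalog)
        assert len(rep.sites_only_in_a) == 1
        assert rep.sites_only_in_b == ()
        (site,), = (rep.sites_only_in_a,)
        snv = rep.attributions[site]
        assert (snv.position, snv.ref_allele, snv.alt_allele) == (2029, "C", "T")
        assert rep.probe_lengths_a == (1097,)
        assert rep.probe_lengths_b == (1594,)

    def test_self_comparison_is_silent(self, pair):
        rep = rflp_compare(pair.reference, pair.reference,
                           probe_interval_a=pair.probe_interval_ref,
                           probe_interval_b=pair.probe_interval_ref)
        assert rep.sites_only_in_a == () and rep.sites_only_in_b == ()
        assert rep.probe_lengths_a == rep.probe_lengths_b
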
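import random

import pandas as pd
import pytest
from Bio.Seq import Seq

from allelescope.genemodel import AlleleSequence
from allelescope.pcr import (PrimerPair, ReferenceRule, ThresholdRule,
                             concordance, find_binding, genotype_panel,
                             predict_amplicon)
from allelescope.pipeline import packaged_phenotype_table
from allelescope.synthetic import make_panel
from tests.conftest import random_seq


def naive_binding(seq, primer, max_mismatch, exact3):
    """Independent Hamming scan in both orientations."""
    out = []
    for word, strand, right3 in ((primer, "+", True),
                                 (str(Seq(primer).reverse_complement()), "-", False)):
        m = len(word)
        for i in range(len(seq) - m + 1):
            window = seq[i:i + m]
            mm = [j for j in range(m) if window[j] != word[j] or window[j] == "N"]
            tail = range(m - exact3, m) if right3 else range(exact3)
            if len(mm) <= max_mismatch and not any(j in tail for j in mm):
                out.append((i + 1, strand))
    return sorted(out)


class TestFindBinding:
    def test_planted_primer_found_exactly_once(self, rng):
        primer = "CCCCTTAAAAACTGCTCCCATT"
        seq = random_seq(rng, 300).replace("CCCC", "ATAT") + primer \
            + random_seq(rng, 300).replace("CCCC", "ATAT")
        sites = [b for b in find_binding(seq, primer) if b.strand == "+"]
        assert len(sites) == 1

    def test_internal_mismatch_respects_threshold(self):
        primer = "AGCTTAGGCATCCAT"
        template = "TTTT" + primer[:7] + "A" + primer[8:] + "TTTT"
        assert find_binding(template, primer, max_mismatch=0) == []
        hits = find_binding(template, primer, max_mismatch=1)
        assert len(hits) == 1 and hits[0].mismatches == 1

    def test_3prime_mismatch_always_blocks(self):
        primer = "AGCTTAGGCATCCAT"
        template = "TTTT" + primer[:-1] + "G" + "TTTT"   # 3'-terminal mismatch
        assert find_binding(template, primer, max_mismatch=2) == []

    def test_agrees_with_naive_hamming_scan(self, rng):
        for _ in range(30):
            seq = random_seq(rng, 500)
            primer = random_seq(rng, rng.randint(10, 14))
            for mm in (0, 1, 2):
                ours = sorted((b.start, b.strand)
                              for b in find_binding(seq, primer, mm, 3))
                assert ours == naive_binding(seq, primer, mm, 3)


class TestPredictAmplicon:
    def _template(self, rng, pair, spacer):
        rc = str(Seq(pair.reverse).reverse_complement())
        return random_seq(rng, 120) + pair.forward + spacer + rc \
            + random_seq(rng, 120)

    def test_planted_sites_give_expected_product_length(self, rng):
        pair = PrimerPair("t", "CCCCTTAAAAACTGCTCCCATT",
                          "GGAGACCAAAGAATTACTAGTGAGTGA")
        spacer = random_seq(rng, 151)
        res = predict_amplicon(self._template(rng, pair, spacer), pair)
        assert res.status == "ok"
        assert res.amplicon.length == len(pair.forward) + 151 + len(pair.reverse)
        assert res.amplicon.sequence.startswith(pair.forward)

    def test_missing_reverse_site_means_no_amplification(self, rng):
        pair = PrimerPair("t", "CCCCTTAAAAACTGCTCCCATT",
                          "GGAGACCAAAGAATTACTAGTGAGTGA")
        template = random_seq(rng, 200) + pair.forward + random_seq(rng, 200)
        assert predict_amplicon(template, pair).status == "no-amplification"

    def test_reverse_complemented_template_gives_same_length(self, pair):
        res_fwd = predict_amplicon(pair.reference, pair.primer_pair)
        rc = str(Seq(pair.reference.residues).reverse_complement())
        res_rc = predict_amplicon(rc, pair.primer_pair)
        assert res_fwd.status == res_rc.status == "ok"
        assert res_fwd.amplicon.length == res_rc.amplicon.length

    def test_amplicon_difference_equals_net_indel_length(self, pair):
        ref = predict_amplicon(pair.reference, pair.primer_pair)
        der = predict_amplicon(pair.derived, pair.primer_pair)
        assert der.amplicon.length - ref.amplicon.length == 311

    def test_calls_invariant_to_sequence_outside_amplified_interval(self, pair,
                                                                    rng):
        amp = predict_amplicon(pair.reference, pair.primer_pair).amplicon
        residues = list(pair.reference.residues)
        for i in list(range(0, amp.start - 50)) + \
                list(range(amp.end + 50, len(residues))):
            if rng.random() < 0.02:
                residues[i] = rng.choice("ACGT")
        mutated = AlleleSequence(name="mut", residues="".join(residues),
                                 anchor=pair.reference.anchor)
        res = predict_amplicon(mutated, pair.primer_pair)
        assert res.status == "ok" and res.amplicon.length == amp.length


class TestGenotypePanel:
    def test_four_plus_seven_panel_calls(self, pair):
        calls = genotype_panel(make_panel(pair), pair.primer_pair)
        assert sum(c.call == "W3-type" for c in calls) == 4
        assert sum(c.call == "w3-type" for c in calls) == 7

    def test_boundary_length_is_ambiguous(self):
        rule = ThresholdRule(threshold=350)
        assert rule.classify(350) == "ambiguous"
        assert rule.classify(349) == "W3-type"
        assert rule.classify(351) == "w3-type"

    def test_reference_rule_tolerances(self):
        rule = ReferenceRule(w3_length=200, w3_derived_length=511, tolerance=50)
        assert rule.classify(205) == "W3-type"
        assert rule.classify(511) == "w3-type"
        assert rule.classify(355) == "ambiguous"

    def test_empty_panel_gives_empty_output(self, pair):
        assert genotype_panel([], pair.primer_pair) == []


class TestConcordance:
    def test_packaged_table_reports_three_database_conflicts(self, pair):
        calls = genotype_panel(make_panel(pair), pair.primer_pair)
        report = concordance(calls, packaged_phenotype_table())
        assert sorted(report.conflicts_db) == ["PI 437570", "PI 437918",
                                               "PI 550733"]
        assert report.conflicts_observed == ()

    def test_fully_concordant_panel_has_zero_conflicts(self, pair):
        calls = genotype_panel(make_panel(pair), pair.primer_pair)
        table = pd.DataFrame(
            [{"accession": c.accession,
              "db_phenotype": ("purple throat" if c.call == "W3-type"
                               else "near-white"),
              "observed_phenotype": ("purple throat" if c.call == "W3-type"
                                     else "near-white")} for c in calls])
        report = concordance(calls, table)
        assert report.conflicts_db == () and report.conflicts_observed == ()

    def test_conflict_count_matches_brute_force_recount(self, pair, rng):
        calls = genotype_panel(make_panel(pair), pair.primer_pair)
        phenos = ["purple throat", "near-white"]
        table = pd.DataFrame(
            [{"accession": c.accession, "db_phenotype": rng.choice(phenos),
              "observed_phenotype": rng.choice(phenos)} for c in calls])
        report = concordance(calls, table)
        expected = {"W3-type": "purple throat", "w3-type": "near-white"}
        brute = sum(1 for c in calls
                    if expected[c.call] != table.set_index("accession")
                    .loc[c.accession, "db_phenotype"])
        assert len(report.conflicts_db) == brute

    def test_missing_accessions_reported_and_excluded(self, pair):
        calls = genotype_panel(make_panel(pair)[:5], pair.primer_pair)
        report = concordance(calls, packaged_phenotype_table())
        assert set(c.accession for c in calls) - set(report.missing) \
            == {c.accession for c in calls}
        assert len(report.missing) > 0
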
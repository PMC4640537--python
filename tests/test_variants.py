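import random

import pytest

from allelescope._align import GLOBAL_SCORING
from allelescope.genemodel import AlleleSequence, GeneModel
from allelescope.variants import (Variant, annotate, apply_catalog, call_variants,
                                  global_align, merge_complex, protein_effect,
                                  write_catalog_vcf)
from tests.conftest import random_seq
from tests.dp_oracle import global_score


def plant_random_edits(rng, seq, n_edits):
    """Apply n scattered random edits; returns the edited sequence.

    Edit loci are kept >= 30 bp apart so truth stays unambiguous.
    """
    positions = sorted(rng.sample(range(20, len(seq) - 20), n_edits),
                       reverse=True)
    filtered = []
    for p in positions:
        if all(abs(p - q) >= 30 for q in filtered):
            filtered.append(p)
    out = seq
    for p in filtered:
        kind = rng.choice(["snv", "ins", "del"])
        if kind == "snv":
            alt = rng.choice([b for b in "ACGT" if b != out[p]])
            out = out[:p] + alt + out[p + 1:]
        elif kind == "ins":
            out = out[:p] + random_seq(rng, rng.randint(1, 12)) + out[p:]
        else:
            out = out[:p] + out[p + rng.randint(1, 12):]
    return out


class TestGlobalAlign:
    def test_identical_sequences_have_no_variants(self, rng):
        seq = random_seq(rng, 200)
        catalog = call_variants(global_align(seq, seq))
        assert len(catalog) == 0

    def test_single_base_deletion_called(self):
        catalog = call_variants(global_align("ACGT", "ACT"))
        assert len(catalog) == 1
        v = catalog.variants[0]
        assert v.vtype == "deletion" and v.ref_len == 1 and v.net_len == -1

    def test_score_matches_brute_force_dp(self, rng):
        s = GLOBAL_SCORING
        for _ in range(25):
            a = random_seq(rng, rng.randint(5, 60))
            b = plant_random_edits(rng, a, 3) if len(a) > 45 else random_seq(
                rng, rng.randint(5, 60))
            aln = global_align(a, b)
            assert aln.score == global_score(a, b, s.match, s.mismatch,
                                             s.gap_open, s.gap_extend)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACGT")


class TestCallVariantsRoundTrip:
    def test_reconstruction_for_random_planted_edit_pairs(self):
        rng = random.Random(424242)
        for _ in range(40):
            ref = random_seq(rng, rng.randint(300, 700))
            alt = plant_random_edits(rng, ref, rng.randint(1, 8))
            catalog = call_variants(global_align(ref, alt))
            assert apply_catalog(catalog, ref) == alt
            merged = merge_complex(catalog, window=10)
            assert apply_catalog(merged, ref) == alt

    def test_opposite_direction_flips_net_length_signs(self, rng):
        ref = random_seq(rng, 400)
        alt = plant_random_edits(rng, ref, 5)
        fwd = call_variants(global_align(ref, alt))
        rev = call_variants(global_align(alt, ref))
        assert len(fwd) == len(rev)
        assert sorted(v.net_len for v in fwd) == sorted(-v.net_len for v in rev)


class TestMergeComplex:
    def test_adjacent_insertion_and_deletion_merge_to_net_311(self, pair,
                                                              merged_catalog):
        cx = [v for v in merged_catalog if v.vtype == "complex_indel"]
        assert len(cx) == 1
        v = cx[0]
        assert (v.position, v.ref_len, v.alt_len, v.net_len) == (-230, 14, 325, 311)
        assert v.feature == "upstream"

    def test_indels_beyond_window_stay_separate(self, rng):
        ref = random_seq(rng, 200)
        # deletion at 50..53 and insertion before 120: 60+ bp apart
        alt = ref[:49] + ref[53:115] + "TTTTT" + ref[115:]
        catalog = merge_complex(call_variants(global_align(ref, alt)), window=10)
        assert sorted(v.vtype for v in catalog) == ["deletion", "insertion"]

    def test_merging_preserves_total_net_length(self, rng):
        for _ in range(20):
            ref = random_seq(rng, 400)
            alt = plant_random_edits(rng, ref, 6)
            catalog = call_variants(global_align(ref, alt))
            merged = merge_complex(catalog, window=25)
            assert merged.net_length == catalog.net_length

    def test_merged_catalog_still_round_trips(self, pair, merged_catalog):
        assert apply_catalog(merged_catalog, pair.reference) \
            == pair.derived.residues

    def test_snvs_survive_merging_untouched(self, pair, merged_catalog):
        snvs = merged_catalog.of_type("snv")
        assert all(v.ref_len == v.alt_len == 1 for v in snvs)
        assert len(snvs) == 9   # 4 upstream + 4 intronic + 1 exonic


class TestAnnotateAndProteinEffect:
    def _toy(self):
        # exon1 1-6, intron1 7-12, exon2 13-21; CDS ATG GGA GAC TAA
        model = GeneModel(gene_id="t", upstream_length=6,
                          exons=((1, 6), (13, 21)))
        residues = "TTTTTT" + "ATGGGA" + "TTTTTT" + "GACGGATAA"
        ref = AlleleSequence(name="ref", residues=residues, anchor=7)
        return model, ref

    def test_variant_positions_labelled_by_anchoring_base(self):
        model, ref = self._toy()
        alt_res = ref.residues[:4] + "G" + ref.residues[5:]      # upstream snv
        alt = AlleleSequence(name="alt", residues=alt_res, anchor=7)
        catalog = annotate(call_variants(global_align(ref, alt),
                                         ref_allele=ref), model)
        assert [v.feature for v in catalog] == ["upstream"]

    def test_exonic_snv_gives_amino_acid_substitution(self):
        model, ref = self._toy()
        # gene position 17 = CDS position 11 (codon 4: GGA); G->C makes GCA=Ala
        idx = ref.signed_to_index(17)
        alt_res = ref.residues[:idx - 1] + "C" + ref.residues[idx:]
        alt = AlleleSequence(name="alt", residues=alt_res, anchor=7)
        catalog = call_variants(global_align(ref, alt), ref_allele=ref)
        protein_effect(catalog, ref, alt, model)
        (v,) = catalog.variants
        assert v.feature == "exon 2"
        assert v.protein_effect == ("G", 4, "A")
        assert v.synonymous is False

    def test_synonymous_exonic_snv_flagged(self):
        model, ref = self._toy()
        # codon 2 GGA -> GGG is still Gly: gene position 6, A->G
        idx = ref.signed_to_index(6)
        alt_res = ref.residues[:idx - 1] + "G" + ref.residues[idx:]
        alt = AlleleSequence(name="alt", residues=alt_res, anchor=7)
        catalog = call_variants(global_align(ref, alt), ref_allele=ref)
        protein_effect(catalog, ref, alt, model)
        (v,) = catalog.variants
        assert v.protein_effect == ("G", 2, "G")
        assert v.synonymous is True

    def test_intronic_snv_has_no_protein_effect(self):
        model, ref = self._toy()
        idx = ref.signed_to_index(9)
        alt_res = ref.residues[:idx - 1] + "A" + ref.residues[idx:]
        alt = AlleleSequence(name="alt", residues=alt_res, anchor=7)
        catalog = call_variants(global_align(ref, alt), ref_allele=ref)
        protein_effect(catalog, ref, alt, model)
        (v,) = catalog.variants
        assert v.feature == "intron 1" and v.protein_effect is None

    def test_packaged_pair_shows_single_gly338ala(self, merged_catalog):
        effects = [v for v in merged_catalog
                   if isinstance(v.protein_effect, tuple)]
        assert len(effects) == 1
        assert effects[0].protein_effect == ("G", 338, "A")
        assert effects[0].position == 3941
        assert effects[0].feature == "exon 6"


class TestVcfOutput:
    def test_minimal_vcf_left_anchors_indels(self, tmp_path, rng):
        ref = random_seq(rng, 100)
        alt = ref[:40] + ref[52:]     # 12-bp deletion
        catalog = call_variants(global_align(ref, alt))
        out = tmp_path / "out.vcf"
        write_catalog_vcf(catalog, out)
        lines = [l for l in out.read_text().splitlines()
                 if not l.startswith("#")]
        assert len(lines) == 1
        chrom, pos, _, vref, valt, *_ = lines[0].split("\t")
        assert len(vref) == 13 and len(valt) == 1
        assert vref[0] == valt[0]     # left-anchor base shared
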
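"""Integrase anchoring, direct-repeat detection, junctions and presence."""

import numpy as np
import pytest

from mgescan.finder import (DirectRepeatPair, IntegraseAnchor, associate_trna,
                            cross_strain_presence, excise, find_direct_repeats,
                            find_elements, find_integrases, junctions,
                            select_element)
from mgescan.genome_io import Feature, GenomeRecord, GenomeSet
from mgescan.homology import ProteinRecord
from mgescan.pipeline import scan_genome
from mgescan.seedext import maximal_matches
from mgescan.synthetic import SimConfig, random_dna, reverse_translate, \
    simulate_strain_pair, _random_protein


def _cds(fid, start, end, product, replicon="chr"):
    return Feature(fid, replicon, start, end, "+", "CDS", product=product)


class TestSeedExtend:
    def test_exact_repeat_found_at_exact_coordinates(self, rng):
        a = random_dna(rng, 3000, 0.5)
        rep = random_dna(rng, 60, 0.5)
        b = random_dna(rng, 1000, 0.5) + rep + random_dna(rng, 1000, 0.5)
        a = a[:500] + rep + a[560:]
        hits = [m for m in maximal_matches(a, b, min_len=30) if m.length >= 30]
        # maximality may extend past the implant by chance base agreement,
        # so check containment on the implant diagonal
        assert any(m.a_start <= 500 and m.a_end >= 560
                   and m.b_start - m.a_start == 500 for m in hits)

    def test_mutated_repeat_found_above_identity_floor(self, rng):
        rep = random_dna(rng, 200, 0.5)
        noisy = list(rep)
        for p in range(10, 200, 25):  # 8 substitutions, 96% identity
            noisy[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[noisy[p]]
        a = random_dna(rng, 500, 0.5) + rep + random_dna(rng, 500, 0.5)
        b = random_dna(rng, 500, 0.5) + "".join(noisy) + random_dna(rng, 500, 0.5)
        hits = maximal_matches(a, b, min_len=100, min_identity=0.9)
        assert hits and hits[0].length >= 190


class TestFindIntegrases:
    FEATS = [
        _cds("c1", 0, 900, "tyrosine recombinase/integrase"),
        _cds("c2", 1000, 1900, "IS5 family transposase"),
        _cds("c3", 2000, 2900, "hypothetical protein"),
    ]

    def test_keyword_rules(self):
        anchors = find_integrases(self.FEATS, mode="keyword")
        assert [a.feature_id for a in anchors] == ["c1"]

    def test_cog_qualifier_hits(self):
        f = _cds("c9", 0, 900, "uncharacterized protein")
        f.qualifiers["db_xref"] = "COG4974"
        assert find_integrases([f], mode="keyword")

    def test_similarity_mode_requires_queries(self):
        with pytest.raises(ValueError):
            find_integrases(self.FEATS, mode="similarity")

    def test_similarity_mode_finds_encoded_integrase(self, rng):
        prot = _random_protein(rng, 300)
        nt = reverse_translate(prot)
        seq = random_dna(rng, 200, 0.5) + nt + random_dna(rng, 200, 0.5)
        rec = GenomeRecord("chr", seq)
        feats = [_cds("cX", 200, 200 + len(nt), "uncharacterized protein")]
        query = ProteinRecord("intQ", "ref", prot)
        anchors = find_integrases(feats, mode="similarity",
                                  query_proteins=[query], records=[rec])
        assert [a.feature_id for a in anchors] == ["cX"]


def _alt(base):
    return {"A": "C", "C": "G", "G": "T", "T": "A"}[base]


def _toy_element(rng, dl=77, dr=46, cargo_len=14_000, flank=12_000):
    """Random record with one implanted repeat-flanked element."""
    att = random_dna(rng, dl, 0.5)
    left = random_dna(rng, flank, 0.5)
    cargo = random_dna(rng, cargo_len, 0.5)
    right = random_dna(rng, flank, 0.5)
    # force boundary mismatches so the maximal match is the repeat itself
    if cargo[-1] == left[-1]:
        cargo = cargo[:-1] + _alt(cargo[-1])
    after_left_core = att[dr] if dl > dr else cargo[0]
    if right[0] == after_left_core:
        right = _alt(right[0]) + right[1:]
    seq = left + att + cargo + att[:dr] + right
    rec = GenomeRecord("chr", seq)
    a0 = flank
    anchor = IntegraseAnchor("int1", "chr", a0 + dl + 100, a0 + dl + 1000,
                             "keyword")
    extent = (a0, a0 + dl + cargo_len + dr)
    return rec, anchor, extent, att


class TestFindDirectRepeats:
    def test_implanted_pair_recovered(self, rng):
        rec, anchor, (start, end), att = _toy_element(rng)
        pairs = find_direct_repeats(rec, anchor)
        assert pairs
        best = pairs[0]
        assert (best.left_start, best.left_end) == (start, start + 46)
        assert (best.right_start, best.right_end) == (end - 46, end)
        assert best.identity == 1.0

    def test_repeat_below_min_length_ignored(self, rng):
        rec, anchor, _, _ = _toy_element(rng, dl=10, dr=10)
        assert find_direct_repeats(rec, anchor, min_len=14) == []

    def test_truncated_right_repeat_detected_core(self, rng):
        rec, anchor, (start, end), att = _toy_element(rng, dl=77, dr=46)
        best = find_direct_repeats(rec, anchor)[0]
        assert best.right_len == 46

    def test_edge_anchor_warns_and_returns_empty(self):
        rec = GenomeRecord("chr", "ACGT" * 5)
        anchor = IntegraseAnchor("i", "chr", 0, 12, "keyword")
        with pytest.warns(UserWarning, match="no usable flank"):
            assert find_direct_repeats(rec, anchor, flank_window=2) == []


class TestAssociateTrna:
    def _pair(self):
        return DirectRepeatPair("chr", 1000, 1077, 21000, 21046, 1.0)

    def test_trna_three_prime_within_range_labels_pair(self):
        trna = Feature("t1", "chr", 944, 1020, "+", "tRNA",
                       product="tRNA-Met-CAT")
        pair = associate_trna(self._pair(), [trna])
        assert pair.att_label == "Met-CAT"
        assert pair.is_trna_associated

    def test_no_trna_keeps_non_trna_label(self):
        far = Feature("t1", "chr", 5000, 5076, "+", "tRNA",
                      product="tRNA-Met-CAT")
        assert associate_trna(self._pair(), [far]).att_label == "non-tRNA"

    def test_tmrna_target_accepted(self):
        srra = Feature("s1", "chr", 944, 1020, "+", "other",
                       product="srrA tmRNA")
        assert associate_trna(self._pair(), [srra]).att_label == "srrA tmRNA"


class TestSelectElement:
    anchor = IntegraseAnchor("i", "chr", 1200, 2400, "keyword")

    def _rec(self, rng):
        return GenomeRecord("chr", random_dna(rng, 40_000, 0.5))

    def test_single_pair_gives_span_sized_element(self, rng):
        pair = DirectRepeatPair("chr", 1000, 1077, 21000, 21077, 1.0)
        el = select_element([pair], self.anchor, self._rec(rng), [],
                            element_id="e")
        assert el.size_bp == pair.span == 20_077

    def test_trna_pair_beats_longer_non_trna_pair(self, rng):
        trna_pair = DirectRepeatPair("chr", 1000, 1046, 21000, 21046, 1.0,
                                     trna_id="t1", att_label="Met-CAT")
        longer = DirectRepeatPair("chr", 900, 1100, 30900, 31100, 1.0)
        el = select_element([longer, trna_pair], self.anchor, self._rec(rng),
                            [], element_id="e")
        assert el.repeat is trna_pair

    def test_sub_minimum_span_not_reported(self, rng):
        pair = DirectRepeatPair("chr", 1000, 1046, 3000, 3046, 1.0)
        assert select_element([pair], self.anchor, self._rec(rng), []) is None

    def test_deterministic_choice(self, rng):
        rec = self._rec(rng)
        pairs = [DirectRepeatPair("chr", 1000, 1050, 21000, 21050, 1.0),
                 DirectRepeatPair("chr", 990, 1040, 25990, 26040, 1.0)]
        first = select_element(list(pairs), self.anchor, rec, [],
                               element_id="e")
        second = select_element(list(reversed(pairs)), self.anchor, rec, [],
                                element_id="e")
        assert (first.start, first.end) == (second.start, second.end)


class TestJunctions:
    def test_toy_junctions_match_hand_assembly(self, rng):
        rec, anchor, (start, end), att = _toy_element(
            rng, dl=20, dr=20, cargo_len=8000, flank=6000)
        pairs = find_direct_repeats(rec, anchor)
        el = select_element(pairs, anchor, rec, [], element_id="e")
        seq = rec.sequence
        rep = el.repeat
        expected_attb = (seq[rep.left_start - 200:rep.left_start]
                         + seq[rep.left_start:rep.left_end]
                         + seq[rep.right_end:rep.right_end + 200])
        expected_atti = (seq[rep.right_start - 200:rep.right_start]
                         + seq[rep.right_start:rep.right_end]
                         + seq[rep.left_end:rep.left_end + 200])
        assert el.att_b == expected_attb
        assert el.att_i == expected_atti

    def test_attb_contains_no_cargo_atti_contains_cargo_ends(self, rng):
        rec, anchor, (start, end), att = _toy_element(rng)
        el = select_element(find_direct_repeats(rec, anchor), anchor, rec, [],
                            element_id="e")
        cargo = rec.sequence[el.repeat.left_end:el.repeat.right_start]
        assert cargo[:150] not in el.att_b
        assert cargo[-150:] not in el.att_b
        assert cargo[-150:] in el.att_i

    def test_excision_reconstructs_original_locus(self, rng):
        """Empty site + circle re-inserted after the repeat equals the
        original replicon, with the repeat duplicated exactly once."""
        rec, anchor, _, _ = _toy_element(rng)
        el = select_element(find_direct_repeats(rec, anchor), anchor, rec, [],
                            element_id="e")
        empty, circle = excise(el, rec)
        rep = el.repeat
        assert len(empty) + len(circle) == len(rec.sequence)
        reinserted = empty[:rep.left_end] + circle + empty[rep.left_end:]
        assert reinserted == rec.sequence
        # one repeat copy in each excision product
        repeat_seq = rec.sequence[rep.left_start:rep.left_end]
        assert empty.count(repeat_seq) == 1
        assert circle.count(repeat_seq[: rep.right_len]) == 1


class TestCrossStrainPresence:
    def test_same_strain_is_present(self, small_pair):
        genome = small_pair.genome_a
        elements, _ = scan_genome(genome)
        rec = genome.record(elements[0].replicon_id)
        assert cross_strain_presence(elements[0], rec, genome) == "present"

    def test_strain_specific_element_absent_with_empty_site(self, small_pair):
        elements, _ = scan_genome(small_pair.genome_a)
        truth_gi = next(t for t in small_pair.truth_for("A")
                        if t.element_id == "gi")
        el = next(e for e in elements if e.start == truth_gi.start)
        rec = small_pair.genome_a.record(el.replicon_id)
        status = cross_strain_presence(el, rec, small_pair.genome_b)
        assert status == "absent_with_empty_site"

    def test_unrelated_genome_has_no_site(self, small_pair, rng):
        elements, _ = scan_genome(small_pair.genome_a)
        rec = small_pair.genome_a.record(elements[0].replicon_id)
        other = GenomeSet("X", [GenomeRecord("chr", random_dna(rng, 100_000,
                                                               0.5))], [])
        assert cross_strain_presence(elements[0], rec, other) == "no_site"


class TestFalsePositives:
    def test_lone_integrase_without_repeats_yields_nothing(self, rng):
        seq = random_dna(rng, 200_000, 0.61)
        rec = GenomeRecord("chr", seq)
        feats = [_cds("i1", 100_000, 101_200, "site-specific integrase")]
        genome = GenomeSet("S", [rec], feats)
        assert find_elements(genome) == []

    def test_implant_free_genome_yields_nothing(self):
        cfg = SimConfig(seed=42, implants=(),
                        replicons=(("chromosome", 500_000, "linear", 0.61),),
                        orthologs=(), unique_a=0, unique_b=0)
        pair = simulate_strain_pair(cfg)
        assert find_elements(pair.genome_a) == []
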
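"""Module detection, TA pairing, ICE/IME/GI/prophage rules and families."""

import itertools

import pytest

from mgescan.classify import (DEFAULT_CATALOG, ModuleHit, assign_family,
                              classify, detect_modules, load_catalog,
                              pair_toxin_antitoxin, summarize)
from mgescan.genome_io import Feature
from mgescan.pipeline import scan_genome
from mgescan.synthetic import SimConfig, ImplantSpec, simulate_strain_pair


def _cds(fid, start, product):
    return Feature(fid, "chr", start, start + 600, "+", "CDS", product=product)


def _hits(features):
    return detect_modules(features, DEFAULT_CATALOG)


class TestDetectModules:
    def test_t4ss_and_coupling_products(self):
        feats = [_cds("a", 0, "TrbL conjugal transfer protein"),
                 _cds("b", 1000, "VirB4 secretion component"),
                 _cds("c", 2000, "VirD4 coupling protein")]
        tags = {h.tag for h in _hits(feats)}
        assert tags == {"t4ss", "virD4"}

    def test_toxin_antitoxin_products(self):
        feats = [_cds("t", 0, "MazF toxin"), _cds("a", 700, "MazE antitoxin")]
        roles = {h.role for h in _hits(feats)}
        assert roles == {"toxin", "antitoxin"}

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            detect_modules([], ())

    def test_catalog_tsv_round_trip(self, tmp_path):
        p = tmp_path / "catalog.tsv"
        p.write_text("tag\tpatterns\trole\ncustom\tmycin;other\tmodule\n")
        catalog = load_catalog(p)
        assert catalog[0].tag == "custom"
        assert catalog[0].patterns == ("mycin", "other")


class TestPairToxinAntitoxin:
    def test_adjacent_pair(self):
        feats = [_cds("t", 0, "VapC toxin"), _cds("a", 700, "Phd antitoxin")]
        pairs, orphans = pair_toxin_antitoxin(_hits(feats), feats)
        assert len(pairs) == 1 and not orphans
        assert (pairs[0][0].tag, pairs[0][1].tag) == ("tox_VapC", "anti_Phd")

    def test_lone_toxin_is_orphan(self):
        feats = [_cds("t", 0, "VapC toxin"), _cds("x", 700, "hypothetical")]
        pairs, orphans = pair_toxin_antitoxin(_hits(feats), feats)
        assert pairs == [] and orphans == ["tox_VapC"]

    def test_distant_genes_not_paired(self):
        feats = ([_cds("t", 0, "VapC toxin")]
                 + [_cds(f"x{i}", 700 * (i + 1), "hypothetical")
                    for i in range(4)]
                 + [_cds("a", 3500, "Phd antitoxin")])
        pairs, _ = pair_toxin_antitoxin(_hits(feats), feats)
        assert pairs == []

    def test_interleaved_systems_greedy_nearest(self):
        feats = [_cds("t1", 0, "MazF toxin"), _cds("a1", 700, "MazE antitoxin"),
                 _cds("t2", 1400, "HigB toxin"), _cds("a2", 2100, "HigA antitoxin")]
        pairs, orphans = pair_toxin_antitoxin(_hits(feats), feats)
        assert len(pairs) == 2 and not orphans
        # exhaustive oracle: nearest-distance matching is unique here
        got = {(t.feature_id, a.feature_id) for t, a in pairs}
        assert got == {("t1", "a1"), ("t2", "a2")}


def _mk_hits(tags, n_t4ss=0):
    hits = [ModuleHit(t, f"f{i}", "module", t) for i, t in enumerate(tags)]
    hits += [ModuleHit("t4ss", f"g{i}", "t4ss", f"virB{i+1}")
             for i in range(n_t4ss)]
    return hits


class TestClassifyRules:
    def test_ice_from_t4ss(self):
        cls = classify(_mk_hits({"int", "parAB"}, n_t4ss=7), 104_341)
        assert cls.label == "ICE"

    def test_ime_from_relaxase_plus_coupling(self):
        cls = classify(_mk_hits({"int", "virD2", "virD4"}), 80_923)
        assert cls.label == "IME"

    def test_gi_from_bare_integrase(self):
        assert classify(_mk_hits({"int"}), 13_644).label == "GI"

    def test_prophage_from_phage_module_set(self):
        cls = classify(_mk_hits({"int", "xis", "cI", "cro"}), 59_363)
        assert cls.label == "prophage"

    def test_phage_regulators_with_t4ss_stay_ice(self):
        cls = classify(_mk_hits({"int", "xis", "cI", "cII", "cro"}, n_t4ss=7),
                       183_318)
        assert cls.label == "ICE"

    def test_small_element_without_evidence_unclassified(self):
        assert classify(_mk_hits({"int"}), 3_000).label == "unclassified"

    def test_adding_t4ss_never_demotes(self):
        base = classify(_mk_hits({"int"}, n_t4ss=4), 20_000)
        more = classify(_mk_hits({"int"}, n_t4ss=8), 20_000)
        assert base.label == more.label == "ICE"

    def test_removing_mobility_evidence_yields_gi(self):
        cls = classify(_mk_hits({"int", "parAB"}), 20_000)
        assert cls.label == "GI"

    def test_rule_order_is_total(self):
        tags = ["int", "xis", "cI", "cro", "virD2", "virD4", "parAB"]
        for r in range(len(tags) + 1):
            for combo in itertools.combinations(tags, r):
                for n in (0, 5):
                    label = classify(_mk_hits(set(combo), n_t4ss=n), 10_000).label
                    assert label in {"ICE", "IME", "GI", "prophage"}


@pytest.fixture(scope="module")
def family_pair():
    """Two strains with ICE-type elements sharing a 56-kb backbone; the
    strain-A copy lacks T4SS genes and relies on family promotion."""
    cfg = SimConfig(
        seed=21,
        replicons=(("chromosome", 400_000, "linear", 0.61),),
        implants=(
            ImplantSpec("iceA", "GI", 70_000, 77, 46, "CAT", strains=("A",),
                        module_inventory=("int", "parAB", "ta_higBA"),
                        backbone_id="fam1", backbone_len=56_000),
            ImplantSpec("iceB", "ICE", 80_000, 77, 46, "GTT", strains=("B",),
                        backbone_id="fam1", backbone_len=56_000,
                        backbone_divergence=0.02),
            ImplantSpec("loner", "GI", 20_000, 77, 77, "CCG", strains=("B",)),
        ),
        orthologs=(), unique_a=0, unique_b=0,
    )
    return simulate_strain_pair(cfg)


class TestAssignFamily:
    def test_shared_backbone_joins_family_and_promotes(self, family_pair):
        els_a, _ = scan_genome(family_pair.genome_a)
        els_b, _ = scan_genome(family_pair.genome_b)
        elements = els_a + els_b
        seqs = {}
        for el, genome in [(e, family_pair.genome_a) for e in els_a] + \
                          [(e, family_pair.genome_b) for e in els_b]:
            seqs[el.element_id] = genome.record(
                el.replicon_id).sequence[el.start:el.end]
        labels_before = {e.element_id: e.classification.label for e in elements}
        fams = assign_family(elements, seqs)
        ice_a = next(e for e in els_a if e.size_bp == 70_000)
        ice_b = next(e for e in els_b if e.size_bp == 80_000)
        loner = next(e for e in els_b if e.size_bp == 20_000)
        assert fams[ice_a.element_id] == fams[ice_b.element_id]
        assert fams[loner.element_id] != fams[ice_a.element_id]
        assert labels_before[ice_a.element_id] == "GI"
        assert ice_a.classification.label == "ICE"
        assert ice_a.classification.by_family
        assert not ice_b.classification.by_family


class TestSummarize:
    def test_report_rows_match_truth(self, small_pair):
        _, report = scan_genome(small_pair.genome_a)
        truth = {t.start: t for t in small_pair.truth_for("A")}
        assert len(report) == len(truth)
        for _, row in report.iterrows():
            t = truth[row["start"]]
            assert row["type"] == t.element_class
            assert row["size_bp"] == t.size_bp
            assert row["att"] == t.att_label
            assert row["orf_count"] == t.n_orfs

    def test_empty_element_list_gives_header_only(self):
        report = summarize([], strain_id="S")
        assert len(report) == 0
        assert "MGE_ID" in report.columns

    def test_dr_rendering(self, small_pair):
        _, report = scan_genome(small_pair.genome_a)
        assert report["dr"].str.match(r"DR \(\d+, \d+\)").all()
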
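"""Dual-site pairing, tasi element detection, phasing, classification and
TAS6-TAS3 complexes."""

import numpy as np
import pytest

from tas3scan.seqs import SequenceRecord, as_dna, random_dna, revcomp
from tas3scan.simulate import (FeatureKind, FeatureSpec,
                               make_tas3_locus, make_tas6_tas3_complex,
                               plant_features)
from tas3scan.targets import find_target_sites
from tas3scan.taslocus import (ArchitectureClass, PhaseParams, Tas3Locus,
                               ap2_functionality, classify_architecture,
                               detect_tas6_tas3_complex, detect_tasi_elements,
                               pair_dual_sites, phase_register,
                               resolve_locus_overlaps, scan_tas_loci)

GUIDE = "AAGCTCAGGAGGGATAGCGCC"


def locus_from_record(record, guide=GUIDE, span_range=(150, 400)):
    hits = find_target_sites(record, guide, 4.0)
    cands = pair_dual_sites(hits, span_range)
    return resolve_locus_overlaps(cands)


class TestPairDualSites:
    def test_planted_256_span_locus(self, cfg):
        rec, truth = make_tas3_locus(ArchitectureClass.ONE_TASIAP2_ONLY,
                                     GUIDE, cfg.tasi_refs, spacing=214,
                                     seed=11)
        loci = locus_from_record(rec)
        assert len(loci) == 1
        assert loci[0].length == 256
        assert (loci[0].start, loci[0].end) == (0, 256)

    def test_opposite_strand_sites_never_pair(self, rng):
        site = revcomp(GUIDE)
        seq = (random_dna(rng, 100) + site + random_dna(rng, 150)
               + revcomp(site) + random_dna(rng, 100))
        hits = find_target_sites(SequenceRecord("t", seq), GUIDE, 4.0)
        strands = {h.strand for h in hits if h.penalty == 0.0}
        assert strands == {"+", "-"}
        assert pair_dual_sites(hits, (100, 400)) == []

    def test_three_sites_give_three_candidates(self, rng):
        site = revcomp(GUIDE)
        seq = (random_dna(rng, 50) + site + random_dna(rng, 80) + site
               + random_dna(rng, 80) + site + random_dna(rng, 50))
        hits = [h for h in find_target_sites(SequenceRecord("t", seq), GUIDE,
                                             4.0) if h.penalty == 0.0]
        assert len(hits) == 3
        cands = pair_dual_sites(hits, (50, 500))
        assert len(cands) == 3  # (A,B), (B,C), (A,C)
        spans = sorted(c.length for c in cands)
        assert spans[2] > spans[0] and spans[2] > spans[1]


class TestDetectTasiElements:
    def test_planted_plus_strand_ap2_identity_one(self, cfg, rng):
        name, kind, ref = next(r for r in cfg.tasi_refs if r[1] == "AP2")
        region = random_dna(rng, 80) + ref + random_dna(rng, 80)
        hits = detect_tasi_elements(region, cfg.tasi_refs, 0.75)
        ap2 = [h for h in hits if h.kind == "AP2"]
        assert len(ap2) == 1
        assert ap2[0].identity == 1.0
        assert ap2[0].strand_of_match == "+"
        assert (ap2[0].start, ap2[0].end) == (80, 80 + len(ref))

    def test_minus_strand_arf_reports_minus(self, cfg, rng):
        name, kind, ref = next(r for r in cfg.tasi_refs if r[1] == "ARF")
        region = random_dna(rng, 60) + revcomp(ref) + random_dna(rng, 60)
        hits = [h for h in detect_tasi_elements(region, cfg.tasi_refs, 0.75)
                if h.kind == "ARF"]
        assert len(hits) == 1
        assert hits[0].strand_of_match == "-"

    def test_identity_threshold_boundary(self, cfg, rng):
        # 21-mer at 0.75: 16/21 matches pass, 15/21 fail
        name, kind, ref = next(r for r in cfg.tasi_refs if r[1] == "ARF")
        for n_subs, expect_hit in ((5, True), (6, False)):
            mutated = list(ref)
            for pos in range(0, 3 * n_subs, 3):
                mutated[pos] = {"A": "C", "C": "A", "G": "T",
                                "T": "G"}[mutated[pos]]
            region = "T" * 40 + "".join(mutated) + "T" * 40
            hits = [h for h in detect_tasi_elements(region, [(name, kind,
                                                              ref)], 0.75)]
            assert bool(hits) == expect_hit, n_subs

    def test_single_indel_match_found(self, cfg):
        name, kind, ref = next(r for r in cfg.tasi_refs if r[1] == "ARF")
        dropped = ref[:10] + ref[11:]  # one deletion
        region = "A" * 50 + dropped + "A" * 50
        hits = [h for h in detect_tasi_elements(region, [(name, kind, ref)],
                                                0.75) if h.kind == "ARF"]
        assert hits
        assert hits[0].identity == pytest.approx(20 / 21, abs=1e-4)

    def test_empty_reference_set_is_an_error(self):
        with pytest.raises(ValueError):
            detect_tasi_elements("ACGT" * 30, [], 0.75)


class TestPhaseRegister:
    def _locus(self, cfg, phase_offset=0, seed=21):
        rec, truth = make_tas3_locus(ArchitectureClass.TWO_TASIARF_TANDEM,
                                     GUIDE, cfg.tasi_refs, spacing=214,
                                     seed=seed, phase_offset=phase_offset)
        loci = scan_tas_loci(rec, find_target_sites(rec, GUIDE, 4.0),
                             cfg.tasi_refs)
        assert len(loci) == 1
        return rec, truth, loci[0]

    def test_cleavage_coordinate_registers_zero(self, cfg):
        _, _, locus = self._locus(cfg)
        origin = locus.site3.cleavage_coord
        assert phase_register(locus, origin) == 0

    def test_mod21_periodicity(self, cfg):
        _, _, locus = self._locus(cfg)
        origin = locus.site3.cleavage_coord
        assert phase_register(locus, origin - 42) == 0
        assert phase_register(locus, origin - 43) == 1

    def test_planted_elements_in_phase(self, cfg):
        _, _, locus = self._locus(cfg)
        assert locus.tasi_hits
        assert all(h.phase_register == 0 for h in locus.tasi_hits)

    def test_planted_off_phase_elements_register_three(self, cfg):
        _, _, locus = self._locus(cfg, phase_offset=3, seed=22)
        assert locus.tasi_hits
        assert all(h.phase_register == 3 for h in locus.tasi_hits)

    def test_position_outside_phased_region_raises(self, cfg):
        _, _, locus = self._locus(cfg)
        with pytest.raises(ValueError):
            phase_register(locus, locus.end + 50)

    def test_register_invariant_under_whole_locus_translation(self, cfg,
                                                              sim_defaults):
        spec = FeatureSpec(FeatureKind.TAS3_LOCUS,
                           architecture=ArchitectureClass.TWO_TASIARF_TANDEM)
        for seed in (31, 32):
            genome, truths = plant_features(3000, [spec], seed=seed,
                                            defaults=sim_defaults)
            loci = scan_tas_loci(genome,
                                 find_target_sites(genome, GUIDE, 4.0),
                                 truths and sim_defaults["tasi_refs"])
            assert len(loci) == 1
            assert all(h.phase_register == 0 for h in loci[0].tasi_hits)


class TestClassifyArchitecture:
    @pytest.mark.parametrize("arch", [
        ArchitectureClass.ONE_TASIAP2_ONLY,
        ArchitectureClass.ONE_TASIAP2_ONE_TASIARF,
        ArchitectureClass.ONE_TASIARF_ONLY,
        ArchitectureClass.TWO_TASIARF_TANDEM,
        ArchitectureClass.TWO_TASIARF_SPACER,
    ])
    def test_generator_classes_round_trip(self, cfg, arch):
        rec, truth = make_tas3_locus(arch, GUIDE, cfg.tasi_refs,
                                     spacing=214, seed=41)
        loci = scan_tas_loci(rec, find_target_sites(rec, GUIDE, 4.0),
                             cfg.tasi_refs,
                             ap2_target_ref=cfg.ap2_target_ref)
        assert len(loci) == 1
        assert loci[0].architecture == arch

    def test_tandem_vs_spacer_gap_rule(self, cfg):
        tandem, _ = make_tas3_locus(ArchitectureClass.TWO_TASIARF_TANDEM,
                                    GUIDE, cfg.tasi_refs, seed=42)
        spacer, _ = make_tas3_locus(ArchitectureClass.TWO_TASIARF_SPACER,
                                    GUIDE, cfg.tasi_refs, seed=42)
        t = scan_tas_loci(tandem, find_target_sites(tandem, GUIDE, 4.0),
                          cfg.tasi_refs)[0]
        s = scan_tas_loci(spacer, find_target_sites(spacer, GUIDE, 4.0),
                          cfg.tasi_refs)[0]
        arf_t = sorted([h for h in t.tasi_hits if h.kind == "ARF"],
                       key=lambda h: h.start)
        arf_s = sorted([h for h in s.tasi_hits if h.kind == "ARF"],
                       key=lambda h: h.start)
        assert arf_t[1].start - arf_t[0].end < 10
        assert arf_s[1].start - arf_s[0].end >= 10

    def test_unclassified_without_elements(self, cfg):
        rec, _ = make_tas3_locus(ArchitectureClass.ONE_TASIARF_ONLY, GUIDE,
                                 cfg.tasi_refs, seed=43)
        locus = locus_from_record(rec)[0]
        locus.tasi_hits = []
        assert classify_architecture(locus) == \
            ArchitectureClass.UNCLASSIFIED


class TestTas6Tas3Complex:
    def test_planted_complex_total_span_895(self, cfg, sim_defaults):
        # tas6 (161) + gap (478) + tas3 (256) = 895, the PpTAS3a-like span
        rec, t6, t3 = make_tas6_tas3_complex(
            GUIDE, sim_defaults["guide156"], sim_defaults["guide529"],
            cfg.tasi_refs, gap=478, seed=51)
        assert len(rec) == 895
        from tas3scan.pipeline import scan_record
        res = scan_record(rec, cfg)
        assert len(res["complexes"]) == 1
        cx = res["complexes"][0]
        assert cx.total_length == 895
        assert cx.tas3.architecture == ArchitectureClass.TAS6_TAS3

    def test_gap_beyond_max_is_rejected(self, cfg, sim_defaults):
        rec, t6, t3 = make_tas6_tas3_complex(
            GUIDE, sim_defaults["guide156"], sim_defaults["guide529"],
            cfg.tasi_refs, gap=478, seed=52)
        from tas3scan.pipeline import scan_record
        res = scan_record(rec, cfg)
        assert detect_tas6_tas3_complex(res["tas6_loci"], res["loci"],
                                        max_gap=100) == []

    def test_tas6_downstream_is_rejected(self, cfg, sim_defaults):
        rec, t6, t3 = make_tas6_tas3_complex(
            GUIDE, sim_defaults["guide156"], sim_defaults["guide529"],
            cfg.tasi_refs, gap=200, seed=53)
        from tas3scan.pipeline import scan_record
        res = scan_record(rec, cfg)
        # flip roles: pretend the TAS3 list is the upstream partner set
        swapped = detect_tas6_tas3_complex(res["loci"], res["tas6_loci"],
                                           max_gap=1500)
        assert swapped == []


class TestAp2Functionality:
    def test_perfect_complement_is_functional(self):
        elem = "TGGCATGATCTTGATCCAGCT"
        target = revcomp(elem)
        out = ap2_functionality(elem, target, max_breaking_subs=3)
        assert out == {"functional": True, "breaking_subs": 0}

    def test_five_breaking_subs_exceed_budget_of_three(self):
        elem = list("TGGCATGATCTTGATCCAGCT")
        target = revcomp("".join(elem))
        # five C<->A style changes that can neither WC- nor wobble-pair
        flip = {"A": "C", "C": "A", "G": "A", "T": "C"}
        for pos in (0, 4, 8, 12, 16):
            elem[pos] = flip[elem[pos]]
        out = ap2_functionality("".join(elem), target, max_breaking_subs=3)
        assert out["breaking_subs"] == 5
        assert out["functional"] is False

    def test_wobble_tolerated_until_substitution_breaks_it(self):
        # element G opposite target C pairs WC; G->A yields A:C (broken).
        # element G opposite target T is a wobble and does not count.
        elem = "TGGCATGATCTTGATCCAGCT"
        target = revcomp(elem)
        g_pos = elem.index("G")
        broken = elem[:g_pos] + "A" + elem[g_pos + 1:]
        assert ap2_functionality(broken, target)["breaking_subs"] == 1
        wob_target = list(target)
        # target base opposite element position g_pos is target[-1-g_pos]
        assert wob_target[len(target) - 1 - g_pos] == "C"
        wob_target[len(target) - 1 - g_pos] = "T"
        out = ap2_functionality(elem, "".join(wob_target))
        assert out["breaking_subs"] == 0

    def test_missing_reference_is_an_error(self):
        with pytest.raises(ValueError):
            ap2_functionality("ACGT" * 5 + "A", "")


class TestStrandSymmetry:
    def test_minus_strand_locus_mirrors_plus_result(self, cfg, sim_defaults):
        spec = FeatureSpec(FeatureKind.TAS3_LOCUS,
                           architecture=ArchitectureClass.TWO_TASIARF_SPACER,
                           strand="-")
        genome, truths = plant_features(3000, [spec], seed=61,
                                        defaults=sim_defaults)
        from tas3scan.pipeline import scan_record
        res = scan_record(genome, cfg)
        assert len(res["loci"]) == 1
        locus = res["loci"][0]
        t = truths[0]
        assert (locus.start, locus.end, locus.strand) == \
            (t.start, t.end, "-")
        assert locus.architecture == t.architecture

        flipped = genome.reverse_complement("flipped")
        res2 = scan_record(flipped, cfg)
        assert len(res2["loci"]) == 1
        m = res2["loci"][0]
        n = len(genome)
        assert (m.start, m.end) == (n - locus.end, n - locus.start)
        assert m.strand == "+"
        assert m.architecture == locus.architecture
        assert sorted(h.phase_register for h in m.tasi_hits) == \
            sorted(h.phase_register for h in locus.tasi_hits)
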
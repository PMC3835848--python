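"""Inverted-repeat search and the four strict precursor criteria."""

import numpy as np
import pytest

from tas3scan.fold import HairpinFold, fold_best_hairpin, parse_dot_bracket
from tas3scan.precursor import (ConfigError, StrictCriteriaParams,
                                duplex_geometry, evaluate_criteria,
                                evaluate_precursor, find_duplex_candidates,
                                merge_candidates, scan_precursors)
from tas3scan.seqs import SequenceRecord, random_dna, revcomp
from tas3scan.simulate import (FeatureKind, FeatureSpec, StarPolicy,
                               make_mir390_precursor, plant_features)

from conftest import make_perfect_hairpin
from oracles import naive_arm_scan


def synthetic_fold(n_pairs: int, length: int, mfe: float,
                   multibranch: bool = False) -> HairpinFold:
    """A hand-built fold record with the requested summary statistics."""
    if multibranch:
        outer, inner = 10, (n_pairs - 10) // 2
        db = ("(" * outer + "(" * inner + "...." + ")" * inner + ".."
              + "(" * inner + "...." + ")" * inner + ")" * outer)
        db += "." * (length - len(db))
    else:
        loop = length - 2 * n_pairs
        db = "(" * n_pairs + "." * loop + ")" * n_pairs
    assert len(db) == length
    return HairpinFold("fixture", length, parse_dot_bracket(db), db, mfe)


class TestStrictCriteria:
    def test_each_boundary_fixture_flips_exactly_one_flag(self):
        params = StrictCriteriaParams()
        fixtures = {
            "min_length": synthetic_fold(22, 59, -40.0),
            "min_stem_bp": synthetic_fold(21, 60, -40.0),
            "max_mfe": synthetic_fold(22, 60, -34.9),
            "no_multibranch": synthetic_fold(24, 60, -40.0,
                                             multibranch=True),
        }
        for failing, fold in fixtures.items():
            flags = evaluate_criteria(fold, params)
            assert not flags[failing]
            assert not flags["pass"]
            others = {k: v for k, v in flags.items()
                      if k not in (failing, "pass")}
            assert all(others.values()), (failing, flags)

    def test_inclusive_boundaries_pass(self):
        params = StrictCriteriaParams()
        ok = evaluate_criteria(synthetic_fold(22, 60, -35.0), params)
        assert ok["pass"]
        assert ok["min_length"] and ok["min_stem_bp"] and ok["max_mfe"]

    def test_real_folds_at_the_length_boundary(self):
        # 60-nt perfect hairpin passes; dropping one loop base fails only
        # the length criterion
        stem = "GCGCGGCGCATGCGCAGCGCGGCATCGC"  # 28 bp
        params = StrictCriteriaParams()
        seq60 = make_perfect_hairpin(stem, "ATAC")
        seq59 = make_perfect_hairpin(stem, "ATA")
        assert len(seq60) == 60 and len(seq59) == 59
        f60 = evaluate_criteria(fold_best_hairpin(seq60), params)
        f59 = evaluate_criteria(fold_best_hairpin(seq59), params)
        assert f60["pass"]
        assert not f59["min_length"] and not f59["pass"]
        assert f59["min_stem_bp"] and f59["max_mfe"] and f59["no_multibranch"]

    def test_real_folds_at_the_stem_boundary(self):
        params = StrictCriteriaParams()
        f22 = evaluate_criteria(
            fold_best_hairpin("G" * 22 + "A" * 16 + "C" * 22), params)
        f21 = evaluate_criteria(
            fold_best_hairpin("G" * 21 + "A" * 18 + "C" * 21), params)
        assert f22["pass"]
        assert not f21["min_stem_bp"] and not f21["pass"]
        assert f21["min_length"] and f21["max_mfe"]

    def test_threshold_validation(self):
        with pytest.raises(ConfigError):
            StrictCriteriaParams(max_mfe=1.0)
        with pytest.raises(ConfigError):
            StrictCriteriaParams(min_stem_bp=0)

    def test_filter_monotonicity(self, mir390):
        # relaxing any single threshold never shrinks the passing set
        rng = np.random.default_rng(5)
        folds = []
        for seed in range(12):
            rec, _ = make_mir390_precursor(mir390,
                                           stem_ext_bp=(0, 2, 5, 9)[seed % 4],
                                           loop_len=4 + seed % 5, seed=seed)
            seq = list(rec.seq)
            # degrade some copies so criteria outcomes vary
            for pos in rng.choice(len(seq), size=(seed % 6) * 4,
                                  replace=False):
                seq[pos] = "ACGT"[rng.integers(4)]
            folds.append(fold_best_hairpin("".join(seq)))
        strict = StrictCriteriaParams()
        relaxed = [StrictCriteriaParams(min_precursor_len=40),
                   StrictCriteriaParams(min_stem_bp=15),
                   StrictCriteriaParams(max_mfe=-20.0)]
        base_pass = {i for i, f in enumerate(folds)
                     if evaluate_criteria(f, strict)["pass"]}
        for params in relaxed:
            loose_pass = {i for i, f in enumerate(folds)
                          if evaluate_criteria(f, params)["pass"]}
            assert base_pass <= loose_pass


class TestFindDuplexCandidates:
    def test_planted_pair_recovered_exactly(self, cfg, mir390, sim_defaults):
        genome, truths = plant_features(
            8000, [FeatureSpec(FeatureKind.MIR390_HAIRPIN)], seed=2,
            defaults=sim_defaults)
        pairs = find_duplex_candidates(
            genome, cfg.guide_variants("miR390"),
            cfg.star_variants("miR390"), max_mm_per_arm=2)
        t = truths[0]
        plus = [p for p in pairs if p.strand == "+"]
        assert [(p.guide_start, p.guide_end, p.star_start, p.star_end)
                for p in plus] == [
            (t.elements["miR"]["start"], t.elements["miR"]["end"],
             t.elements["miR_star"]["start"], t.elements["miR_star"]["end"])]

    def test_featureless_genome_yields_nothing(self, cfg):
        rec = SequenceRecord("a", "A" * 2000)
        assert find_duplex_candidates(rec, cfg.guide_variants("miR390"),
                                      cfg.star_variants("miR390")) == []

    def test_empty_guide_set_is_a_config_error(self, cfg):
        with pytest.raises(ConfigError):
            find_duplex_candidates(SequenceRecord("a", "ACGT" * 100), [],
                                   cfg.star_variants("miR390"))

    def test_matches_naive_sliding_window_oracle(self, cfg, rng):
        guides = cfg.guide_variants("miR390")
        stars = cfg.star_variants("miR390")
        # random genome seeded with a few half-matches to make hits likely
        g = random_dna(rng, 10000)
        from tas3scan.seqs import as_dna
        frag = as_dna(guides[0])
        g = g[:2000] + frag + g[2021:6000] + revcomp(frag) + g[6021:]
        rec = SequenceRecord("r", g)
        got = {(p.strand, p.guide_start, p.guide_end, p.star_start, p.star_end)
               for p in find_duplex_candidates(rec, guides, stars, 3,
                                               (40, 400))}
        expect = set()
        n = len(rec)
        for strand in "+-":
            seq = rec.seq if strand == "+" else revcomp(rec.seq)
            gh = naive_arm_scan(seq, [str(v).upper().replace("U", "T")
                                      for v in guides], 3)
            sh = naive_arm_scan(seq, [str(v).upper().replace("U", "T")
                                      for v in stars], 3)
            for gs, (gmm, gv) in gh.items():
                for ss, (smm, sv) in sh.items():
                    ge, se = gs + len(gv), ss + len(sv)
                    if max(gs, ss) < min(ge, se):
                        continue
                    span = max(ge, se) - min(gs, ss)
                    if not 40 <= span <= 400:
                        continue
                    if strand == "+":
                        expect.add(("+", gs, ge, ss, se))
                    else:
                        expect.add(("-", n - ge, n - gs, n - se, n - ss))
        assert got == expect


class TestEvaluatePrecursor:
    def test_planted_precursor_passes_with_canonical_geometry(
            self, cfg, mir390, sim_defaults):
        genome, truths = plant_features(
            6000, [FeatureSpec(FeatureKind.MIR390_HAIRPIN)], seed=4,
            defaults=sim_defaults)
        cands = scan_precursors(genome, cfg.guide_variants("miR390"),
                                cfg.star_variants("miR390"))
        t = truths[0]
        mir = (t.elements["miR"]["start"], t.elements["miR"]["end"])
        exact = [c for c in cands if c.strand == "+"
                 and (c.start + c.mir_arm[0], c.start + c.mir_arm[1]) == mir]
        assert len(exact) == 1
        c = exact[0]
        assert c.passes
        assert (c.overhang_5p_arm, c.overhang_3p_arm) == (2, 2)
        assert c.is_canonical_duplex
        assert c.lower_stem_bp == 17

    def test_blunt_duplex_geometry(self, mir390):
        rec, truth = make_mir390_precursor(
            mir390, star_policy=StarPolicy.PERFECT, seed=6)
        from tas3scan.precursor import ArmPair
        pair = ArmPair(rec.id, "+",
                       truth.elements["miR"]["start"],
                       truth.elements["miR"]["end"],
                       truth.elements["miR_star"]["start"],
                       truth.elements["miR_star"]["end"], 0, 0)
        cand = evaluate_precursor(rec, pair, flank=0)
        assert (cand.overhang_5p_arm, cand.overhang_3p_arm) == (0, 0)
        assert not cand.is_canonical_duplex
        # a perfect-complement duplex pairs the full guide
        assert cand.fold.stem_bp >= len(mir390) - 2

    def test_window_truncation_is_recorded(self, cfg, mir390):
        rec, truth = make_mir390_precursor(mir390, stem_ext_bp=0, seed=8)
        from tas3scan.precursor import ArmPair
        pair = ArmPair(rec.id, "+",
                       truth.elements["miR"]["start"],
                       truth.elements["miR"]["end"],
                       truth.elements["miR_star"]["start"],
                       truth.elements["miR_star"]["end"], 0, 0)
        cand = evaluate_precursor(rec, pair, flank=30)
        assert cand.truncated
        assert cand.start == 0 and cand.end == len(rec)

    def test_overlapping_candidates_merge_to_best_mfe(self, cfg, mir390,
                                                      sim_defaults):
        genome, _ = plant_features(
            6000, [FeatureSpec(FeatureKind.MIR390_HAIRPIN)], seed=9,
            defaults=sim_defaults)
        pairs = find_duplex_candidates(genome, cfg.guide_variants("miR390"),
                                       cfg.star_variants("miR390"))
        cands = [evaluate_precursor(genome, p) for p in pairs]
        merged = merge_candidates(cands + cands)  # duplicates must collapse
        assert len(merged) == len(merge_candidates(cands))
        per_strand = {}
        for c in merged:
            per_strand.setdefault(c.strand, []).append(c)
        for group in per_strand.values():
            assert len(group) == 1

    def test_background_genome_has_no_passing_candidates(self, cfg, rng):
        rec = SequenceRecord("bg", random_dna(rng, 30000))
        cands = scan_precursors(rec, cfg.guide_variants("miR390"),
                                cfg.star_variants("miR390"))
        assert [c for c in cands if c.passes] == []
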
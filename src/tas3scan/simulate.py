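"""Synthetic genomes with planted MIR390 hairpins and TAS3/TAS6 loci.

Every generator is deterministic under its seed and emits a machine-readable
truth record alongside the sequence, so detector recovery can be scored
without external data. Planted features are built clean (the generators
verify their own postconditions by running the relevant detector on the
fresh feature and resampling the random filler on the rare failure), then
optionally diverged by an i.i.d. per-site substitution process that leaves
truth coordinates valid (no indels by default).

Background composition is i.i.d. with configurable GC. Minus-strand
features are inserted as reverse complements with mirrored truth
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .seqs import SequenceRecord, as_dna, random_dna, revcomp
from .taslocus import ArchitectureClass


class FeatureKind(str, Enum):
    MIR390_HAIRPIN = "MIR390_HAIRPIN"
    TAS3_LOCUS = "TAS3_LOCUS"
    TAS6_TAS3_COMPLEX = "TAS6_TAS3_COMPLEX"
    DECOY = "DECOY"


class StarPolicy(str, Enum):
    CANONICAL = "canonical"  # 2-nt 3' overhangs at both duplex ends
    PERFECT = "perfect"      # star = revcomp(guide): blunt, fully paired


class GeometryError(ValueError):
    pass


class PlacementError(RuntimeError):
    pass


@dataclass
class FeatureSpec:
    kind: FeatureKind
    architecture: ArchitectureClass | None = None
    strand: str = "+"
    divergence: float = 0.0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.divergence < 1:
            raise ValueError("divergence must lie in [0, 1)")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


@dataclass
class TruthAnnotation:
    feature_id: str
    sequence_id: str
    start: int  # 0-based half-open on the host + strand axis
    end: int
    strand: str
    kind: FeatureKind
    architecture: ArchitectureClass | None = None
    #: element name -> {start, end, strand, kind, phase_register}
    elements: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def shifted(self, offset: int, sequence_id: str) -> "TruthAnnotation":
        els = {k: {**v, "start": v["start"] + offset, "end": v["end"] + offset}
               for k, v in self.elements.items()}
        return TruthAnnotation(self.feature_id, sequence_id,
                               self.start + offset, self.end + offset,
                               self.strand, self.kind, self.architecture,
                               els, dict(self.params))

    def mirrored(self, length: int, sequence_id: str) -> "TruthAnnotation":
        """Coordinates after reverse-complementing a host of `length`."""
        flip = {"+": "-", "-": "+"}
        els = {k: {**v, "start": length - v["end"], "end": length - v["start"],
                   "strand": flip[v["strand"]]}
               for k, v in self.elements.items()}
        return TruthAnnotation(self.feature_id, sequence_id,
                               length - self.end, length - self.start,
                               flip[self.strand], self.kind,
                               self.architecture, els, dict(self.params))


def mutate(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """i.i.d. per-site substitution with probability `divergence`."""
    if divergence == 0:
        return seq
    bases = "ACGT"
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < divergence)[0]
    for i in hits:
        alts = bases.replace(out[i], "")
        out[i] = alts[rng.integers(len(alts))]
    return "".join(out)


# ---------------------------------------------------------------------------
# MIR390 precursor


def make_mir390_precursor(guide: str, star_policy: StarPolicy = StarPolicy.CANONICAL,
                          stem_ext_bp: int = 17, loop_len: int = 8,
                          seed: int = 1) -> tuple[SequenceRecord, TruthAnnotation]:
    """A stem-loop whose duplex holds `guide` and its star, with a lower
    stem of `stem_ext_bp` base pairs below the duplex.

    The canonical star policy leaves 2-nt 3' overhangs at both duplex ends
    (the duplex geometry a DCL enzyme excises); the perfect policy pairs the
    full guide (blunt duplex). Random filler (lower stem, loop, overhang) is
    resampled until folding the construct reproduces the intended geometry.
    """
    from .fold import fold_best_hairpin, lower_stem_extension
    from .precursor import PrecursorCandidate, duplex_geometry, evaluate_criteria

    g = as_dna(guide)
    if not 20 <= len(g) <= 22:
        raise GeometryError("guide length must be 20-22 nt")
    if loop_len < 3:
        raise GeometryError("loop_len must be >= 3")
    if stem_ext_bp < 0:
        raise GeometryError("stem_ext_bp must be >= 0")
    m = len(g)
    star_policy = StarPolicy(star_policy)
    if star_policy is StarPolicy.CANONICAL and stem_ext_bp == 1:
        # below the 2-nt overhang bulge a lone closing pair has nothing to
        # stack on, so a 1-bp lower stem cannot appear in an MFE structure
        raise GeometryError(
            "a 1-bp lower stem is not realizable under the canonical "
            "overhang geometry; use 0 or >= 2")

    for attempt in range(100):
        rng = np.random.default_rng([seed & 0x7FFFFFFF, 7, attempt])
        # G/C lower stem: keeps even short extensions thermodynamically
        # committed below the overhang bulge
        e5 = "".join("GC"[int(b)] for b in rng.integers(2, size=stem_ext_bp))
        loop = random_dna(rng, loop_len)
        if star_policy is StarPolicy.PERFECT:
            star = revcomp(g)
        else:
            star = revcomp(g[:-2]) + random_dna(rng, 2)
        seq = e5 + g + loop + star + revcomp(e5)
        mir_arm = (stem_ext_bp, stem_ext_bp + m)
        star_arm = (stem_ext_bp + m + loop_len,
                    stem_ext_bp + m + loop_len + len(star))

        fold = fold_best_hairpin(seq)
        if lower_stem_extension(fold, (mir_arm, star_arm)) != stem_ext_bp:
            continue
        duplex = [(i, j) for i, j in fold.pairing
                  if mir_arm[0] <= i < mir_arm[1]
                  and star_arm[0] <= j < star_arm[1]]
        want_pairs = m if star_policy is StarPolicy.PERFECT else m - 2
        if len(duplex) != want_pairs:
            continue
        cand = PrecursorCandidate(
            sequence_id="precursor", start=0, end=len(seq), strand="+",
            mir_arm=mir_arm, star_arm=star_arm, fold=fold,
            criteria={}, passes=True)
        geom = duplex_geometry(cand)
        want = (2, 2) if star_policy is StarPolicy.CANONICAL else (0, 0)
        if (geom["overhang_5p_arm"], geom["overhang_3p_arm"]) != want:
            continue

        rec = SequenceRecord(f"mir390_precursor_s{seed}", seq,
                             f"synthetic MIR390 precursor seed={seed}")
        truth = TruthAnnotation(
            feature_id=rec.id, sequence_id=rec.id, start=0, end=len(seq),
            strand="+", kind=FeatureKind.MIR390_HAIRPIN,
            elements={
                "miR": {"start": mir_arm[0], "end": mir_arm[1],
                        "strand": "+", "kind": "miRNA"},
                "miR_star": {"start": star_arm[0], "end": star_arm[1],
                             "strand": "+", "kind": "miRNA_star"},
            },
            params={"stem_ext_bp": stem_ext_bp, "loop_len": loop_len,
                    "star_policy": star_policy.value, "seed": seed},
        )
        return rec, truth
    raise PlacementError("could not realize the requested hairpin geometry")


# ---------------------------------------------------------------------------
# TAS3 / TAS6 loci

#: per-architecture plan: (element kind, phase slot k) — the element start
#: sits 21*k nt 5' of the 3'-site cleavage coordinate
_ARCH_PLANS = {
    ArchitectureClass.ONE_TASIAP2_ONLY: [("AP2", 3)],
    ArchitectureClass.ONE_TASIAP2_ONE_TASIARF: [("ARF", 4), ("AP2", 2)],
    ArchitectureClass.TAS6_TAS3: [("ARF", 4), ("AP2", 2)],
    ArchitectureClass.ONE_TASIARF_ONLY: [("ARF", 3)],
    ArchitectureClass.TWO_TASIARF_TANDEM: [("ARF", 3), ("ARF", 2)],
    ArchitectureClass.TWO_TASIARF_SPACER: [("ARF", 5), ("ARF", 2)],
}


def _ref_by_kind(tasi_refs: list, kind: str) -> tuple:
    for name, k, seq in tasi_refs:
        if k == kind:
            return name, k, as_dna(seq)
    raise GeometryError(f"no {kind} reference element supplied")


def make_tas3_locus(architecture: ArchitectureClass, guide: str,
                    tasi_refs: list, spacing: int = 214,
                    strand_of_tasi: str = "-", seed: int = 1,
                    phase_offset: int = 0,
                    ) -> tuple[SequenceRecord, TruthAnnotation]:
    """A TAS3-like locus: two perfect guide target sites bounding tasi
    elements planted in phase with the 3'-site cleavage register.

    `spacing` is the inter-site length; the locus length is
    ``spacing + 2 * len(site)``. tasiARF elements go on `strand_of_tasi`
    (moss tasiARFs derive from the minus strand), tasiAP2 on plus.
    `phase_offset` shifts every element off the processing grid by that
    many nt (0 = in phase). Elements must fit: architectures whose plan
    exceeds `spacing` raise a geometry error.
    """
    from .targets import find_target_sites

    architecture = ArchitectureClass(architecture)
    g = as_dna(guide)
    site = revcomp(g)
    slen = len(site)
    plan = _ARCH_PLANS.get(architecture)
    if plan is None:
        raise GeometryError(f"no generative plan for {architecture}")

    # locus-relative cleavage boundary of the 3' site (between the bases
    # opposite guide positions 10 and 11)
    b3 = slen + spacing + (slen - 10)
    placements = []
    for kind, k in plan:
        name, _, ref = _ref_by_kind(tasi_refs, kind)
        p = b3 - 21 * k - phase_offset
        if p < slen or p + len(ref) > slen + spacing:
            raise GeometryError(
                f"architecture {architecture.value} does not fit in "
                f"spacing {spacing}")
        placements.append((p, kind, name, ref))
    placements.sort()
    for (p1, _, _, r1), (p2, _, _, _r2) in zip(placements, placements[1:]):
        if p1 + len(r1) > p2:
            raise GeometryError("planted elements overlap")

    for attempt in range(100):
        rng = np.random.default_rng([seed & 0x7FFFFFFF, 11, attempt])
        internal = list(random_dna(rng, spacing))
        elements = {}
        for idx, (p, kind, name, ref) in enumerate(placements):
            planted = ref if (kind == "AP2" or strand_of_tasi == "+") \
                else revcomp(ref)
            internal[p - slen:p - slen + len(ref)] = planted
            strand = "+" if (kind == "AP2" or strand_of_tasi == "+") else "-"
            elements[f"tasi{kind}_{idx}"] = {
                "start": p, "end": p + len(ref), "strand": strand,
                "kind": f"tasi{kind}",
                "phase_register": phase_offset % 21,
            }
        seq = site + "".join(internal) + site
        elements["site5"] = {"start": 0, "end": slen, "strand": "+",
                             "kind": "miR390_target_site"}
        elements["site3"] = {"start": slen + spacing,
                             "end": 2 * slen + spacing, "strand": "+",
                             "kind": "miR390_target_site"}

        rec = SequenceRecord(f"tas3_{architecture.value.lower()}_s{seed}", seq)
        # postconditions: the two planted sites are the only hits, and the
        # random filler spawned no spurious near-identity tasi match
        hits = find_target_sites(rec, g, max_penalty=4.0)
        plus_hits = [(h.start, h.end) for h in hits if h.strand == "+"]
        if plus_hits != [(0, slen), (slen + spacing, 2 * slen + spacing)]:
            continue
        from .taslocus import detect_tasi_elements
        detected = detect_tasi_elements(seq[slen:slen + spacing], tasi_refs,
                                        min_identity=0.75,
                                        region_offset=slen)
        want_elements = sorted(
            (v["start"], v["end"], v["kind"].removeprefix("tasi"),
             v["strand"])
            for v in elements.values() if v["kind"].startswith("tasi"))
        got_elements = sorted((h.start, h.end, h.kind, h.strand_of_match)
                              for h in detected)
        if got_elements != want_elements:
            continue
        truth = TruthAnnotation(
            feature_id=rec.id, sequence_id=rec.id, start=0, end=len(seq),
            strand="+", kind=FeatureKind.TAS3_LOCUS,
            architecture=architecture, elements=elements,
            params={"spacing": spacing, "seed": seed,
                    "phase_offset": phase_offset,
                    "strand_of_tasi": strand_of_tasi},
        )
        return rec, truth
    raise PlacementError("could not realize a clean TAS3 locus")


def make_tas6_locus(guide156: str, guide529: str, inner_len: int = 120,
                    seed: int = 1) -> tuple[SequenceRecord, TruthAnnotation]:
    """A TAS6-like locus: a 5' miR529 target site and a 3' miR156 target
    site bounding unconstrained filler."""
    s529 = revcomp(as_dna(guide529))
    s156 = revcomp(as_dna(guide156))
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 13])
    seq = s529 + random_dna(rng, inner_len) + s156
    rec = SequenceRecord(f"tas6_s{seed}", seq)
    truth = TruthAnnotation(
        feature_id=rec.id, sequence_id=rec.id, start=0, end=len(seq),
        strand="+", kind=FeatureKind.TAS3_LOCUS,
        elements={
            "site5_miR529": {"start": 0, "end": len(s529), "strand": "+",
                             "kind": "miR529_target_site"},
            "site3_miR156": {"start": len(seq) - len(s156), "end": len(seq),
                             "strand": "+", "kind": "miR156_target_site"},
        },
        params={"inner_len": inner_len, "seed": seed})
    return rec, truth


def make_tas6_tas3_complex(guide390: str, guide156: str, guide529: str,
                           tasi_refs: list, gap: int = 100,
                           tas3_spacing: int = 214, tas6_inner: int = 120,
                           seed: int = 1,
                           ) -> tuple[SequenceRecord, TruthAnnotation, TruthAnnotation]:
    """TAS6 upstream of TAS3 on one strand, `gap` nt apart.

    Returns the combined record plus separate TAS6 and TAS3 truths (the
    TAS3 architecture is TAS6_TAS3, the upgraded class)."""
    t6_rec, t6_truth = make_tas6_locus(guide156, guide529, tas6_inner, seed)
    t3_rec, t3_truth = make_tas3_locus(ArchitectureClass.TAS6_TAS3, guide390,
                                       tasi_refs, tas3_spacing, seed=seed)
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 17])
    seq = t6_rec.seq + random_dna(rng, gap) + t3_rec.seq
    rec = SequenceRecord(f"tas6_tas3_s{seed}", seq)
    t6 = t6_truth.shifted(0, rec.id)
    t3 = t3_truth.shifted(len(t6_rec.seq) + gap, rec.id)
    t3.params["gap"] = gap
    t3.params["complex_total_length"] = len(seq)
    return rec, t6, t3


# ---------------------------------------------------------------------------
# genome assembly


def _build_feature(spec: FeatureSpec, defaults: dict, seed: int,
                   index: int) -> tuple[str, list]:
    """Feature sequence (+ orientation) and its truths (feature-relative)."""
    sub_seed = (seed * 1000003 + index * 101) & 0x7FFFFFFF
    p = {**defaults, **spec.params}
    if spec.kind is FeatureKind.MIR390_HAIRPIN:
        rec, truth = make_mir390_precursor(
            p["guide390"], p.get("star_policy", StarPolicy.CANONICAL),
            p.get("stem_ext_bp", 17), p.get("loop_len", 8), sub_seed)
        return rec.seq, [truth]
    if spec.kind is FeatureKind.TAS3_LOCUS:
        rec, truth = make_tas3_locus(
            spec.architecture or ArchitectureClass.ONE_TASIARF_ONLY,
            p["guide390"], p["tasi_refs"], p.get("spacing", 214),
            p.get("strand_of_tasi", "-"), sub_seed,
            p.get("phase_offset", 0))
        return rec.seq, [truth]
    if spec.kind is FeatureKind.TAS6_TAS3_COMPLEX:
        rec, t6, t3 = make_tas6_tas3_complex(
            p["guide390"], p["guide156"], p["guide529"], p["tasi_refs"],
            p.get("gap", 100), p.get("spacing", 214),
            p.get("tas6_inner", 120), sub_seed)
        return rec.seq, [t6, t3]
    if spec.kind is FeatureKind.DECOY:
        # a lone guide target site: dual-site pairing must reject it
        site = revcomp(as_dna(p["guide390"]))
        truth = TruthAnnotation(
            feature_id=f"decoy_{index}", sequence_id="", start=0,
            end=len(site), strand="+", kind=FeatureKind.DECOY)
        return site, [truth]
    raise ValueError(f"unknown feature kind {spec.kind}")


def plant_features(genome_len: int, specs: list[FeatureSpec],
                   background_gc: float = 0.5, seed: int = 1,
                   margin: int = 60, sequence_id: str | None = None,
                   defaults: dict | None = None,
                   ) -> tuple[SequenceRecord, list[TruthAnnotation]]:
    """An i.i.d. background genome with the requested features inserted at
    non-overlapping positions (plus `margin` nt of clearance).

    Placement retries up to 100 positions per feature before giving up.
    Divergence is applied to the feature copy before insertion, so truth
    coordinates stay exact.
    """
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 23])
    genome = list(random_dna(rng, genome_len, background_gc))
    sequence_id = sequence_id or f"synthetic_genome_s{seed}"
    occupied: list[tuple[int, int]] = []
    truths: list[TruthAnnotation] = []

    for index, spec in enumerate(specs):
        fseq, ftruths = _build_feature(spec, defaults or {}, seed, index)
        fseq = mutate(fseq, spec.divergence, rng)
        flen = len(fseq)
        if flen > genome_len:
            raise PlacementError(f"feature {index} longer than the genome")
        placed = False
        for _ in range(100):
            start = int(rng.integers(0, genome_len - flen + 1))
            if all(start - margin >= e or start + flen + margin <= s
                   for s, e in occupied):
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place feature {index} without overlap")
        if spec.strand == "-":
            genome[start:start + flen] = revcomp(fseq)
            new = [t.mirrored(flen, sequence_id).shifted(start, sequence_id)
                   for t in ftruths]
        else:
            genome[start:start + flen] = fseq
            new = [t.shifted(start, sequence_id) for t in ftruths]
        for t in new:
            t.feature_id = f"feat{index}_{t.kind.value.lower()}"
            t.params["divergence"] = spec.divergence
        truths.extend(new)
        occupied.append((start, start + flen))

    rec = SequenceRecord(sequence_id, "".join(genome),
                         f"synthetic genome seed={seed} gc={background_gc}")
    truths.sort(key=lambda t: t.start)
    return rec, truths
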
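"""miR390 precursor candidate discovery: imperfect inverted-repeat search
seeded from a guide/star variant set, hairpin folding, and the four strict
structural criteria.

The strict criteria applied to every folded candidate window are:

1. window length >= ``min_precursor_len`` (default 60 nt);
2. total base pairs in the stem, G:U wobble included, >= ``min_stem_bp``
   (default 22);
3. MFE <= ``max_mfe`` (default -35.0 kcal/mol, inclusive);
4. no multibranch loop in the structure.

Comparisons are inclusive, matching the "minimum / at least / maximum"
wording of each threshold; the MFE comparison is made on the 2-decimal
reported value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energy import EnergyModel
from .fold import HairpinFold, fold_best_hairpin, lower_stem_extension
from .seqs import SequenceRecord, as_dna, encode, hamming_profile, revcomp


class ConfigError(ValueError):
    pass


@dataclass
class StrictCriteriaParams:
    min_precursor_len: int = 60
    min_stem_bp: int = 22
    max_mfe: float = -35.0
    forbid_multibranch: bool = True

    def __post_init__(self) -> None:
        if self.min_precursor_len <= 0 or self.min_stem_bp <= 0:
            raise ConfigError("length/stem thresholds must be positive")
        if self.max_mfe >= 0:
            raise ConfigError("max_mfe must be negative")


@dataclass
class ArmPair:
    """A guide-arm / star-arm match pair on one strand (genome coordinates,
    0-based half-open, always on the + strand axis)."""

    sequence_id: str
    strand: str
    guide_start: int
    guide_end: int
    star_start: int
    star_end: int
    guide_mm: int
    star_mm: int
    guide_variant: str = ""
    star_variant: str = ""

    @property
    def span(self) -> int:
        return max(self.guide_end, self.star_end) - min(self.guide_start,
                                                        self.star_start)


@dataclass
class PrecursorCandidate:
    sequence_id: str
    start: int  # window, 0-based half-open on + strand axis
    end: int
    strand: str
    mir_arm: tuple  # window-relative 0-based half-open
    star_arm: tuple
    fold: HairpinFold
    criteria: dict
    passes: bool
    overhang_5p_arm: int | None = None
    overhang_3p_arm: int | None = None
    is_canonical_duplex: bool = False
    lower_stem_bp: int = 0
    truncated: bool = False

    @property
    def window_len(self) -> int:
        return self.end - self.start


def evaluate_criteria(fold: HairpinFold, params: StrictCriteriaParams) -> dict:
    """Per-criterion booleans + overall pass for an already-folded window."""
    flags = {
        "min_length": fold.length >= params.min_precursor_len,
        "min_stem_bp": fold.stem_bp >= params.min_stem_bp,
        "max_mfe": round(fold.mfe, 2) <= params.max_mfe,
        "no_multibranch": (not fold.has_multibranch
                           if params.forbid_multibranch else True),
    }
    flags["pass"] = all(flags.values())
    return flags


def _variant_hits(template_enc: np.ndarray, variants, max_mm: int):
    """(start, mm, variant) for every window within max_mm of any variant.

    When several variants hit the same start, the lowest-mismatch one wins.
    """
    best: dict[int, tuple[int, str]] = {}
    for var in variants:
        v = as_dna(var)
        prof = hamming_profile(template_enc, encode(v))
        for s in np.nonzero(prof <= max_mm)[0]:
            mm = int(prof[s])
            if s not in best or mm < best[s][0]:
                best[int(s)] = (mm, v)
    return [(s, mm, var) for s, (mm, var) in sorted(best.items())]


def find_duplex_candidates(record: SequenceRecord, guides, stars,
                           max_mm_per_arm: int = 3,
                           span_range: tuple = (40, 400)) -> list[ArmPair]:
    """Imperfect inverted repeats: a guide match and a star match on the same
    strand within `span_range` (inclusive span over both arms), each within
    `max_mm_per_arm` mismatches of *some* configured variant. Both strands
    are scanned; minus-strand coordinates are reported on the + strand axis.
    """
    if not guides:
        raise ConfigError("guide variant set must not be empty")
    if not stars:
        raise ConfigError("star variant set must not be empty")
    lo, hi = span_range
    if not (0 < lo <= hi <= 1000):
        raise ConfigError("span_range must lie within (0, 1000]")

    out: list[ArmPair] = []
    n = len(record)
    for strand in "+-":
        seq = record.seq if strand == "+" else revcomp(record.seq)
        enc = encode(seq)
        ghits = _variant_hits(enc, guides, max_mm_per_arm)
        shits = _variant_hits(enc, stars, max_mm_per_arm)
        for gs, gmm, gvar in ghits:
            ge = gs + len(gvar)
            for ss, smm, svar in shits:
                se = ss + len(svar)
                if max(gs, ss) < min(ge, se):
                    continue  # arms must be disjoint
                span = max(ge, se) - min(gs, ss)
                if not lo <= span <= hi:
                    continue
                if strand == "+":
                    pair = ArmPair(record.id, "+", gs, ge, ss, se,
                                   gmm, smm, gvar, svar)
                else:
                    pair = ArmPair(record.id, "-", n - ge, n - gs,
                                   n - se, n - ss, gmm, smm, gvar, svar)
                out.append(pair)
    out.sort(key=lambda p: (min(p.guide_start, p.star_start), p.span,
                            p.strand))
    return out


def evaluate_precursor(record: SequenceRecord, arm_pair: ArmPair,
                       params: StrictCriteriaParams | None = None,
                       model: EnergyModel | None = None,
                       flank: int = 20) -> PrecursorCandidate:
    """Fold the window spanning both arms (+- `flank`) and fill the criteria
    report, duplex 3' overhangs and lower-stem extension."""
    params = params or StrictCriteriaParams()
    if flank < 0:
        raise ValueError("flank must be non-negative")
    n = len(record)
    lo = min(arm_pair.guide_start, arm_pair.star_start) - flank
    hi = max(arm_pair.guide_end, arm_pair.star_end) + flank
    truncated = lo < 0 or hi > n
    lo, hi = max(lo, 0), min(hi, n)

    window = record.seq[lo:hi]
    if arm_pair.strand == "-":
        window = revcomp(window)
        # window-relative coords on the minus strand reading
        g = (hi - arm_pair.guide_end, hi - arm_pair.guide_start)
        s = (hi - arm_pair.star_end, hi - arm_pair.star_start)
    else:
        g = (arm_pair.guide_start - lo, arm_pair.guide_end - lo)
        s = (arm_pair.star_start - lo, arm_pair.star_end - lo)

    fold = fold_best_hairpin(window, model,
                             sequence_id=f"{record.id}:{lo}-{hi}")
    criteria = evaluate_criteria(fold, params)
    cand = PrecursorCandidate(
        sequence_id=record.id, start=lo, end=hi, strand=arm_pair.strand,
        mir_arm=g, star_arm=s, fold=fold, criteria=criteria,
        passes=criteria["pass"], truncated=truncated,
        lower_stem_bp=lower_stem_extension(fold, (g, s)),
    )
    geom = duplex_geometry(cand)
    cand.overhang_5p_arm = geom["overhang_5p_arm"]
    cand.overhang_3p_arm = geom["overhang_3p_arm"]
    cand.is_canonical_duplex = geom["is_canonical"]
    return cand


def duplex_geometry(candidate: PrecursorCandidate) -> dict:
    """3'-overhang lengths at both ends of the miR/miR* duplex.

    The duplex is read off the fold's pairing: pairs with one index in each
    arm. The loop-side overhang is the 3' tail of the 5' arm beyond its last
    duplex pair minus the 5' tail of the 3' arm; the base-side overhang is
    symmetric. A fully unpaired arm yields a geometry-undefined flag (None
    overhangs) rather than an exception.
    """
    (a_s, a_e), (b_s, b_e) = sorted([candidate.mir_arm, candidate.star_arm])
    duplex = [(i, j) for i, j in candidate.fold.pairing
              if a_s <= i < a_e and b_s <= j < b_e]
    if not duplex:
        return {"overhang_5p_arm": None, "overhang_3p_arm": None,
                "is_canonical": False, "defined": False}
    i_top = max(i for i, _ in duplex)
    j_top = min(j for i, j in duplex if i == i_top)
    i_bot = min(i for i, _ in duplex)
    j_bot = max(j for i, j in duplex if i == i_bot)
    loop_side = (a_e - 1 - i_top) - (j_top - b_s)
    base_side = (b_e - 1 - j_bot) - (i_bot - a_s)
    return {
        "overhang_5p_arm": loop_side,
        "overhang_3p_arm": base_side,
        "is_canonical": loop_side == 2 and base_side == 2,
        "defined": True,
    }


def merge_candidates(cands: list[PrecursorCandidate],
                     min_overlap: float = 0.5) -> list[PrecursorCandidate]:
    """Collapse candidates whose windows overlap >= `min_overlap` of the
    shorter window; the lowest-MFE candidate represents each group."""
    ordered = sorted(cands, key=lambda c: (c.sequence_id, c.start, c.end))
    kept: list[PrecursorCandidate] = []
    for c in ordered:
        merged = False
        for idx, k in enumerate(kept):
            if k.sequence_id != c.sequence_id or k.strand != c.strand:
                continue
            ov = min(k.end, c.end) - max(k.start, c.start)
            if ov <= 0:
                continue
            if ov / min(k.window_len, c.window_len) >= min_overlap:
                if c.fold.mfe < k.fold.mfe:
                    kept[idx] = c
                merged = True
                break
        if not merged:
            kept.append(c)
    return kept


def scan_precursors(record: SequenceRecord, guides, stars,
                    params: StrictCriteriaParams | None = None,
                    model: EnergyModel | None = None,
                    max_mm_per_arm: int = 3, span_range: tuple = (40, 400),
                    flank: int = 20) -> list[PrecursorCandidate]:
    """End-to-end precursor stage: arm pairs -> folded, criteria-checked,
    merged candidate list (passing and failing candidates both returned)."""
    pairs = find_duplex_candidates(record, guides, stars, max_mm_per_arm,
                                   span_range)
    cands = [evaluate_precursor(record, p, params, model, flank)
             for p in pairs]
    return merge_candidates(cands)
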
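"""TAS3/TAS6 locus assembly: dual-target-site pairing, tasiARF/tasiAP2
element detection with 21-nt phasing, architecture classification and
TAS6-TAS3 genomic cluster detection.

A TAS3-like locus is a same-strand pair of miR390 target sites whose
inclusive span (both sites counted — the reporting convention used
throughout) falls in a configured range, with the trans-acting siRNA source
elements between them. Elements are matched against reference tasiARF /
tasiAP2 sequences on both strands (moss tasiARFs come off the minus strand
of the locus), allowing at most one indel. The phasing register of a
position is its signed distance from the 3'-site cleavage coordinate,
reduced modulo the 21-nt DCL4 processing cycle, measured toward the 5' site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .seqs import SequenceRecord, as_dna, revcomp
from .targets import TargetSiteHit


class ArchitectureClass(str, Enum):
    ONE_TASIAP2_ONLY = "ONE_TASIAP2_ONLY"
    ONE_TASIAP2_ONE_TASIARF = "ONE_TASIAP2_ONE_TASIARF"
    TAS6_TAS3 = "TAS6_TAS3"
    ONE_TASIARF_ONLY = "ONE_TASIARF_ONLY"
    TWO_TASIARF_TANDEM = "TWO_TASIARF_TANDEM"
    TWO_TASIARF_SPACER = "TWO_TASIARF_SPACER"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass
class PhaseParams:
    cycle: int = 21

    def __post_init__(self) -> None:
        if self.cycle <= 0:
            raise ValueError("phasing cycle must be positive")


@dataclass
class TasiHit:
    kind: str  # 'ARF' or 'AP2'
    ref_name: str
    start: int  # 0-based half-open, + strand axis of the host sequence
    end: int
    strand_of_match: str
    identity: float
    phase_register: int | None = None
    functional: bool | None = None
    seq: str = ""


@dataclass
class Tas3Locus:
    sequence_id: str
    strand: str
    site5: TargetSiteHit
    site3: TargetSiteHit
    tasi_hits: list = field(default_factory=list)
    architecture: ArchitectureClass = ArchitectureClass.UNCLASSIFIED

    @property
    def start(self) -> int:
        return min(self.site5.start, self.site3.start)

    @property
    def end(self) -> int:
        return max(self.site5.end, self.site3.end)

    @property
    def length(self) -> int:
        """Inclusive span counting both border target sites."""
        return self.end - self.start

    @property
    def penalty(self) -> float:
        return self.site5.penalty + self.site3.penalty

    def intersite_interval(self) -> tuple:
        """The + axis interval strictly between the two sites."""
        return (min(self.site5.end, self.site3.end),
                max(self.site5.start, self.site3.start))


@dataclass
class Tas6Tas3Complex:
    tas6: Tas3Locus
    tas3: Tas3Locus
    gap: int

    @property
    def total_length(self) -> int:
        """Span from the TAS6 5' site start through the TAS3 3' site end."""
        return (max(self.tas3.end, self.tas6.end)
                - min(self.tas3.start, self.tas6.start))


def pair_dual_sites(hits: list[TargetSiteHit],
                    span_range: tuple = (150, 400)) -> list[Tas3Locus]:
    """Candidate loci: all same-strand hit pairs whose inclusive span lies
    in `span_range`. The transcript-5' site is the left hit on + and the
    right hit on -. Candidates are ordered by span, then start."""
    lo, hi = span_range
    out: list[Tas3Locus] = []
    ordered = sorted(hits, key=lambda h: (h.start, h.strand))
    for a_i, a in enumerate(ordered):
        for b in ordered[a_i + 1:]:
            if a.strand != b.strand or a.sequence_id != b.sequence_id:
                continue
            if a.end > b.start:
                continue  # sites must not overlap
            span = b.end - a.start
            if not lo <= span <= hi:
                continue
            if a.strand == "+":
                out.append(Tas3Locus(a.sequence_id, "+", site5=a, site3=b))
            else:
                out.append(Tas3Locus(a.sequence_id, "-", site5=b, site3=a))
    out.sort(key=lambda c: (c.length, c.start))
    return out


# ---------------------------------------------------------------------------
# tasi element detection


def _match_stats(window: str, ref: str) -> tuple[int, int]:
    """(matches, alignment_columns) for `window` vs `ref` allowing at most
    one indel (equal lengths: ungapped; off-by-one: best single gap)."""
    n, m = len(window), len(ref)
    if n == m:
        return sum(a == b for a, b in zip(window, ref)), m
    if abs(n - m) != 1:
        raise ValueError("windows may differ from the reference by <= 1 nt")
    long_s, short_s = (window, ref) if n > m else (ref, window)
    ll = len(long_s)
    # prefix[i]: matches of first i chars; suffix[i]: matches of last i chars
    best = 0
    for gap_at in range(ll):  # position of the unaligned long-string char
        m_pref = sum(a == b for a, b in zip(long_s[:gap_at], short_s[:gap_at]))
        m_suf = sum(a == b for a, b in zip(long_s[gap_at + 1:],
                                           short_s[gap_at:]))
        best = max(best, m_pref + m_suf)
    return best, ll


def detect_tasi_elements(region_seq: str, refs: list,
                         min_identity: float = 0.75,
                         region_offset: int = 0) -> list[TasiHit]:
    """Matches of reference tasi elements on both strands of an inter-site
    region. `refs` is a list of (name, kind, sequence) with kind ARF or AP2.
    Identity = matches / alignment columns, gapped (<=1 indel) and ungapped
    matches both considered. Overlapping same-kind hits keep the best
    identity (ties: leftmost). Coordinates are region-relative shifted by
    `region_offset` (host + strand axis).
    """
    if not refs:
        raise ValueError("reference tasi element set must not be empty")
    region = as_dna(region_seq)
    raw: list[TasiHit] = []
    for name, kind, ref in refs:
        ref = as_dna(ref)
        m = len(ref)
        for strand in "+-":
            r = ref if strand == "+" else revcomp(ref)
            for wlen in (m - 1, m, m + 1):
                if wlen <= 0:
                    continue
                for s in range(len(region) - wlen + 1):
                    matches, cols = _match_stats(region[s:s + wlen], r)
                    ident = matches / cols
                    if ident >= min_identity:
                        raw.append(TasiHit(kind, name,
                                           region_offset + s,
                                           region_offset + s + wlen,
                                           strand, round(ident, 4),
                                           seq=region[s:s + wlen]))
    # overlap resolution per kind: best identity, then leftmost, then exact
    # length preferred over gapped variants of the same match
    raw.sort(key=lambda h: (-h.identity, h.start, h.end - h.start))
    kept: list[TasiHit] = []
    for h in raw:
        if any(k.kind == h.kind
               and max(k.start, h.start) < min(k.end, h.end) for k in kept):
            continue
        kept.append(h)
    kept.sort(key=lambda h: h.start)
    return kept


# ---------------------------------------------------------------------------
# phasing


def phase_register(locus: Tas3Locus, position: int,
                   params: PhaseParams | None = None) -> int:
    """Register in [0, cycle) of a template position (0-based boundary)
    measured from the 3'-site cleavage coordinate toward the 5' site."""
    params = params or PhaseParams()
    lo, hi = locus.intersite_interval()
    origin = locus.site3.cleavage_coord
    if origin is None:
        raise ValueError("3' site cleavage coordinate undefined")
    # positions run from the inter-site region up to the cleavage coordinate
    # itself (which sits inside the 3' site)
    allowed = (lo, origin) if locus.strand == "+" else (origin, hi)
    if not allowed[0] <= position <= allowed[1]:
        raise ValueError(f"position {position} outside the phased region")
    if locus.strand == "+":
        return (origin - position) % params.cycle
    return (position - origin) % params.cycle


def element_phase_position(locus: Tas3Locus, hit: TasiHit) -> int:
    """The boundary of `hit` nearest the locus 5' end — the coordinate whose
    register places the element on the 21-nt processing grid."""
    return hit.start if locus.strand == "+" else hit.end


# ---------------------------------------------------------------------------
# classification


def classify_architecture(locus: Tas3Locus,
                          adjacency_gap: int = 10) -> ArchitectureClass:
    """Table-style internal organization from the element content.

    Two tasiARF copies closer than `adjacency_gap` count as a tandem;
    otherwise they are spacer-separated. TAS6 proximity upgrades are applied
    separately (see :func:`detect_tas6_tas3_complex`)."""
    arf = sorted((h for h in locus.tasi_hits if h.kind == "ARF"),
                 key=lambda h: h.start)
    ap2 = [h for h in locus.tasi_hits if h.kind == "AP2"]
    if ap2 and not arf:
        return ArchitectureClass.ONE_TASIAP2_ONLY
    if ap2 and arf:
        return ArchitectureClass.ONE_TASIAP2_ONE_TASIARF
    if len(arf) == 1:
        return ArchitectureClass.ONE_TASIARF_ONLY
    if len(arf) == 2:
        gap = arf[1].start - arf[0].end
        if gap < adjacency_gap:
            return ArchitectureClass.TWO_TASIARF_TANDEM
        return ArchitectureClass.TWO_TASIARF_SPACER
    return ArchitectureClass.UNCLASSIFIED


def detect_tas6_tas3_complex(tas6_loci: list[Tas3Locus],
                             tas3_loci: list[Tas3Locus],
                             max_gap: int = 1500) -> list[Tas6Tas3Complex]:
    """Same-strand TAS6 loci transcriptionally upstream of a TAS3 locus
    within `max_gap` nt. Upstream means lower + axis coordinates on the
    + strand and higher on the - strand. Each TAS6 joins only its nearest
    downstream TAS3 (the pair transcribed as one precursor)."""
    out = []
    for t6 in tas6_loci:
        best = None
        for t3 in tas3_loci:
            if (t6.sequence_id != t3.sequence_id
                    or t6.strand != t3.strand):
                continue
            if t6.strand == "+":
                gap = t3.start - t6.end
            else:
                gap = t6.start - t3.end
            if 0 <= gap <= max_gap and (best is None or gap < best.gap):
                best = Tas6Tas3Complex(t6, t3, gap)
        if best is not None:
            out.append(best)
    out.sort(key=lambda c: (c.tas3.start, c.gap))
    return out


# ---------------------------------------------------------------------------
# tasiAP2 functionality


def ap2_functionality(element_seq: str, ap2_target_ref: str,
                      max_breaking_subs: int = 3) -> dict:
    """Can the element still base-pair its AP2 target mRNA segment?

    The small RNA (element, 5'->3') pairs antiparallel to the target
    reference (5'->3'). A position "breaks" pairing when it can form
    neither a Watson-Crick nor a G:U wobble pair. The element is called
    functional when the number of breaking positions is at most
    `max_breaking_subs`. Sequences must be the same length.
    """
    if not ap2_target_ref:
        raise ValueError("ap2_target_ref must be provided")
    e = as_dna(element_seq)
    t = as_dna(ap2_target_ref)[::-1]  # antiparallel
    if len(e) != len(t):
        raise ValueError("element and target reference lengths differ")
    wc = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
    wobble = {("G", "T"), ("T", "G")}
    breaking = sum(1 for a, b in zip(e, t)
                   if (a, b) not in wc and (a, b) not in wobble)
    return {"functional": breaking <= max_breaking_subs,
            "breaking_subs": breaking}


# ---------------------------------------------------------------------------
# locus assembly


def resolve_locus_overlaps(cands: list[Tas3Locus]) -> list[Tas3Locus]:
    """Overlapping candidates resolved by lowest combined site penalty,
    then shortest span, then leftmost."""
    ordered = sorted(cands, key=lambda c: (c.penalty, c.length, c.start))
    kept: list[Tas3Locus] = []
    for c in ordered:
        if any(k.sequence_id == c.sequence_id and k.strand == c.strand
               and max(k.start, c.start) < min(k.end, c.end) for k in kept):
            continue
        kept.append(c)
    kept.sort(key=lambda c: (c.sequence_id, c.start))
    return kept


def annotate_locus(record: SequenceRecord, locus: Tas3Locus, refs: list,
                   min_identity: float = 0.75, adjacency_gap: int = 10,
                   ap2_target_ref: str | None = None,
                   max_breaking_subs: int = 3,
                   phase: PhaseParams | None = None) -> Tas3Locus:
    """Fill elements, phase registers, AP2 functionality and architecture."""
    lo, hi = locus.intersite_interval()
    hits = detect_tasi_elements(record.seq[lo:hi], refs, min_identity,
                                region_offset=lo)
    for h in hits:
        h.phase_register = phase_register(locus,
                                          element_phase_position(locus, h),
                                          phase)
        if h.kind == "AP2" and ap2_target_ref is not None \
                and len(h.seq) == len(ap2_target_ref):
            elem = h.seq if h.strand_of_match == "+" else revcomp(h.seq)
            h.functional = ap2_functionality(
                elem, ap2_target_ref, max_breaking_subs)["functional"]
    locus.tasi_hits = hits
    locus.architecture = classify_architecture(locus, adjacency_gap)
    return locus


def scan_tas_loci(record: SequenceRecord, mir390_hits: list[TargetSiteHit],
                  refs: list, span_range: tuple = (150, 400),
                  min_identity: float = 0.75, adjacency_gap: int = 10,
                  ap2_target_ref: str | None = None,
                  max_breaking_subs: int = 3) -> list[Tas3Locus]:
    """Dual-site pairing + overlap resolution + full annotation."""
    cands = pair_dual_sites(mir390_hits, span_range)
    loci = resolve_locus_overlaps(cands)
    return [annotate_locus(record, l, refs, min_identity, adjacency_gap,
                           ap2_target_ref, max_breaking_subs)
            for l in loci]
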
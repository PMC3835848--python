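"""Plant-style miRNA target-site scoring and genome scanning.

Scoring follows the de facto plant complementarity rule set: each guide
position contributes 0 for a Watson-Crick pair, a wobble weight for G:U, a
mismatch weight otherwise, and a bulge weight per unpaired base; all weights
are doubled inside the 5'-core region (guide positions 2-13 by default).
The guide pairs antiparallel to the site, so guide position 1 sits opposite
the site's 3'-most base. Site length may differ from guide length by up to
three bases (banded alignment, band +-3).

A site is called *cleavable* when the guide position(s) configured in
``PenaltyWeights.cleavable_positions`` (default: position 10 only) pair
Watson-Crick; the cleavage coordinate is the template phosphate between the
bases opposite guide positions 10 and 11.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .seqs import SequenceRecord, as_dna, revcomp

WC = {"A": "T", "T": "A", "G": "C", "C": "G"}
_ORDER = "ACGT"


@dataclass
class PenaltyWeights:
    mismatch: float = 1.0
    gu: float = 0.5
    bulge: float = 2.0
    core_range: tuple = (2, 13)  # guide positions, 1-based inclusive
    core_factor: float = 2.0
    cleavable_positions: tuple = (10,)

    def factor(self, pos: int) -> float:
        lo, hi = self.core_range
        return self.core_factor if lo <= pos <= hi else 1.0

    def pair_cost(self, guide_base: str, site_base: str, pos: int) -> float:
        """Cost of guide position `pos` pairing template base `site_base`
        (both DNA spelling)."""
        if site_base == WC.get(guide_base):
            return 0.0
        if (guide_base, site_base) in (("G", "T"), ("T", "G")):
            return self.gu * self.factor(pos)
        return self.mismatch * self.factor(pos)

    def pair_state(self, guide_base: str, site_base: str) -> str:
        if site_base == WC.get(guide_base):
            return "WC"
        if (guide_base, site_base) in (("G", "T"), ("T", "G")):
            return "GU"
        return "MISMATCH"


@dataclass
class TargetAlignment:
    guide: str  # 5'->3', DNA spelling
    site: str   # matched segment, 5'->3' on its own strand
    states: list  # (guide position or None, state) in 5'->3' guide order
    penalty: float
    position10_state: str
    #: site index (0-based, 5'->3' within `site`) paired to each guide
    #: position; None for bulged guide positions
    site_index_of: dict = field(default_factory=dict)


@dataclass
class TargetSiteHit:
    sequence_id: str
    start: int  # 0-based half-open, + strand axis
    end: int
    strand: str
    guide_name: str
    alignment: TargetAlignment
    cleavable: bool
    cleavage_coord: int | None  # 0-based boundary on the + strand axis
    cleavage_approximate: bool = False

    @property
    def penalty(self) -> float:
        return self.alignment.penalty


def align_guide_to_site(guide: str, site: str,
                        weights: PenaltyWeights | None = None) -> TargetAlignment:
    """Optimal banded global alignment of `guide` against `site`
    (antiparallel pairing), minimizing the position-weighted penalty.

    A bulged guide position is charged at its own positional weight; an
    extra (bulged) site base between guide positions p and p+1 is charged
    at the weight of position max(1, p) — i.e. the 5'-ward flanking guide
    position, clipped at the guide ends.
    """
    weights = weights or PenaltyWeights()
    g = as_dna(guide)
    s = as_dna(site)
    if abs(len(s) - len(g)) > 3:
        raise ValueError("site length must be within 3 nt of guide length")
    u = s[::-1]  # u[k] is the site base opposite guide position k+1
    L, M = len(g), len(u)
    band = 3
    INF = math.inf

    def site_bulge_cost(i: int) -> float:
        # bulged site base after i consumed guide positions
        return weights.bulge * weights.factor(max(1, i))

    # D[i][j]: guide[:i] vs u[:j]
    D = [[INF] * (M + 1) for _ in range(L + 1)]
    D[0][0] = 0.0
    for j in range(1, min(M, band) + 1):  # site bases beyond guide pos 1
        D[0][j] = D[0][j - 1] + site_bulge_cost(0)
    for i in range(1, L + 1):
        for j in range(max(0, i - band), min(M, i + band) + 1):
            best = INF
            if j > 0:
                best = min(best, D[i - 1][j - 1]
                           + weights.pair_cost(g[i - 1], u[j - 1], i))
            # guide position i bulged (no site partner)
            best = min(best, D[i - 1][j] + weights.bulge * weights.factor(i))
            # extra site base between guide positions i and i+1
            if j > 0 and abs(i - (j - 1)) <= band:
                best = min(best, D[i][j - 1] + site_bulge_cost(i))
            D[i][j] = best

    # traceback
    states: list = []
    site_index_of: dict = {}
    i, j = L, M
    while i > 0 or j > 0:
        cur = D[i][j]
        if i > 0 and j > 0 and abs(i - 1 - (j - 1)) <= band and \
                math.isclose(cur, D[i - 1][j - 1]
                             + weights.pair_cost(g[i - 1], u[j - 1], i),
                             abs_tol=1e-9):
            states.append((i, weights.pair_state(g[i - 1], u[j - 1])))
            site_index_of[i] = M - j  # index into `site` (5'->3')
            i, j = i - 1, j - 1
        elif i > 0 and abs(i - 1 - j) <= band and \
                math.isclose(cur, D[i - 1][j]
                             + weights.bulge * weights.factor(i),
                             abs_tol=1e-9):
            states.append((i, "BULGE"))
            site_index_of[i] = None
            i -= 1
        else:
            states.append((None, "BULGE"))
            j -= 1
    states.reverse()
    p10 = next((st for pos, st in states if pos == 10), "BULGE")
    return TargetAlignment(g, s, states, D[L][M], p10, site_index_of)


def _cost_table(guide: str, weights: PenaltyWeights) -> np.ndarray:
    """(L x 5) cost of guide position k+1 against template base index
    (A C G T other)."""
    L = len(guide)
    C = np.zeros((L, 5))
    for k in range(L):
        for b, base in enumerate(_ORDER):
            C[k, b] = weights.pair_cost(guide[k], base, k + 1)
        C[k, 4] = weights.mismatch * weights.factor(k + 1)
    return C


def _scan_strand(seq: str, guide: str, max_penalty: float,
                 weights: PenaltyWeights) -> list[tuple[int, int, float]]:
    """(start, site_len, penalty) of every window with an alignment penalty
    <= max_penalty, by a banded DP vectorized over all start positions.

    The guide is walked 3'->5' so that it advances left-to-right along the
    template; drift d = template bases consumed minus guide bases consumed.
    """
    from .seqs import encode
    n, L = len(seq), len(guide)
    if n < L - 3:
        return []
    band = 3
    enc = encode(seq)
    enc5 = np.where(enc < 4, enc, 4).astype(np.int64)
    r = guide[::-1]  # r[m-1] is guide position L - m + 1
    C = _cost_table(guide, weights)
    INF = np.inf
    # padded per-template-position cost vectors for each reversed-guide step
    pad = L + band + 2
    cost_rows = []
    for m in range(L):
        gpos = L - m  # guide position consumed at step m+1
        row = np.full(n + pad, INF)
        row[:n] = C[gpos - 1, enc5]
        cost_rows.append(row)

    width = n + pad
    A = {d: np.full(width, INF) for d in range(-band, band + 1)}
    A[0][:n] = 0.0

    def bulge_weight_after(m: int) -> float:
        # site bulge between guide positions (L - m + 1) and (L - m); charged
        # at the 3'-ward guide position, clipped to the guide ends
        gpos = max(1, min(L, L - m))
        return weights.bulge * weights.factor(gpos)

    def closure(level: dict, m: int) -> None:
        w = bulge_weight_after(m)
        for d in range(-band + 1, band + 1):
            np.minimum(level[d], level[d - 1] + w, out=level[d])

    closure(A, 0)
    for m in range(L):
        N = {d: np.full(width, INF) for d in range(-band, band + 1)}
        for d in range(-band, band + 1):
            # diagonal: guide step m+1 consumes template index s + m + d
            shift = m + d
            if shift >= 0:
                diag = A[d][:width - shift] + cost_rows[m][shift:]
                N[d][:width - shift] = diag
            else:
                N[d][-shift:] = A[d][:width + shift] + cost_rows[m][:width + shift]
            # guide bulge: guide advances without template
            if d + 1 <= band:
                gpos = L - m
                np.minimum(N[d], A[d + 1] + weights.bulge * weights.factor(gpos),
                           out=N[d])
        closure(N, m + 1)
        A = N

    hits = []
    for s in range(n):
        # lowest penalty; ties go to the site length closest to the guide's
        cands = [(A[d][s], abs(d), d) for d in range(-band, band + 1)
                 if s + L + d <= n and L + d > 0]
        if not cands:
            continue
        p, _, d = min(cands)
        if p <= max_penalty + 1e-9:
            hits.append((s, L + d, float(p)))
    return hits


def dedup_hits(hits: list[TargetSiteHit]) -> list[TargetSiteHit]:
    """Collapse overlapping same-strand hits to local penalty minima:
    lowest penalty wins, ties go to the leftmost start."""
    ordered = sorted(hits, key=lambda h: (h.penalty, h.start, h.strand))
    kept: list[TargetSiteHit] = []
    for h in ordered:
        if any(k.sequence_id == h.sequence_id and k.strand == h.strand
               and max(k.start, h.start) < min(k.end, h.end) for k in kept):
            continue
        kept.append(h)
    kept.sort(key=lambda h: (h.start, h.strand))
    return kept


def _make_hit(record_id: str, strand: str, tstart: int, tend: int,
              site_plus_axis: str, aln: TargetAlignment, guide_name: str,
              weights: PenaltyWeights) -> TargetSiteHit:
    cleavable = all(
        next((st for pos, st in aln.states if pos == p), "BULGE") == "WC"
        for p in weights.cleavable_positions)
    coord, approx = _cleavage_boundary(aln, strand, tstart, tend)
    return TargetSiteHit(record_id, tstart, tend, strand, guide_name, aln,
                         cleavable, coord, approx)


def _cleavage_boundary(aln: TargetAlignment, strand: str, tstart: int,
                       tend: int) -> tuple[int | None, bool]:
    q10 = aln.site_index_of.get(10)
    q11 = aln.site_index_of.get(11)
    if 10 not in aln.site_index_of and 11 not in aln.site_index_of:
        return None, True
    approx = q10 is None or q11 is None or (q10 - q11) != 1
    if q10 is None:
        q10 = (q11 + 1) if q11 is not None else None
    if q10 is None:
        return None, True
    if strand == "+":
        return tstart + q10, approx
    return tend - q10, approx


def find_target_sites(record: SequenceRecord, guide: str,
                      max_penalty: float = 4.0,
                      weights: PenaltyWeights | None = None,
                      guide_name: str = "guide",
                      dedup: bool = True) -> list[TargetSiteHit]:
    """All target sites of `guide` on both strands of `record` with penalty
    <= `max_penalty`, deduplicated to local penalty minima."""
    weights = weights or PenaltyWeights()
    g = as_dna(guide)
    if not 20 <= len(g) <= 22:
        raise ValueError("guide length must be 20-22 nt")
    n = len(record)
    hits: list[TargetSiteHit] = []
    for strand in "+-":
        seq = record.seq if strand == "+" else revcomp(record.seq)
        for s, slen, _pen in _scan_strand(seq, g, max_penalty, weights):
            site = seq[s:s + slen]
            aln = align_guide_to_site(g, site, weights)
            if aln.penalty > max_penalty + 1e-9:
                continue
            if strand == "+":
                tstart, tend = s, s + slen
            else:
                tstart, tend = n - (s + slen), n - s
            hits.append(_make_hit(record.id, strand, tstart, tend, site,
                                  aln, guide_name, weights))
    return dedup_hits(hits) if dedup else sorted(
        hits, key=lambda h: (h.start, h.strand))


def cleavage_coordinate(hit: TargetSiteHit) -> int:
    """Template boundary (0-based, between bases) opposite guide positions
    10/11; raises if the alignment leaves it undefined."""
    if hit.cleavage_coord is None:
        raise ValueError("cleavage coordinate undefined for this alignment")
    return hit.cleavage_coord
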
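"""In-silico PCR with IUPAC degenerate primers.

A primer "hits" a template window when every position of the window falls in
the primer's per-position IUPAC set, up to `max_mm` mismatches, with the
3'-terminal `three_prime_exact` bases matching exactly (polymerases extend
only from a matched 3' end). Amplification is purely combinatorial — one
product per facing pair of opposite-strand sites whose length falls in the
configured product range. No melting temperature, dimer or mobility
modelling.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product as _iproduct

import numpy as np

from .seqs import IUPAC, AlphabetError, SequenceRecord, as_dna, revcomp

_IUPAC_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp_iupac(primer: str) -> str:
    return primer.translate(_IUPAC_COMP)[::-1]


@dataclass
class PrimerSet:
    name: str
    forward: str
    reverse: list  # reverse primer variants (a degenerate mixture)
    max_mm: int = 2
    three_prime_exact: int = 3
    product_range: tuple = (80, 1500)

    def __post_init__(self) -> None:
        self.forward = as_dna(self.forward)
        self.reverse = [as_dna(r) for r in self.reverse]
        for p in [self.forward, *self.reverse]:
            if len(p) < 15:
                raise ValueError(f"primer {p!r} shorter than 15 nt")
            if self.three_prime_exact > len(p):
                raise ValueError("three_prime_exact exceeds primer length")


@dataclass
class PrimerSite:
    sequence_id: str
    start: int  # 0-based half-open on the + strand axis
    end: int
    strand: str  # '+': primer sequence appears on +, extends rightward
    primer: str
    mismatches: int


@dataclass
class Amplicon:
    sequence_id: str
    start: int  # 0-based half-open: forward 5' end .. reverse 5' end
    end: int
    fwd_site: PrimerSite
    rev_site: PrimerSite
    total_mismatches: int

    @property
    def length(self) -> int:
        return self.end - self.start


def expand_degenerate(primer: str) -> list[str]:
    """All concrete sequences of an IUPAC primer (product of degeneracies)."""
    p = as_dna(primer)
    return ["".join(t) for t in _iproduct(*(IUPAC[c] for c in p))]


def _iupac_match_matrix(primer: str) -> np.ndarray:
    """len(primer) x 4 boolean matrix: does template base b satisfy
    primer position k?"""
    order = "ACGT"
    m = np.zeros((len(primer), 4), dtype=bool)
    for k, c in enumerate(primer):
        for b in IUPAC[c]:
            m[k, order.index(b)] = True
    return m


def _scan_plus(template_enc: np.ndarray, primer: str, max_mm: int,
               three_prime_exact: int) -> list[tuple[int, int]]:
    """(start, mismatches) of IUPAC-aware hits of `primer` read on +."""
    n, m = len(template_enc), len(primer)
    if n < m:
        return []
    match = _iupac_match_matrix(primer)
    # ambiguity codes in the template (enc 255) never match
    ok = np.zeros((m, n), dtype=bool)
    valid = template_enc < 4
    for k in range(m):
        ok[k, valid] = match[k, template_enc[valid]]
    mm = np.zeros(n - m + 1, dtype=np.int64)
    exact3 = np.ones(n - m + 1, dtype=bool)
    for k in range(m):
        col = ok[k, k:n - m + 1 + k]
        mm += ~col
        if k >= m - three_prime_exact:
            exact3 &= col
    hits = np.nonzero((mm <= max_mm) & exact3)[0]
    return [(int(s), int(mm[s])) for s in hits]


def find_primer_sites(template: SequenceRecord, primer: str, max_mm: int = 2,
                      three_prime_exact: int = 3) -> list[PrimerSite]:
    """All binding sites of `primer` on both strands of `template`.

    A '+' site means the primer sequence matches the + strand (the primer
    anneals to the - strand and extends rightward); a '-' site is the mirror
    case, the primer extending leftward. Coordinates are always on the
    + strand axis.
    """
    primer = as_dna(primer)
    if len(template) < len(primer):
        return []
    from .seqs import encode
    enc = encode(template.seq)
    m = len(primer)
    sites = [PrimerSite(template.id, s, s + m, "+", primer, mm)
             for s, mm in _scan_plus(enc, primer, max_mm, three_prime_exact)]
    # '-' strand: the revcomp of the primer appears on +; the primer 3' end
    # maps to the START of that window, so the exactness constraint flips.
    rc = revcomp_iupac(primer)
    match = _iupac_match_matrix(rc)
    n = len(enc)
    ok = np.zeros((m, n), dtype=bool)
    valid = enc < 4
    for k in range(m):
        ok[k, valid] = match[k, enc[valid]]
    mm = np.zeros(n - m + 1, dtype=np.int64)
    exact3 = np.ones(n - m + 1, dtype=bool)
    for k in range(m):
        col = ok[k, k:n - m + 1 + k]
        mm += ~col
        if k < three_prime_exact:
            exact3 &= col
    for s in np.nonzero((mm <= max_mm) & exact3)[0]:
        sites.append(PrimerSite(template.id, int(s), int(s) + m, "-",
                                primer, int(mm[s])))
    sites.sort(key=lambda x: (x.start, x.strand))
    return sites


def predict_amplicons(template: SequenceRecord,
                      primer_set: PrimerSet) -> list[Amplicon]:
    """Products of (forward, reverse-variant) primer pairs on `template`.

    Either primer may provide the + strand site; the product runs from the
    + site's 5' end through the - site's 5' end (rightmost base), inclusive.
    """
    fwd_sites = find_primer_sites(template, primer_set.forward,
                                  primer_set.max_mm,
                                  primer_set.three_prime_exact)
    rev_sites: list[PrimerSite] = []
    for rp in primer_set.reverse:
        rev_sites.extend(find_primer_sites(template, rp, primer_set.max_mm,
                                           primer_set.three_prime_exact))
    lo, hi = primer_set.product_range
    out = []
    for fs, rs in _iproduct(fwd_sites, rev_sites):
        if fs.strand == rs.strand:
            continue
        plus, minus = (fs, rs) if fs.strand == "+" else (rs, fs)
        length = minus.end - plus.start
        if plus.start < minus.end and lo <= length <= hi:
            out.append(Amplicon(template.id, plus.start, minus.end,
                                fs, rs, fs.mismatches + rs.mismatches))
    out.sort(key=lambda a: (a.start, a.end))
    return out
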
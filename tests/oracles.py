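"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately simple, scalar Python: these functions
define expected behaviour by direct enumeration so the production
(vectorized) code paths can be checked against them.
"""

from __future__ import annotations

import math

from tas3scan.seqs import IUPAC, revcomp
from tas3scan.targets import PenaltyWeights


def naive_primer_scan(template: str, primer: str, max_mm: int,
                      three_prime_exact: int) -> list:
    """Position-by-position IUPAC primer scan, both strands.

    Returns (start, end, strand, mismatches) on the + strand axis.
    """
    n, m = len(template), len(primer)
    rc = revcomp(template)
    out = []
    for strand in "+-":
        scanned = template if strand == "+" else rc
        for s in range(n - m + 1):
            window = scanned[s:s + m]
            mism = [window[k] not in IUPAC[primer[k]] for k in range(m)]
            if sum(mism) <= max_mm and not any(mism[m - three_prime_exact:]):
                if strand == "+":
                    out.append((s, s + m, "+", sum(mism)))
                else:
                    out.append((n - s - m, n - s, "-", sum(mism)))
    return sorted(out)


def banded_site_penalty(guide: str, window: str, weights: PenaltyWeights,
                        cutoff: float = math.inf) -> float:
    """Best global alignment penalty of guide vs one fixed window
    (antiparallel), banded at +-3 — plain nested-loop DP.

    All step costs are non-negative, so the running row minimum is a lower
    bound on the final penalty; rows whose minimum exceeds `cutoff` abandon
    early and return inf (exact for all results <= cutoff).
    """
    u = window[::-1]
    L, M = len(guide), len(u)
    band = 3
    INF = math.inf
    D = [[INF] * (M + 1) for _ in range(L + 1)]
    D[0][0] = 0.0
    for j in range(1, min(M, band) + 1):
        D[0][j] = D[0][j - 1] + weights.bulge * weights.factor(1)
    for i in range(1, L + 1):
        row_min = INF
        for j in range(max(0, i - band), min(M, i + band) + 1):
            best = INF
            if j > 0:
                best = min(best, D[i - 1][j - 1]
                           + weights.pair_cost(guide[i - 1], u[j - 1], i))
            best = min(best, D[i - 1][j] + weights.bulge * weights.factor(i))
            if j > 0 and abs(i - (j - 1)) <= band:
                best = min(best, D[i][j - 1]
                           + weights.bulge * weights.factor(max(1, i)))
            D[i][j] = best
            row_min = min(row_min, best)
        if row_min > cutoff:
            return INF
    return D[L][M]


def brute_force_target_scan(seq: str, guide: str, max_penalty: float,
                            weights: PenaltyWeights,
                            cutoff: float = math.inf) -> list:
    """Sliding-window scan of one strand: every start, window lengths
    guide +-3, best penalty; (start, site_len, penalty) for passes.
    Ties on penalty prefer the length closest to the guide's. A finite
    `cutoff` >= max_penalty prunes hopeless windows without changing any
    reported hit."""
    n, L = len(seq), len(guide)
    out = []
    for s in range(n):
        cands = []
        for d in range(-3, 4):
            wlen = L + d
            if wlen <= 0 or s + wlen > n:
                continue
            p = banded_site_penalty(guide, seq[s:s + wlen], weights, cutoff)
            cands.append((p, abs(d), d))
        if not cands:
            continue
        p, _, d = min(cands)
        if p <= max_penalty + 1e-9:
            out.append((s, L + d, round(p, 6)))
    return out


def enumerate_alignment_scores(a: str, b: str, match=1.0, mismatch=-1.0,
                               gap_open=-4.0, gap_extend=-1.0) -> float:
    """Best global affine-gap score by exhaustive path enumeration.

    Gap of length k costs gap_open + (k-1)*gap_extend. Exponential; for
    sequences up to ~12 nt."""
    best = -math.inf
    n, m = len(a), len(b)

    def go(i, j, score, gap_state):
        nonlocal best
        if i == n and j == m:
            best = max(best, score)
            return
        # bound: remaining columns can add at most +match each
        if score + match * (max(n - i, m - j)) < best:
            return
        if i < n and j < m:
            s = match if a[i] == b[j] else mismatch
            go(i + 1, j + 1, score + s, 0)
        if i < n:
            cost = gap_extend if gap_state == 1 else gap_open
            go(i + 1, j, score + cost, 1)
        if j < m:
            cost = gap_extend if gap_state == 2 else gap_open
            go(i, j + 1, score + cost, 2)

    go(0, 0, 0.0, 0)
    return best


def naive_arm_scan(seq: str, variants: list, max_mm: int) -> dict:
    """start -> (mismatches, variant) best ungapped variant match."""
    best = {}
    for var in variants:
        m = len(var)
        for s in range(len(seq) - m + 1):
            mm = sum(1 for a, b in zip(seq[s:s + m], var) if a != b)
            if mm <= max_mm and (s not in best or mm < best[s][0]):
                best[s] = (mm, var)
    return best
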
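"""Hairpin-restricted minimum-free-energy RNA folding.

The structure space is every non-crossing secondary structure with **no
multibranch loop**: a single chain of nested base pairs whose consecutive
pairs are separated by stacks, bulges or internal loops and which terminates
in one hairpin loop. The unfolded state (energy 0) is always admissible, so
the reported MFE is never positive.

``fold_best_hairpin`` is an O(n^2 * c^2) dynamic program (interior loops
capped at ``model.max_interior`` unpaired nucleotides, the cap used by
standard folders), vectorized over window positions with numpy.
``exhaustive_hairpin_mfe`` is an independent top-down enumeration over the
same structure space, practical for windows of a few dozen nucleotides; it
exists so the production DP can be validated against brute force.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .energy import PAIR_TYPES, EnergyModel, load_default_model
from .seqs import as_rna

_RNA_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}


@dataclass
class HairpinFold:
    """A non-crossing pairing of one window with its energy and stats."""

    sequence_id: str
    length: int
    pairing: frozenset  # of (i, j) tuples, i < j, 0-based on the window
    dot_bracket: str
    mfe: float  # kcal/mol, rounded to 2 decimals
    stem_bp: int = field(init=False)
    has_multibranch: bool = field(init=False)
    loop_lengths: tuple = field(init=False)

    def __post_init__(self) -> None:
        self.stem_bp = len(self.pairing)
        self.has_multibranch = has_multibranch(self.pairing)
        self.loop_lengths = unpaired_runs(self.length, self.pairing)


def parse_dot_bracket(db: str) -> frozenset:
    """Pairing set of a Vienna dot-bracket string."""
    stack: list[int] = []
    pairs = set()
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            pairs.add((stack.pop(), i))
        elif c != ".":
            raise ValueError(f"illegal dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced '(' in dot-bracket string")
    return frozenset(pairs)


def to_dot_bracket(n: int, pairing) -> str:
    out = ["."] * n
    for i, j in pairing:
        out[i], out[j] = "(", ")"
    return "".join(out)


def has_multibranch(pairing) -> bool:
    """True iff some pair directly encloses two or more disjoint helices."""
    pairs = sorted(pairing)
    # count direct children of each pair via an interval stack
    events = []
    for i, j in pairs:
        events.append((i, 0, (i, j)))
        events.append((j, 1, (i, j)))
    events.sort()
    stack: list[list] = []  # [pair, n_children]
    for _, kind, pair in events:
        if kind == 0:
            stack.append([pair, 0])
        else:
            _, nch = stack.pop()
            if nch >= 2:
                return True
            if stack:
                stack[-1][1] += 1
    return False


def unpaired_runs(n: int, pairing) -> tuple:
    paired = np.zeros(n, dtype=bool)
    for i, j in pairing:
        paired[i] = paired[j] = True
    runs, cur = [], 0
    for p in paired:
        if p:
            if cur:
                runs.append(cur)
            cur = 0
        else:
            cur += 1
    if cur:
        runs.append(cur)
    return tuple(runs)


def structure_stats(fold: HairpinFold) -> dict:
    return {
        "stem_bp": fold.stem_bp,
        "mfe": fold.mfe,
        "has_multibranch": fold.has_multibranch,
        "max_loop": max(fold.loop_lengths, default=0),
    }


def _pair_index_matrix(seq: str, model: EnergyModel) -> np.ndarray:
    """n x n int matrix: index into PAIR_TYPES, or -1 if (i, j) cannot pair."""
    lut = np.full((4, 4), -1, dtype=np.int64)
    for idx, p in enumerate(PAIR_TYPES):
        if model.pair_type(p[0], p[1]) is not None:
            lut[_RNA_INDEX[p[0]], _RNA_INDEX[p[1]]] = idx
    enc = np.array([_RNA_INDEX[c] for c in seq], dtype=np.int64)
    return lut[enc[:, None], enc[None, :]]


def fold_best_hairpin(window: str, model: EnergyModel | None = None,
                      sequence_id: str = "window") -> HairpinFold:
    """Minimum-energy single stem-loop structure of `window`.

    Accepts T or U spelling; raises :class:`AlphabetError` on anything else.
    Returns the unfolded state (empty pairing, mfe 0.0) when no structure
    has negative energy.
    """
    model = model or _default_model()
    seq = as_rna(window)
    n = len(seq)
    min_span = model.min_hairpin_loop + 1
    if n <= min_span:
        return HairpinFold(sequence_id, n, frozenset(), "." * n, 0.0)

    pi = _pair_index_matrix(seq, model)
    stack_t = model.stack_table
    term = np.array([model.terminal_penalty(p) for p in PAIR_TYPES])
    cap = model.max_interior

    V = np.full((n, n), np.inf)
    for span in range(min_span, n):
        i_idx = np.arange(n - span)
        j_idx = i_idx + span
        ptypes = pi[i_idx, j_idx]
        mask = ptypes >= 0
        if not mask.any():
            continue
        best = np.full(n - span, np.inf)
        best[mask] = model.hairpin_energy(span - 1)
        for a in range(cap + 1):
            if span - 2 - a < min_span:
                break
            for b in range(cap + 1 - a):
                inner_span = span - 2 - a - b
                if inner_span < min_span:
                    break
                k = i_idx + 1 + a
                l = j_idx - 1 - b
                vin = V[k, l]
                if a == 0 and b == 0:
                    inner_p = pi[k, l]
                    cost = np.where(inner_p >= 0,
                                    stack_t[ptypes, inner_p], np.inf)
                elif a + b == 1:
                    inner_p = pi[k, l]
                    cost = np.where(
                        inner_p >= 0,
                        model.bulge_energy(1) + stack_t[ptypes, inner_p],
                        np.inf)
                elif a == 0 or b == 0:
                    cost = model.bulge_energy(a + b)
                else:
                    cost = model.internal_energy(a + b)
                best = np.minimum(best, vin + cost)
        best[~mask] = np.inf
        V[i_idx, j_idx] = best

    total = np.where(pi >= 0, V + term[pi], np.inf)
    if not np.isfinite(total).any() or total.min() >= 0:
        return HairpinFold(sequence_id, n, frozenset(), "." * n, 0.0)
    oi, oj = np.unravel_index(int(np.argmin(total)), total.shape)
    mfe = float(total[oi, oj])

    pairs = _traceback(int(oi), int(oj), V, pi, model)
    return HairpinFold(sequence_id, n, frozenset(pairs),
                       to_dot_bracket(n, pairs), round(mfe, 2))


def _traceback(i: int, j: int, V: np.ndarray, pi: np.ndarray,
               model: EnergyModel) -> list:
    """Recover one optimal structure under the deterministic preference
    order: stack, then interior candidates by growing loop size (5' side
    first), hairpin last."""
    min_span = model.min_hairpin_loop + 1
    cap = model.max_interior
    stack_t = model.stack_table
    pairs = []
    tol = 1e-9
    while True:
        pairs.append((i, j))
        target = V[i, j]
        span = j - i
        found = None
        for total_loop in range(cap + 1):
            for a in range(total_loop + 1):
                b = total_loop - a
                k, l = i + 1 + a, j - 1 - b
                if l - k < min_span or k >= l:
                    continue
                if not np.isfinite(V[k, l]):
                    continue
                if a == 0 and b == 0:
                    if pi[k, l] < 0:
                        continue
                    cost = stack_t[pi[i, j], pi[k, l]]
                elif a + b == 1:
                    if pi[k, l] < 0:
                        continue
                    cost = model.bulge_energy(1) + stack_t[pi[i, j], pi[k, l]]
                elif a == 0 or b == 0:
                    cost = model.bulge_energy(a + b)
                else:
                    cost = model.internal_energy(a + b)
                if abs(V[k, l] + cost - target) <= tol:
                    found = (k, l)
                    break
            if found:
                break
        if found is None:
            # terminal hairpin loop
            return pairs
        i, j = found


# ---------------------------------------------------------------------------
# independent reference: exhaustive enumeration over the same structure space


def exhaustive_hairpin_mfe(window: str, model: EnergyModel | None = None) -> float:
    """Brute-force MFE over all non-crossing, non-multibranch structures.

    Top-down recursion over chains of nested pairs, evaluating the energy of
    every admissible chain directly from the model. Exponential without the
    memo on subproblems; intended for windows up to a few dozen nt as a
    validation reference for :func:`fold_best_hairpin`.
    """
    model = model or _default_model()
    seq = as_rna(window)
    n = len(seq)
    min_loop = model.min_hairpin_loop

    @lru_cache(maxsize=None)
    def closed(i: int, j: int) -> float:
        """Best energy of a chain whose outermost pair is (i, j)."""
        pt = model.pair_type(seq[i], seq[j])
        if pt is None:
            return float("inf")
        best = model.hairpin_energy(j - i - 1)
        for k in range(i + 1, j):
            for l in range(j - 1, k, -1):
                left, right = k - i - 1, j - l - 1
                if left + right > model.max_interior:
                    continue
                if l - k - 1 < min_loop:
                    break
                inner = model.pair_type(seq[k], seq[l])
                if inner is None:
                    continue
                cost = model.interior_energy(pt, inner, left, right)
                best = min(best, cost + closed(k, l))
        return best

    best = 0.0
    for i in range(n):
        for j in range(i + min_loop + 1, n):
            pt = model.pair_type(seq[i], seq[j])
            if pt is None:
                continue
            e = closed(i, j) + model.terminal_penalty(pt)
            best = min(best, e)
    return round(best, 2)


def lower_stem_extension(fold: HairpinFold, duplex) -> int:
    """Base pairs in the stem below (outside) the miR/miR* duplex.

    `duplex` is a pair of 0-based half-open arm intervals on the window.
    """
    (s1, e1), (s2, e2) = sorted([tuple(duplex[0]), tuple(duplex[1])])
    if s1 < 0 or e2 > fold.length or s1 >= e1 or s2 >= e2:
        raise ValueError("duplex arms must lie within the folded window")
    return sum(1 for i, j in fold.pairing if i < s1 and j >= e2)


_MODEL_CACHE: dict = {}


def _default_model() -> EnergyModel:
    if "default" not in _MODEL_CACHE:
        _MODEL_CACHE["default"] = load_default_model()
    return _MODEL_CACHE["default"]
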
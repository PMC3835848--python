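"""Nucleotide sequence primitives shared across the package.

Conventions used everywhere:

* internal coordinates are 0-based, half-open; the GFF3/report writers
  convert to 1-based inclusive at the boundary (`tas3scan.gff`);
* genomic sequences are canonicalized to uppercase DNA (``T`` spelling);
  folding converts to RNA (``U`` spelling) at the point of use;
* IUPAC ambiguity codes are honoured only where degenerate primers are
  involved — genome scanners treat non-ACGT letters as never matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")

#: IUPAC code -> set of concrete DNA bases it stands for.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


class AlphabetError(ValueError):
    """Raised when a sequence contains characters outside the expected alphabet."""


@dataclass
class SequenceRecord:
    """An identified nucleotide sequence (DNA spelling, uppercase)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        self.seq = as_dna(self.seq)

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self, new_id: str | None = None) -> "SequenceRecord":
        return SequenceRecord(new_id or f"{self.id}_rc", revcomp(self.seq),
                              self.description)


def as_dna(seq: str) -> str:
    """Uppercase and spell in DNA (U -> T). Accepts IUPAC ambiguity codes."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - set(IUPAC)
    if bad:
        raise AlphabetError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return s


def as_rna(seq: str) -> str:
    """Uppercase and spell in RNA (T -> U); strict ACGU alphabet."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - set("ACGU")
    if bad:
        raise AlphabetError(f"non-ACGU characters in sequence: {sorted(bad)}")
    return s


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode strict-ACGT DNA as uint8 indices (A=0 C=1 G=2 T=3; other=255).

    Non-ACGT (ambiguity) codes encode to 255 so that scanners built on
    equality comparisons never match through them.
    """
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def hamming_profile(template: np.ndarray, pattern: np.ndarray) -> np.ndarray:
    """Mismatch count of `pattern` at every start offset of `template`.

    Vectorized O(n·m): one boolean comparison per pattern position.
    Returns an int array of length ``len(template) - len(pattern) + 1``
    (empty if the pattern is longer than the template).
    """
    n, m = len(template), len(pattern)
    if n < m:
        return np.zeros(0, dtype=np.int64)
    counts = np.zeros(n - m + 1, dtype=np.int64)
    for k in range(m):
        counts += template[k:n - m + 1 + k] != pattern[k]
    return counts


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """i.i.d. random DNA with the requested expected GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    return "".join(bases[rng.choice(4, size=length, p=p)])
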
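"""Nearest-neighbor RNA energy model for hairpin-restricted folding.

The model is a deliberately small Turner-style parameterisation: stacking
free energies over adjacent base pairs, loop-initiation tables for hairpin,
bulge and internal loops (log-extrapolated beyond the tabulated sizes), a
terminal AU/GU penalty on the outermost pair, and nothing else — no dangling
ends, no coaxial stacking, no sequence-specific loop bonuses. Temperature is
fixed at 37 °C and the unfolded state has energy 0.

Parameters ship in ``data/energy_params.json`` so the model is auditable and
swappable. A single-nucleotide bulge keeps the stack between its flanking
pairs (standard treatment); larger loops interrupt stacking.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

#: canonical pair order used for integer pair encoding in the DP
PAIR_TYPES = ("AU", "UA", "CG", "GC", "GU", "UG")
_PAIR_INDEX = {p: i for i, p in enumerate(PAIR_TYPES)}

WC_PAIRS = {"AU", "UA", "CG", "GC"}
WOBBLE_PAIRS = {"GU", "UG"}


@dataclass
class EnergyModel:
    stack: dict
    hairpin_loop: dict
    bulge_loop: dict
    internal_loop: dict
    terminal_au_gu: float
    lxc: float
    min_hairpin_loop: int = 3
    max_interior: int = 30
    allow_gu: bool = True

    # derived lookup tables (filled in __post_init__)
    stack_table: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        t = np.full((len(PAIR_TYPES), len(PAIR_TYPES)), np.inf)
        for p1, row in self.stack.items():
            for p2, dg in row.items():
                t[_PAIR_INDEX[p1], _PAIR_INDEX[p2]] = dg
        self.stack_table = t

    # -- pair predicates -------------------------------------------------
    def pair_type(self, x: str, y: str) -> str | None:
        """Pair-type string for bases x (5') and y (3'), or None if unpairable."""
        p = x + y
        if p in WC_PAIRS or (self.allow_gu and p in WOBBLE_PAIRS):
            return p
        return None

    def can_pair(self, x: str, y: str) -> bool:
        return self.pair_type(x, y) is not None

    # -- loop energies ---------------------------------------------------
    def _loop(self, table: dict, size: int) -> float:
        if size in table:
            return table[size]
        mx = max(table)
        return table[mx] + self.lxc * math.log(size / mx)

    def hairpin_energy(self, size: int) -> float:
        if size < self.min_hairpin_loop:
            return math.inf
        return self._loop(self.hairpin_loop, size)

    def bulge_energy(self, size: int) -> float:
        return self._loop(self.bulge_loop, size)

    def internal_energy(self, size: int) -> float:
        return self._loop(self.internal_loop, size)

    def stack_energy(self, outer: str, inner: str) -> float:
        return self.stack[outer][inner]

    def terminal_penalty(self, pair: str) -> float:
        return self.terminal_au_gu if pair not in ("CG", "GC") else 0.0

    def interior_energy(self, outer: str, inner: str, left: int, right: int) -> float:
        """Energy of the loop closed by `outer` enclosing `inner`, with
        `left`/`right` unpaired nucleotides on the 5'/3' sides."""
        if left == 0 and right == 0:
            return self.stack_energy(outer, inner)
        size = left + right
        if size > self.max_interior:
            return math.inf
        if left == 0 or right == 0:
            dg = self.bulge_energy(size)
            if size == 1:  # stacking persists across a single-nt bulge
                dg += self.stack_energy(outer, inner)
            return dg
        return self.internal_energy(size)


def load_default_model(allow_gu: bool = True) -> EnergyModel:
    raw = json.loads(
        resources.files("tas3scan.data").joinpath("energy_params.json").read_text()
    )
    return EnergyModel(
        stack=raw["stack"],
        hairpin_loop={int(k): v for k, v in raw["hairpin_loop"].items()},
        bulge_loop={int(k): v for k, v in raw["bulge_loop"].items()},
        internal_loop={int(k): v for k, v in raw["internal_loop"].items()},
        terminal_au_gu=raw["terminal_au_gu"],
        lxc=raw["lxc"],
        min_hairpin_loop=raw["min_hairpin_loop"],
        max_interior=raw["max_interior"],
        allow_gu=allow_gu,
    )
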
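"""State alphabets.

An :class:`Alphabet` declares which symbols are *counted* states (observations
that enter frequency computations), which are ambiguity codes (allowed but
never counted), and the gap/missing conventions. Gaps ('-') and missing data
('?') are kept distinct on input but both are treated as non-observations by
every downstream statistic.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping


@dataclass(frozen=True)
class Alphabet:
    name: str
    states: tuple[str, ...]
    #: ambiguity symbol -> set of states it may resolve to (never counted)
    ambiguity: Mapping[str, frozenset[str]] = field(default_factory=dict)
    gap: str = "-"
    missing: str = "?"

    @property
    def allowed(self) -> frozenset[str]:
        return frozenset(self.states) | frozenset(self.ambiguity) | {self.gap, self.missing}

    def is_counted(self, symbol: str) -> bool:
        return symbol in self.states

    def normalize(self, symbol: str) -> str:
        symbol = symbol.upper()
        if self.name in ("dna", "ry") and symbol == "U":
            return "T"
        return symbol


_DNA_AMBIGUITY = MappingProxyType({
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
})

DNA = Alphabet("dna", ("A", "C", "G", "T"), _DNA_AMBIGUITY)

#: two-state purine/pyrimidine alphabet produced by RY recoding
RY = Alphabet("ry", ("R", "Y"), MappingProxyType({"N": frozenset("RY")}))

_AA = tuple("ACDEFGHIKLMNPQRSTVWY")
PROTEIN = Alphabet(
    "protein",
    _AA,
    MappingProxyType({
        "X": frozenset(_AA),
        "B": frozenset("DN"),
        "Z": frozenset("EQ"),
        "J": frozenset("IL"),
        "*": frozenset(_AA),  # stop/frameshift marker: allowed, never counted
    }),
)

_BY_NAME = {a.name: a for a in (DNA, RY, PROTEIN)}


def get_alphabet(name) -> Alphabet:
    """Resolve an alphabet by name ('dna', 'ry', 'protein') or pass one through."""
    if isinstance(name, Alphabet):
        return name
    try:
        return _BY_NAME[str(name).lower()]
    except KeyError:
        raise ValueError(f"unknown alphabet {name!r}; known: {sorted(_BY_NAME)}") from None
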
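"""State spaces for reversible substitution models.

The canonical 20-residue alphabet uses the PAML ``dat`` ordering
(A R N D C Q E G H I L K M F P S T W Y V); every matrix, file and index in
the package follows it.  Small alphabets can be constructed for testing and
for low-dimensional oracles, but the public estimation API is 20-state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PAML_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: Symbols treated as "missing data" in likelihoods (partial vector of ones).
DEFAULT_AMBIGUITY = frozenset("BZXJUO?*.")


@dataclass(frozen=True)
class Alphabet:
    """An ordered residue alphabet with gap and missing-data symbols."""

    residues: tuple[str, ...] = tuple(PAML_ORDER)
    gap_symbol: str = "-"
    ambiguity_symbols: frozenset[str] = DEFAULT_AMBIGUITY
    _index: dict[str, int] = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if len(set(self.residues)) != len(self.residues):
            raise ValueError("duplicate residues in alphabet")
        object.__setattr__(
            self, "_index", {r: i for i, r in enumerate(self.residues)}
        )

    @property
    def size(self) -> int:
        return len(self.residues)

    def index(self, symbol: str) -> int:
        """Map a symbol to a state index; gap/ambiguity map to MISSING."""
        if symbol in self._index:
            return self._index[symbol]
        sym = symbol.upper()
        if sym in self._index:
            return self._index[sym]
        if symbol == self.gap_symbol:
            return GAP
        if sym in self.ambiguity_symbols or symbol in self.ambiguity_symbols:
            return MISSING
        raise KeyError(f"symbol {symbol!r} not in alphabet")

    def encode(self, sequence: str) -> np.ndarray:
        """Encode a sequence string as int8 state codes (GAP/MISSING < 0)."""
        return np.array([self.index(c) for c in sequence], dtype=np.int8)

    def decode(self, codes: np.ndarray) -> str:
        out = []
        for c in codes:
            if c == GAP:
                out.append(self.gap_symbol)
            elif c == MISSING:
                out.append("X" if self.size == 20 else "?")
            else:
                out.append(self.residues[int(c)])
        return "".join(out)


#: Sentinel state codes used in encoded sequences.
GAP = -1
MISSING = -2

#: The package-wide canonical amino-acid alphabet.
AMINO = Alphabet()


def toy_alphabet(letters: str) -> Alphabet:
    """A small alphabet for tests and low-dimensional numerical oracles."""
    return Alphabet(residues=tuple(letters), ambiguity_symbols=frozenset("?"))
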
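"""Sequence alphabets for one-hot encoding.

The peptide alphabet is the 20 standard amino acids in alphabetical
one-letter order plus a padding symbol, giving 21 input channels. Synthetic
proof-of-concept datasets use smaller alphabets with the same machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PAD = "-"
START = "^"


@dataclass(frozen=True)
class Alphabet:
    """Ordered symbol set with a distinguished pad and start symbol.

    ``residues`` are the content symbols; the pad symbol occupies the last
    input channel, so ``size = len(residues) + 1``. The start symbol is used
    only on the decoder side and never appears in encoded sequences.
    """

    residues: str = AMINO_ACIDS
    pad_symbol: str = PAD
    start_symbol: str = START
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.residues)) != len(self.residues):
            raise ValueError("duplicate residues in alphabet")
        if self.pad_symbol in self.residues or self.start_symbol in self.residues:
            raise ValueError("pad/start symbol collides with a residue")
        if self.pad_symbol == self.start_symbol:
            raise ValueError("pad and start symbols must differ")
        idx = {aa: i for i, aa in enumerate(self.residues)}
        idx[self.pad_symbol] = len(self.residues)
        object.__setattr__(self, "_index", idx)

    @property
    def size(self) -> int:
        """Number of input channels (residues + pad)."""
        return len(self.residues) + 1

    @property
    def pad_index(self) -> int:
        return len(self.residues)

    def index(self, symbol: str) -> int:
        try:
            return self._index[symbol]
        except KeyError:
            raise KeyError(f"symbol {symbol!r} not in alphabet") from None

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._index


#: Standard peptide alphabet: 20 amino acids + pad = 21 channels.
PEPTIDE_ALPHABET = Alphabet()
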
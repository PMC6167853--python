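"""
Alphabet-encoded sequences.

A sequence is stored not as its symbols but as an array of *symbol codes*:
the code of a symbol is its 0-based index in the ordered symbol list of the
sequence's :class:`Alphabet`.  All downstream operations (alignment,
search) work on the code arrays alone and are therefore independent of the
actual symbol type — symbols may be single characters, multi-character
strings, numbers, tuples, any hashable value.

The integer width of the code array adapts to the alphabet size, so
alphabets with more than 256 symbols are supported transparently.
"""

from __future__ import annotations

from typing import Any, Iterable, Sequence as _PySequence

import numpy as np

__all__ = [
    "AlphabetError",
    "Alphabet",
    "code_width",
    "Sequence",
    "GeneralSequence",
    "NucleotideSequence",
    "ProteinSequence",
    "CodonTable",
]


class AlphabetError(Exception):
    """Raised when a symbol or code is not valid for an alphabet."""


class Alphabet:
    """
    An ordered collection of distinct hashable symbols.

    The position of a symbol in the collection is its *symbol code*.

    Parameters
    ----------
    symbols : iterable of hashable
        The allowed symbols, in code order.  Duplicates are rejected.
    """

    def __init__(self, symbols: Iterable[Any]) -> None:
        self._symbols = tuple(symbols)
        if len(self._symbols) == 0:
            raise AlphabetError("An alphabet must contain at least one symbol")
        self._codes = {sym: i for i, sym in enumerate(self._symbols)}
        if len(self._codes) != len(self._symbols):
            raise AlphabetError("Duplicate symbols in alphabet")

    @property
    def symbols(self) -> tuple:
        return self._symbols

    def __len__(self) -> int:
        return len(self._symbols)

    def __iter__(self):
        return iter(self._symbols)

    def __contains__(self, symbol: Any) -> bool:
        return symbol in self._codes

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alphabet):
            return NotImplemented
        return self._symbols == other._symbols

    def __hash__(self) -> int:
        return hash(self._symbols)

    def __repr__(self) -> str:
        return f"Alphabet({list(self._symbols)!r})"

    def encode(self, symbol: Any) -> int:
        """Return the code (index) of `symbol`."""
        try:
            return self._codes[symbol]
        except (KeyError, TypeError):
            raise AlphabetError(
                f"Symbol {symbol!r} is not in the alphabet"
            ) from None

    def decode(self, code: int) -> Any:
        """Return the symbol with the given code."""
        code = int(code)
        if not 0 <= code < len(self._symbols):
            raise AlphabetError(
                f"Code {code} is out of range for alphabet of size "
                f"{len(self._symbols)}"
            )
        return self._symbols[code]

    def encode_multiple(self, symbols: Iterable[Any]) -> np.ndarray:
        """Encode an iterable of symbols into a code array."""
        dtype = code_dtype(len(self))
        symbols = list(symbols)
        codes = np.empty(len(symbols), dtype=dtype)
        for i, sym in enumerate(symbols):
            try:
                codes[i] = self._codes[sym]
            except (KeyError, TypeError):
                raise AlphabetError(
                    f"Symbol {sym!r} at position {i} is not in the alphabet"
                ) from None
        return codes

    def decode_multiple(self, codes: np.ndarray) -> list:
        """Decode a code array back into a list of symbols."""
        codes = np.asarray(codes)
        if codes.size and (codes.min() < 0 or codes.max() >= len(self)):
            raise AlphabetError("Code array contains out-of-range codes")
        return [self._symbols[int(c)] for c in codes]

    def extends(self, other: "Alphabet") -> bool:
        """
        True if this alphabet equals `other` or is an ordered extension of
        it (i.e. `other`'s symbol list is a prefix of this one's), so that
        codes under `other` are valid under this alphabet.
        """
        if len(other) > len(self):
            return False
        return self._symbols[: len(other)] == other.symbols


def code_width(alphabet_size: int) -> int:
    """
    Number of bytes per symbol code required for an alphabet of the given
    size: the smallest of 1, 2, 4 or 8 bytes whose unsigned range covers
    the size.
    """
    if alphabet_size < 1:
        raise ValueError("Alphabet size must be at least 1")
    if alphabet_size <= 2**8:
        return 1
    if alphabet_size <= 2**16:
        return 2
    if alphabet_size <= 2**32:
        return 4
    return 8


def code_dtype(alphabet_size: int) -> np.dtype:
    """Unsigned integer dtype matching :func:`code_width`."""
    return np.dtype(f"u{code_width(alphabet_size)}")


class Sequence:
    """
    A sequence of symbols over an :class:`Alphabet`, stored as an unsigned
    integer code array.

    Subclasses fix the alphabet; this base class carries the shared
    encode/decode machinery.  Equality compares alphabet and code array.
    """

    def __init__(self, alphabet: Alphabet, symbols: Iterable[Any] = ()) -> None:
        self._alphabet = alphabet
        self._code = alphabet.encode_multiple(symbols)

    @classmethod
    def from_code(cls, alphabet: Alphabet, code: np.ndarray) -> "Sequence":
        """Build a sequence directly from a code array (validated)."""
        seq = cls.__new__(cls)
        Sequence._init_from_code(seq, alphabet, code)
        return seq

    def _init_from_code(self, alphabet: Alphabet, code: np.ndarray) -> None:
        code = np.asarray(code)
        if code.size and (code.min() < 0 or code.max() >= len(alphabet)):
            raise AlphabetError("Code array contains out-of-range codes")
        self._alphabet = alphabet
        self._code = code.astype(code_dtype(len(alphabet)), copy=False)

    @property
    def alphabet(self) -> Alphabet:
        return self._alphabet

    @property
    def code(self) -> np.ndarray:
        return self._code

    @code.setter
    def code(self, code: np.ndarray) -> None:
        self._init_from_code(self._alphabet, code)

    @property
    def symbols(self) -> list:
        return self._alphabet.decode_multiple(self._code)

    def __len__(self) -> int:
        return len(self._code)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Sequence):
            return NotImplemented
        return self._alphabet == other._alphabet and np.array_equal(
            self._code, other._code
        )

    def __getitem__(self, index):
        if isinstance(index, (int, np.integer)):
            return self._alphabet.decode(self._code[index])
        sub = type(self).__new__(type(self))
        Sequence._init_from_code(sub, self._alphabet, self._code[index])
        return sub

    def __str__(self) -> str:
        return "".join(str(s) for s in self.symbols)

    def __repr__(self) -> str:
        return f"{type(self).__name__}({str(self)!r})"


class GeneralSequence(Sequence):
    """A sequence over an arbitrary user-supplied alphabet."""


# IUPAC nucleotide ambiguity complements; unambiguous ACGT is the prefix.
_DNA_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


class NucleotideSequence(Sequence):
    """
    A DNA sequence.

    By default the unambiguous alphabet ``A, C, G, T`` is used; passing
    ``ambiguous=True`` (or supplying ambiguity codes in the input) selects
    the IUPAC-ambiguous extension.  ``U`` is accepted on input and mapped
    to ``T``; the stored alphabet is always DNA.
    """

    alphabet = Alphabet("ACGT")
    alphabet_ambiguous = Alphabet("ACGTRYSWKMBVDHN")

    def __init__(self, sequence: str = "", ambiguous: bool | None = None) -> None:
        sequence = sequence.upper().replace("U", "T")
        if ambiguous is None:
            ambiguous = any(ch not in "ACGT" for ch in sequence)
        alphabet = self.alphabet_ambiguous if ambiguous else self.alphabet
        super().__init__(alphabet, sequence)

    def complement(self) -> "NucleotideSequence":
        """Base-pair complement (IUPAC pairing for ambiguity codes)."""
        comp = NucleotideSequence.__new__(NucleotideSequence)
        table = np.array(
            [self._alphabet.encode(_DNA_COMPLEMENT[s]) for s in self._alphabet],
            dtype=self._code.dtype,
        )
        Sequence._init_from_code(comp, self._alphabet, table[self._code])
        return comp

    def reverse(self) -> "NucleotideSequence":
        rev = NucleotideSequence.__new__(NucleotideSequence)
        Sequence._init_from_code(rev, self._alphabet, self._code[::-1])
        return rev

    def reverse_complement(self) -> "NucleotideSequence":
        """Reverse complement; an involution."""
        return self.complement().reverse()

    def translate(
        self,
        codon_table: "CodonTable | None" = None,
        complete: bool = False,
    ):
        """
        Translate into protein sequence(s).

        With ``complete=True`` the whole sequence is translated in frame 0
        (length must be divisible by 3); stop codons are rendered as
        ``*``.  Otherwise every open reading frame — start codon up to,
        excluding, the first in-frame stop — in the three forward frames
        is translated and a list of proteins is returned together with
        the half-open nucleotide ranges they came from.  ORFs lacking an
        in-frame stop are truncated at the sequence end.  Codons with
        ambiguity codes translate to ``X``.
        """
        if codon_table is None:
            codon_table = CodonTable.default_table()
        seq_str = str(self)
        if complete:
            if len(self) % 3 != 0:
                raise ValueError(
                    "Complete translation requires a sequence length "
                    "divisible by 3"
                )
            protein = "".join(
                codon_table.translate_codon(seq_str[i : i + 3])
                for i in range(0, len(seq_str), 3)
            )
            return ProteinSequence(protein)
        proteins = []
        ranges = []
        for start in range(len(seq_str) - 2):
            if seq_str[start : start + 3] not in codon_table.start_codons:
                continue
            aas = []
            stop_found = False
            end = start
            for i in range(start, len(seq_str) - 2, 3):
                codon = seq_str[i : i + 3]
                aa = codon_table.translate_codon(codon)
                if aa == "*":
                    stop_found = True
                    end = i + 3
                    break
                aas.append(aa)
                end = i + 3
            del stop_found
            proteins.append(ProteinSequence("".join(aas)))
            ranges.append((start, end))
        return proteins, ranges


class ProteinSequence(Sequence):
    """
    A protein sequence over the 20 canonical amino acids plus ``X``
    (unknown) and ``*`` (stop).
    """

    alphabet = Alphabet("ACDEFGHIKLMNPQRSTVWY" + "X*")

    def __init__(self, sequence: str = "") -> None:
        sequence = sequence.upper()
        # Fold non-canonical one-letter codes into X rather than failing
        sequence = "".join(
            ch if ch in self.alphabet else "X" for ch in sequence
        )
        super().__init__(self.alphabet, sequence)


_STANDARD_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


class CodonTable:
    """
    A genetic code: a map from the 64 codons to amino-acid symbols plus a
    set of start codons.  The default is the standard code with ``ATG`` as
    the sole start codon.
    """

    def __init__(self, codon_map: dict, start_codons: Iterable[str] = ("ATG",)):
        if len(codon_map) != 64:
            raise ValueError("A codon table requires exactly 64 codons")
        bad = [aa for aa in codon_map.values() if aa not in ProteinSequence.alphabet]
        if bad:
            raise ValueError(f"Codon table values not in protein alphabet: {bad}")
        self._map = dict(codon_map)
        self._starts = frozenset(start_codons)

    _default: "CodonTable | None" = None

    @classmethod
    def default_table(cls) -> "CodonTable":
        if cls._default is None:
            cls._default = cls(_STANDARD_CODE)
        return cls._default

    @property
    def codon_map(self) -> dict:
        return dict(self._map)

    @property
    def start_codons(self) -> frozenset:
        return self._starts

    def translate_codon(self, codon: str) -> str:
        """Translate one codon; ambiguous or partial codons give 'X'."""
        return self._map.get(codon, "X")

    def __getitem__(self, codon: str) -> str:
        return self.translate_codon(codon)
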
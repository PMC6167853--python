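"""
Optimal pairwise sequence alignment by dynamic programming.

Global (Needleman-Wunsch) and local (Smith-Waterman) alignment with linear
or affine (Gotoh three-state) gap penalties.  Scoring goes through a
:class:`SubstitutionMatrix`, a 2-D integer table indexed directly by the
symbol-code pair of the two aligned symbols — alignment therefore never
touches the symbols themselves and works across sequence types, including
two sequences over *different* alphabets as long as the matrix's alphabets
fit them.

Gap penalties are non-positive score contributions: the first column of a
gap run contributes the *open* penalty, each further column the *extend*
penalty; the linear model is the special case ``open == extend``.  A
single integer selects the dedicated linear-gap kernel, an
``(open, extend)`` pair the affine kernel (also when the two are equal,
which makes the equivalence of the two kernels testable).

An :class:`Alignment` stores the *trace*: an L x 2 table of indices into
the source sequences, -1 denoting a gap.
"""

from __future__ import annotations

from importlib import resources
from typing import Union

import numpy as np

from .sequence import Alphabet, AlphabetError, ProteinSequence, Sequence

__all__ = [
    "SubstitutionMatrix",
    "Alignment",
    "align_global",
    "align_local",
    "load_substitution_matrix",
    "list_bundled_matrices",
    "score_of",
]

_NEG_INF = np.iinfo(np.int64).min // 4  # safe -infinity for integer DP

BUNDLED_MATRICES = (
    "BLOSUM45", "BLOSUM50", "BLOSUM62", "BLOSUM80", "BLOSUM90",
    "PAM30", "PAM70", "PAM250",
)


class SubstitutionMatrix:
    """
    Similarity scores for symbol pairs, indexed by symbol codes.

    Parameters
    ----------
    alphabet1, alphabet2 : Alphabet
        Row and column alphabets; they may differ, enabling alignment of
        unequal sequence types.
    scores : ndarray of shape (len(alphabet1), len(alphabet2)) or dict
        Integer score table, or a mapping ``(symbol1, symbol2) -> score``
        (missing pairs default to 0).
    """

    def __init__(self, alphabet1: Alphabet, alphabet2: Alphabet, scores) -> None:
        self._alph1 = alphabet1
        self._alph2 = alphabet2
        if isinstance(scores, dict):
            table = np.zeros((len(alphabet1), len(alphabet2)), dtype=np.int32)
            for (s1, s2), value in scores.items():
                table[alphabet1.encode(s1), alphabet2.encode(s2)] = value
        else:
            table = np.asarray(scores, dtype=np.int32)
            if table.shape != (len(alphabet1), len(alphabet2)):
                raise ValueError(
                    f"Score table shape {table.shape} does not match "
                    f"alphabet sizes ({len(alphabet1)}, {len(alphabet2)})"
                )
        self._scores = table
        self._scores.setflags(write=False)

    @property
    def alphabet1(self) -> Alphabet:
        return self._alph1

    @property
    def alphabet2(self) -> Alphabet:
        return self._alph2

    @property
    def scores(self) -> np.ndarray:
        return self._scores

    def get_score(self, symbol1, symbol2) -> int:
        return int(
            self._scores[self._alph1.encode(symbol1), self._alph2.encode(symbol2)]
        )

    def is_symmetric(self) -> bool:
        return self._alph1 == self._alph2 and np.array_equal(
            self._scores, self._scores.T
        )

    def fits(self, alphabet1: Alphabet, alphabet2: Alphabet) -> bool:
        """Whether the matrix alphabets equal or extend the given ones."""
        return self._alph1.extends(alphabet1) and self._alph2.extends(alphabet2)

    @classmethod
    def identity(
        cls, alphabet: Alphabet, match: int = 1, mismatch: int = 0
    ) -> "SubstitutionMatrix":
        n = len(alphabet)
        table = np.full((n, n), mismatch, dtype=np.int32)
        np.fill_diagonal(table, match)
        return cls(alphabet, alphabet, table)

    def __repr__(self) -> str:
        return (
            f"SubstitutionMatrix({len(self._alph1)}x{len(self._alph2)})"
        )


def _parse_ncbi_matrix(text: str):
    """Parse NCBI substitution-matrix text into (symbols, score table)."""
    header: list[str] | None = None
    rows: dict[str, list[int]] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].rstrip()
        if not line.strip():
            continue
        fields = line.split()
        if header is None:
            header = fields
            continue
        symbol, values = fields[0], fields[1:]
        if len(values) != len(header):
            raise ValueError(
                f"Line {lineno}: expected {len(header)} scores for row "
                f"{symbol!r}, got {len(values)}"
            )
        try:
            rows[symbol] = [int(v) for v in values]
        except ValueError:
            raise ValueError(
                f"Line {lineno}: non-integer score in row {symbol!r}"
            ) from None
    if header is None or not rows:
        raise ValueError("No matrix data found in text")
    if set(rows) != set(header):
        raise ValueError("Row symbols do not match header symbols")
    table = np.array([rows[s] for s in header], dtype=np.int32)
    return header, table


def list_bundled_matrices() -> tuple:
    return BUNDLED_MATRICES


def load_substitution_matrix(name_or_text: str) -> SubstitutionMatrix:
    """
    Load a substitution matrix.

    `name_or_text` is either the name of a bundled standard NCBI matrix
    (e.g. ``"BLOSUM62"``) or raw NCBI-format matrix text.  Bundled
    matrices are returned over the protein alphabet (rows/columns
    re-indexed accordingly); raw text keeps its own symbol order.
    """
    if "\n" not in name_or_text:
        name = name_or_text.upper()
        if name not in BUNDLED_MATRICES:
            raise ValueError(
                f"Unknown substitution matrix {name_or_text!r}; bundled "
                f"matrices: {', '.join(BUNDLED_MATRICES)}"
            )
        text = (
            resources.files("atomseq").joinpath(f"data/{name}.mat").read_text()
        )
        symbols, table = _parse_ncbi_matrix(text)
        index = {s: i for i, s in enumerate(symbols)}
        alph = ProteinSequence.alphabet
        sel = np.array([index[s] for s in alph], dtype=np.intp)
        return SubstitutionMatrix(alph, alph, table[np.ix_(sel, sel)])
    symbols, table = _parse_ncbi_matrix(name_or_text)
    alph = Alphabet(symbols)
    return SubstitutionMatrix(alph, alph, table)


class Alignment:
    """
    A pairwise alignment: the two source sequences, the trace and the
    score.  Row ``k`` of the trace gives, for each sequence, the index of
    the symbol aligned in column ``k``, or -1 for a gap.
    """

    def __init__(self, sequences, trace: np.ndarray, score: int) -> None:
        self.sequences = list(sequences)
        self.trace = np.asarray(trace, dtype=np.int64).reshape(-1, 2)
        self.score = int(score)
        self._validate()

    def _validate(self) -> None:
        trace = self.trace
        if trace.size == 0:
            return
        if ((trace < 0).sum(axis=1) > 1).any():
            raise ValueError("Alignment column with gaps in both sequences")
        for col, seq in enumerate(self.sequences):
            idx = trace[:, col]
            idx = idx[idx >= 0]
            if idx.size and (np.diff(idx) <= 0).any():
                raise ValueError("Trace indices must be strictly increasing")
            if idx.size and idx.max() >= len(seq):
                raise ValueError("Trace index exceeds sequence length")

    def __len__(self) -> int:
        return len(self.trace)

    def gapped_symbols(self, gap_char: str = "-") -> list[str]:
        """Render each sequence with gap characters inserted."""
        out = []
        for col, seq in enumerate(self.sequences):
            symbols = seq.symbols
            out.append(
                "".join(
                    gap_char if i < 0 else str(symbols[i])
                    for i in self.trace[:, col]
                )
            )
        return out

    def __str__(self) -> str:
        return "\n".join(self.gapped_symbols())

    def __repr__(self) -> str:
        return f"Alignment(score={self.score}, length={len(self)})"


GapPenalty = Union[int, tuple]


def _normalize_gap(gap_penalty: GapPenalty):
    """Return (open, extend, affine_kernel)."""
    if isinstance(gap_penalty, tuple):
        open_, extend = int(gap_penalty[0]), int(gap_penalty[1])
        affine = True
    else:
        open_ = extend = int(gap_penalty)
        affine = False
    if open_ > 0 or extend > 0:
        raise ValueError("Gap penalties must be non-positive scores")
    return open_, extend, affine


def _check_fit(seq1: Sequence, seq2: Sequence, matrix: SubstitutionMatrix):
    if not matrix.fits(seq1.alphabet, seq2.alphabet):
        raise AlphabetError(
            "Substitution matrix alphabets do not fit the sequence alphabets"
        )


# ---------------------------------------------------------------------------
# Linear-gap kernels (plain Needleman-Wunsch / Smith-Waterman)
# ---------------------------------------------------------------------------

def _nw_linear(code1, code2, scores, gap):
    n1, n2 = len(code1), len(code2)
    dp = np.empty((n1 + 1, n2 + 1), dtype=np.int64)
    dp[0, :] = gap * np.arange(n2 + 1)
    dp[:, 0] = gap * np.arange(n1 + 1)
    for i in range(1, n1 + 1):
        row_scores = scores[code1[i - 1], code2]
        prev, cur = dp[i - 1], dp[i]
        for j in range(1, n2 + 1):
            cur[j] = max(
                prev[j - 1] + row_scores[j - 1], prev[j] + gap, cur[j - 1] + gap
            )
    # Traceback, priority: diagonal > vertical (gap in seq2) > horizontal
    trace = []
    i, j = n1, n2
    while i > 0 or j > 0:
        here = dp[i, j]
        if (
            i > 0
            and j > 0
            and here == dp[i - 1, j - 1] + scores[code1[i - 1], code2[j - 1]]
        ):
            i, j = i - 1, j - 1
            trace.append((i, j))
        elif i > 0 and here == dp[i - 1, j] + gap:
            i -= 1
            trace.append((i, -1))
        else:
            j -= 1
            trace.append((-1, j))
    trace.reverse()
    return trace, int(dp[n1, n2])


def _sw_linear(code1, code2, scores, gap):
    n1, n2 = len(code1), len(code2)
    dp = np.zeros((n1 + 1, n2 + 1), dtype=np.int64)
    best, best_ij = 0, (0, 0)
    for i in range(1, n1 + 1):
        row_scores = scores[code1[i - 1], code2]
        prev, cur = dp[i - 1], dp[i]
        for j in range(1, n2 + 1):
            v = max(
                0,
                prev[j - 1] + row_scores[j - 1],
                prev[j] + gap,
                cur[j - 1] + gap,
            )
            cur[j] = v
            if v > best:
                best, best_ij = v, (i, j)
    trace = []
    i, j = best_ij
    while dp[i, j] > 0:
        here = dp[i, j]
        if (
            i > 0
            and j > 0
            and here == dp[i - 1, j - 1] + scores[code1[i - 1], code2[j - 1]]
        ):
            i, j = i - 1, j - 1
            trace.append((i, j))
        elif i > 0 and here == dp[i - 1, j] + gap:
            i -= 1
            trace.append((i, -1))
        else:
            j -= 1
            trace.append((-1, j))
    trace.reverse()
    return trace, int(best)


# ---------------------------------------------------------------------------
# Affine-gap kernels (Gotoh three-state recursion)
# ---------------------------------------------------------------------------
# State M ends in an aligned pair, state V in a gap in seq2 (consuming
# seq1, a "vertical" step), state H in a gap in seq1 ("horizontal").
# Opening a run costs `open_`, each further column `extend`.

def _gotoh_global(code1, code2, scores, open_, extend):
    n1, n2 = len(code1), len(code2)
    M = np.full((n1 + 1, n2 + 1), _NEG_INF, dtype=np.int64)
    V = np.full((n1 + 1, n2 + 1), _NEG_INF, dtype=np.int64)
    H = np.full((n1 + 1, n2 + 1), _NEG_INF, dtype=np.int64)
    M[0, 0] = 0
    for i in range(1, n1 + 1):
        V[i, 0] = open_ + (i - 1) * extend
    for j in range(1, n2 + 1):
        H[0, j] = open_ + (j - 1) * extend
    for i in range(1, n1 + 1):
        row_scores = scores[code1[i - 1], code2]
        for j in range(1, n2 + 1):
            diag = max(M[i - 1, j - 1], V[i - 1, j - 1], H[i - 1, j - 1])
            M[i, j] = diag + row_scores[j - 1]
            V[i, j] = max(
                M[i - 1, j] + open_, V[i - 1, j] + extend, H[i - 1, j] + open_
            )
            H[i, j] = max(
                M[i, j - 1] + open_, H[i, j - 1] + extend, V[i, j - 1] + open_
            )
    # pick final state, priority M > V > H
    i, j = n1, n2
    score = int(max(M[i, j], V[i, j], H[i, j]))
    state = (
        "M" if M[i, j] == score else ("V" if V[i, j] == score else "H")
    )
    trace = []
    while i > 0 or j > 0:
        if state == "M":
            i, j = i - 1, j - 1
            trace.append((i, j))
            prev = max(M[i, j], V[i, j], H[i, j])
            state = "M" if M[i, j] == prev else ("V" if V[i, j] == prev else "H")
        elif state == "V":
            here = V[i, j]
            i -= 1
            trace.append((i, -1))
            if here == M[i, j] + open_:
                state = "M"
            elif here == V[i, j] + extend:
                state = "V"
            else:
                state = "H"
        else:
            here = H[i, j]
            j -= 1
            trace.append((-1, j))
            if here == M[i, j] + open_:
                state = "M"
            elif here == H[i, j] + extend:
                state = "H"
            else:
                state = "V"
    trace.reverse()
    return trace, score


def _gotoh_local(code1, code2, scores, open_, extend):
    n1, n2 = len(code1), len(code2)
    M = np.full((n1 + 1, n2 + 1), _NEG_INF, dtype=np.int64)
    V = np.full((n1 + 1, n2 + 1), _NEG_INF, dtype=np.int64)
    H = np.full((n1 + 1, n2 + 1), _NEG_INF, dtype=np.int64)
    M[0, :] = 0
    M[:, 0] = 0
    best, best_ij = 0, (0, 0)
    for i in range(1, n1 + 1):
        row_scores = scores[code1[i - 1], code2]
        for j in range(1, n2 + 1):
            diag = max(M[i - 1, j - 1], V[i - 1, j - 1], H[i - 1, j - 1])
            m = diag + row_scores[j - 1]
            M[i, j] = max(m, 0)
            V[i, j] = max(
                M[i - 1, j] + open_, V[i - 1, j] + extend, H[i - 1, j] + open_
            )
            H[i, j] = max(
                M[i, j - 1] + open_, H[i, j - 1] + extend, V[i, j - 1] + open_
            )
            if M[i, j] > best:
                best, best_ij = int(M[i, j]), (i, j)
    trace = []
    i, j = best_ij
    state = "M"
    while (i > 0 or j > 0) and not (state == "M" and M[i, j] == 0):
        if state == "M":
            # M[i,j] > 0 here, so it came from the diagonal
            i, j = i - 1, j - 1
            trace.append((i, j))
            prev = max(M[i, j], V[i, j], H[i, j])
            state = "M" if M[i, j] == prev else ("V" if V[i, j] == prev else "H")
        elif state == "V":
            here = V[i, j]
            i -= 1
            trace.append((i, -1))
            if here == M[i, j] + open_:
                state = "M"
            elif here == V[i, j] + extend:
                state = "V"
            else:
                state = "H"
        else:
            here = H[i, j]
            j -= 1
            trace.append((-1, j))
            if here == M[i, j] + open_:
                state = "M"
            elif here == H[i, j] + extend:
                state = "H"
            else:
                state = "V"
    trace.reverse()
    return trace, best


def align_global(
    seq1: Sequence,
    seq2: Sequence,
    matrix: SubstitutionMatrix,
    gap_penalty: GapPenalty = -10,
) -> Alignment:
    """
    Optimal global alignment (Needleman-Wunsch; Gotoh three-state
    recursion for affine gaps).  Terminal gaps are penalized like
    internal ones.  One optimal alignment is returned, with deterministic
    tie-breaking: diagonal > gap in seq2 > gap in seq1.
    """
    _check_fit(seq1, seq2, matrix)
    open_, extend, affine = _normalize_gap(gap_penalty)
    code1 = np.asarray(seq1.code, dtype=np.intp)
    code2 = np.asarray(seq2.code, dtype=np.intp)
    if affine:
        trace, score = _gotoh_global(code1, code2, matrix.scores, open_, extend)
    else:
        trace, score = _nw_linear(code1, code2, matrix.scores, open_)
    return Alignment([seq1, seq2], np.array(trace).reshape(-1, 2), score)


def align_local(
    seq1: Sequence,
    seq2: Sequence,
    matrix: SubstitutionMatrix,
    gap_penalty: GapPenalty = -10,
) -> Alignment:
    """
    Optimal local alignment (Smith-Waterman).  The score is never
    negative; if no positive-scoring segment pair exists the alignment is
    empty with score 0.
    """
    _check_fit(seq1, seq2, matrix)
    open_, extend, affine = _normalize_gap(gap_penalty)
    code1 = np.asarray(seq1.code, dtype=np.intp)
    code2 = np.asarray(seq2.code, dtype=np.intp)
    if affine:
        trace, score = _gotoh_local(code1, code2, matrix.scores, open_, extend)
    else:
        trace, score = _sw_linear(code1, code2, matrix.scores, open_)
    return Alignment([seq1, seq2], np.array(trace).reshape(-1, 2), score)


def score_of(
    alignment: Alignment,
    matrix: SubstitutionMatrix,
    gap_penalty: GapPenalty,
) -> int:
    """
    Recompute an alignment's score from its trace: matrix scores over
    aligned columns plus gap penalties (first column of a gap run counts
    as open, the rest as extend).
    """
    open_, extend, _ = _normalize_gap(gap_penalty)
    seq1, seq2 = alignment.sequences
    trace = alignment.trace
    score = 0
    in_gap = [False, False]
    for i1, i2 in trace:
        if i1 >= 0 and i2 >= 0:
            score += int(matrix.scores[seq1.code[i1], seq2.code[i2]])
            in_gap = [False, False]
        elif i1 < 0:
            score += extend if in_gap[0] else open_
            in_gap = [True, False]
        else:
            score += extend if in_gap[1] else open_
            in_gap = [False, True]
    return score
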
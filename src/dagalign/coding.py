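"""Integer coding of alignment columns and their DP-cell equivalence classes.

An alignment column over N sequences is coded as an N-tuple of integers,
one per row.  If row i holds its sequence's j-th character (1-based) the
entry is ``2j - 1``; if row i holds a gap that sits between characters j
and j+1 the entry is ``2j`` (0 for a gap before the first character).
Distinguishing gaps by position keeps the column graph sparse and acyclic.

Every column lies between two dynamic-programming cells (tuples of even
integers): its *predecessor* key ``f_pred`` (entrywise ``c - c mod 2``)
and *successor* key ``f_succ`` (entrywise ``c + c mod 2``).  Column X' can
immediately precede X in an alignment iff ``f_succ(X') == f_pred(X)``, and
the original code is recovered as ``(f_pred + f_succ) / 2``.

The coarser *plus* coding maps every gap entry to 0, grouping together all
columns that contain the same non-gap characters regardless of where the
gaps sit; it underlies the column-score family of accuracy measures.
"""

from __future__ import annotations

from typing import TYPE_CHECKING, Iterable, Sequence

from .errors import CodingError, PathError

if TYPE_CHECKING:  # pragma: no cover
    from .msa_io import Alignment, SequenceRecord

ColumnCode = tuple[int, ...]
PlusCode = tuple[int, ...]
NodeKey = tuple[int, ...]

#: Cell of a column passed to :func:`encode_column`: ``("c", j)`` for the
#: row's j-th character (1-based), ``("g", j)`` for a gap after j characters
#: (``j == 0`` for a gap before the first character).
Cell = tuple[str, int]

GAP = "-"


def encode_column(cells: Sequence[Cell]) -> ColumnCode:
    """Code one column given per-row character/gap cells.

    Raises
    ------
    CodingError
        If every cell is a gap (all-gap columns have no code).
    """
    code = []
    any_char = False
    for kind, j in cells:
        if kind == "c":
            if j < 1:
                raise CodingError(f"character index must be >= 1, got {j}")
            code.append(2 * j - 1)
            any_char = True
        elif kind == "g":
            if j < 0:
                raise CodingError(f"gap offset must be >= 0, got {j}")
            code.append(2 * j)
        else:
            raise CodingError(f"unknown cell kind {kind!r}")
    if not any_char:
        raise CodingError("all-gap column cannot be coded")
    return tuple(code)


def f_pred(code: ColumnCode) -> NodeKey:
    """Predecessor DP cell: entrywise ``c - c mod 2``."""
    return tuple(c - (c % 2) for c in code)


def f_succ(code: ColumnCode) -> NodeKey:
    """Successor DP cell: entrywise ``c + c mod 2``."""
    return tuple(c + (c % 2) for c in code)


def plus_code(code: ColumnCode) -> PlusCode:
    """Gap-agnostic image of a code: odd entries kept, even entries -> 0."""
    return tuple(c if c % 2 else 0 for c in code)


def source_key(lengths: Sequence[int]) -> NodeKey:
    """DP cell before the first column: all zeros."""
    return tuple(0 for _ in lengths)


def sink_key(lengths: Sequence[int]) -> NodeKey:
    """DP cell after the last column: ``(2*L_1, ..., 2*L_N)``."""
    return tuple(2 * n for n in lengths)


def encode_alignment(alignment: "Alignment") -> tuple[ColumnCode, ...]:
    """Code every column of a gapped alignment, in column order.

    The implicit source ``(0,...,0)`` and sink ``(2L_1,...,2L_N)`` cells are
    not included; obtain them from :func:`source_key` / :func:`sink_key`.
    """
    consumed = [0] * len(alignment.rows)
    codes = []
    for col in range(alignment.length):
        cells: list[Cell] = []
        for i, row in enumerate(alignment.rows):
            ch = row[col]
            if ch == GAP:
                cells.append(("g", consumed[i]))
            else:
                consumed[i] += 1
                cells.append(("c", consumed[i]))
        codes.append(encode_column(cells))
    return tuple(codes)


def is_adjacent(prev: ColumnCode, nxt: ColumnCode) -> bool:
    """True iff *prev* may immediately precede *nxt* on a path."""
    return f_succ(prev) == f_pred(nxt)


def decode_path(
    codes: Iterable[ColumnCode], sequences: Sequence["SequenceRecord"]
) -> "Alignment":
    """Rebuild the gapped alignment a source-to-sink code path represents.

    Raises
    ------
    PathError
        If consecutive codes are not adjacent, or the path does not start
        at the source cell and end at the sink cell.
    """
    from .msa_io import Alignment  # local import to avoid a cycle

    codes = list(codes)
    lengths = [len(s.residues) for s in sequences]
    if not codes:
        raise PathError("empty code path")
    if f_pred(codes[0]) != source_key(lengths):
        raise PathError(f"path does not start at the source: {codes[0]}")
    if f_succ(codes[-1]) != sink_key(lengths):
        raise PathError(f"path does not end at the sink: {codes[-1]}")
    for a, b in zip(codes, codes[1:]):
        if not is_adjacent(a, b):
            raise PathError(f"adjacency violated between {a} and {b}")
    rows = []
    for i, seq in enumerate(sequences):
        chars = []
        for code in codes:
            c = code[i]
            if c % 2:  # character 2j-1 -> residue j
                chars.append(seq.residues[(c + 1) // 2 - 1])
            else:
                chars.append(GAP)
        row = "".join(chars)
        if row.replace(GAP, "") != seq.residues:
            raise PathError(f"decoded row {seq.id!r} does not reproduce its sequence")
        rows.append(row)
    return Alignment(ids=tuple(s.id for s in sequences), rows=tuple(rows))
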
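"""Reading and writing the formats the tool touches.

Aligned FASTA for individual alignments, a concatenated multi-MSA FASTA
container for alignment sample dumps (a new block starts whenever the first
block's first id recurs), Newick for candidate trees, and a TSV table of
per-column posterior annotations for summary outputs.

Gap characters '-' and '.' are both accepted on input and written as '-';
residues are upper-cased.  Columns consisting entirely of gaps are dropped
with a warning: such columns have no code and cannot appear in the column
graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO

from .errors import ConsistencyError, ContractError, FormatError

GAP = "-"
_GAP_CHARS = "-."


@dataclass(frozen=True)
class SequenceRecord:
    """A named ungapped sequence."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ContractError("sequence id must be non-empty")
        if any(g in self.residues for g in _GAP_CHARS):
            raise ContractError(f"sequence {self.id!r} contains gap characters")


@dataclass(frozen=True)
class Alignment:
    """A global multiple sequence alignment: equal-length gapped rows."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ContractError("ids and rows differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise ContractError("duplicate sequence ids")
        if not self.rows:
            raise ContractError("alignment has no rows")
        length = len(self.rows[0])
        for sid, row in zip(self.ids, self.rows):
            if len(row) != length:
                raise FormatError(
                    f"row {sid!r} has length {len(row)}, expected {length}"
                )

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def sequences(self) -> tuple[SequenceRecord, ...]:
        """The ungapped sequences, in row order."""
        return tuple(
            SequenceRecord(sid, row.replace(GAP, ""))
            for sid, row in zip(self.ids, self.rows)
        )

    def reordered(self, ids: Sequence[str]) -> "Alignment":
        """Rows permuted into the given id order."""
        index = {sid: i for i, sid in enumerate(self.ids)}
        try:
            perm = [index[sid] for sid in ids]
        except KeyError as exc:
            raise ConsistencyError(f"id {exc.args[0]!r} missing from alignment")
        if len(ids) != len(self.ids):
            raise ConsistencyError("id sets differ in size")
        return Alignment(
            ids=tuple(self.ids[i] for i in perm),
            rows=tuple(self.rows[i] for i in perm),
        )


@dataclass
class SampleSet:
    """An ordered multiset of alignments of the same sequences.

    Duplicate alignments are retained with their multiplicity: when the
    samples come from an MCMC run, each replica counts as an independent
    draw when estimating marginal probabilities.  Optional non-negative
    per-alignment weights replace the uniform 1/n frequency weighting.
    """

    alignments: list[Alignment]
    sequences: tuple[SequenceRecord, ...]
    weights: Optional[list[float]] = field(default=None)

    def __post_init__(self) -> None:
        if not self.alignments:
            raise ContractError("SampleSet must contain at least one alignment")
        if self.weights is not None:
            if len(self.weights) != len(self.alignments):
                raise ContractError("one weight per alignment required")
            if any(w < 0 for w in self.weights):
                raise ContractError("weights must be non-negative")
        expected = {s.id: s.residues for s in self.sequences}
        for k, aln in enumerate(self.alignments):
            if set(aln.ids) != set(expected):
                raise ConsistencyError(f"sample {k} has a different id set")
            for rec in aln.sequences():
                if rec.residues != expected[rec.id]:
                    raise ConsistencyError(
                        f"sample {k}, id {rec.id!r}: de-gapped residues differ "
                        "from the shared sequence set"
                    )

    def __len__(self) -> int:
        return len(self.alignments)

    @classmethod
    def from_alignments(
        cls, alignments: Iterable[Alignment], weights: Optional[Sequence[float]] = None
    ) -> "SampleSet":
        """Build a SampleSet, canonicalising row order to the first sample's."""
        alns = list(alignments)
        if not alns:
            raise ContractError("no alignments supplied")
        ids = alns[0].ids
        alns = [a if a.ids == ids else a.reordered(ids) for a in alns]
        return cls(
            alignments=alns,
            sequences=alns[0].sequences(),
            weights=list(weights) if weights is not None else None,
        )


def _sanitise(ids: Sequence[str], rows: Sequence[str], origin: str) -> Alignment:
    """Normalise gaps/case and drop all-gap columns (with a warning)."""
    rows = [row.upper().replace(".", GAP) for row in rows]
    length = len(rows[0])
    for sid, row in zip(ids, rows):
        if len(row) != length:
            raise FormatError(
                f"{origin}: record {sid!r} has length {len(row)}, expected {length}"
            )
    keep = [i for i in range(length) if any(row[i] != GAP for row in rows)]
    if len(keep) < length:
        warnings.warn(
            f"{origin}: dropped {length - len(keep)} all-gap column(s)",
            stacklevel=2,
        )
        rows = ["".join(row[i] for i in keep) for row in rows]
    return Alignment(ids=tuple(ids), rows=tuple(rows))


def read_alignment(path: str | Path) -> Alignment:
    """Read one aligned-FASTA file.

    Raises :class:`FormatError` for empty files or rows of unequal length
    (naming the offending record).
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return _sanitise(
        [r.id for r in records], [str(r.seq) for r in records], str(path)
    )


def _iter_blocks(path: Path) -> Iterator[list]:
    """Split a concatenated multi-MSA FASTA into blocks.

    A new block starts whenever an id recurs within the current block
    (for samples written in a fixed row order this is exactly the
    recurrence of the first id; it also tolerates blocks with permuted
    row order).
    """
    block: list = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            yield block
            block, seen = [], set()
        block.append(rec)
        seen.add(rec.id)
    if block:
        yield block


def read_sample_set(path: str | Path) -> SampleSet:
    """Read a directory of aligned FASTA files, or one concatenated file.

    Directory entries are read in sorted name order; block/file order is
    preserved and duplicates are retained (multiset semantics).  Row order
    is canonicalised to the first sample's id order.
    """
    path = Path(path)
    alignments: list[Alignment] = []
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.is_file())
        if not files:
            raise FormatError(f"{path}: directory contains no files")
        for f in files:
            alignments.append(read_alignment(f))
    else:
        for k, block in enumerate(_iter_blocks(path)):
            alignments.append(
                _sanitise(
                    [r.id for r in block],
                    [str(r.seq) for r in block],
                    f"{path} block {k}",
                )
            )
        if not alignments:
            raise FormatError(f"{path}: no FASTA records found")
    return SampleSet.from_alignments(alignments)


def write_alignment(alignment: Alignment, path: str | Path) -> None:
    """Write an alignment as aligned FASTA."""
    with open(path, "w") as fh:
        for sid, row in zip(alignment.ids, alignment.rows):
            fh.write(f">{sid}\n{row}\n")


ANNOTATION_COLUMNS = ("index", "code", "p_C", "p_Cplus", "count")


def write_summary(
    alignment: Alignment,
    annotations: pd.DataFrame,
    fasta_path: str | Path,
    tsv_path: str | Path,
) -> None:
    """Write a summary alignment plus its per-column annotation table.

    *annotations* must have one row per alignment column with columns
    ``code`` (comma-joined integer tuple), ``p_C``, ``p_Cplus``, ``count``.
    """
    if len(annotations) != alignment.length:
        raise ContractError(
            f"{len(annotations)} annotation rows for a "
            f"{alignment.length}-column alignment"
        )
    write_alignment(alignment, fasta_path)
    out = annotations.copy()
    out.insert(0, "index", range(len(out)))
    out = out[list(ANNOTATION_COLUMNS)]
    out.to_csv(tsv_path, sep="\t", index=False)


def read_trees(
    path: str | Path, sequence_ids: Optional[Sequence[str]] = None
) -> list[dendropy.Tree]:
    """Read a Newick file of trees (one per line, branch lengths required).

    All trees share one taxon namespace.  If *sequence_ids* is given, leaf
    labels must match it exactly.
    """
    trees = dendropy.TreeList.get(path=str(path), schema="newick")
    if not trees:
        raise FormatError(f"{path}: no trees found")
    out = []
    for k, tree in enumerate(trees):
        labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
        if sequence_ids is not None and labels != sorted(sequence_ids):
            raise ConsistencyError(
                f"{path} tree {k}: leaf labels {labels} do not match the "
                f"sequence ids"
            )
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise FormatError(f"{path} tree {k}: missing branch length")
        out.append(tree)
    return out


def code_to_str(code: tuple[int, ...]) -> str:
    """Serialise a column code as a comma-joined integer tuple, e.g. '3,2'."""
    return ",".join(str(c) for c in code)


def str_to_code(text: str) -> tuple[int, ...]:
    return tuple(int(t) for t in text.split(","))
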
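"""The alignment column DAG.

Nodes are coded columns observed across a multiset of sampled alignments;
a directed edge runs from X' to X iff ``f_succ(X') == f_pred(X)``.  Edges
are never stored explicitly: each column records only its predecessor and
successor equivalence class (the DP cells flanking it), so storage is
linear in the number of observed columns and every dynamic program runs in
linear time via per-class partial sums.  Each equivalence class has at
most ``2^N - 1`` members (each row is gap or character, all-gap excluded).

Every source-to-sink path through the DAG is a valid global alignment of
the same sequences; interchanges (a shared column with different
neighbours in two samples) and crossovers (two samples meeting at a DP
cell without sharing a column) make the number of encoded alignments grow
far faster than the number of samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterator, Optional

import numpy as np

from .coding import (
    ColumnCode,
    NodeKey,
    PlusCode,
    encode_alignment,
    f_pred,
    f_succ,
    plus_code,
    sink_key,
    source_key,
)
from .errors import ContractError, DagAlignError, SizeError
from .msa_io import SampleSet, SequenceRecord

if TYPE_CHECKING:  # pragma: no cover
    from .marginals import MarginalTable

#: Virtual endpoint used as the partner in boundary pair counts:
#: ``(None, X)`` counts alignments starting with X, ``(X, None)`` those
#: ending with X.  Virtual source/sink columns are never materialised.
BOUNDARY = None


@dataclass
class DagColumn:
    """One observed column with its multiset count and flanking DP cells."""

    code: ColumnCode
    count: float
    pred_key: NodeKey
    succ_key: NodeKey
    plus: PlusCode


@dataclass
class ClassIndex:
    """Columns incident to one DP cell.

    ``in_members``: columns whose successor class is this cell (they can
    precede anything leaving the cell).  ``out_members``: columns whose
    predecessor class is this cell.
    """

    in_members: list[ColumnCode] = field(default_factory=list)
    out_members: list[ColumnCode] = field(default_factory=list)


@dataclass
class AlignmentDAG:
    columns: dict[ColumnCode, DagColumn]
    classes: dict[NodeKey, ClassIndex]
    pair_counts: dict[tuple[Optional[ColumnCode], Optional[ColumnCode]], float]
    n_samples: float
    source: NodeKey
    sink: NodeKey
    sequences: tuple[SequenceRecord, ...]

    def observed_successors(self, code: Optional[ColumnCode]) -> list[ColumnCode]:
        """Columns seen immediately after *code* (source if None) in a sample."""
        return [
            b
            for (a, b) in self.pair_counts
            if a == code and b is not BOUNDARY
        ]

    def successors(self, code: ColumnCode) -> list[ColumnCode]:
        """All columns reachable in one step (crossovers allowed)."""
        return list(self.classes[self.columns[code].succ_key].out_members)


def build_dag(samples: SampleSet) -> AlignmentDAG:
    """Combine a validated sample set into an alignment column DAG.

    Column counts are multiset occurrence totals (or summed weights when
    the sample set carries weights); pair counts record every observed
    adjacency including the virtual source/sink boundaries.
    """
    if not samples.alignments:
        raise ContractError("empty SampleSet")
    lengths = [len(s.residues) for s in samples.sequences]
    src, snk = source_key(lengths), sink_key(lengths)
    if samples.weights is not None:
        total = float(sum(samples.weights))
        if total <= 0:
            raise ContractError("weights sum to zero")
        weights = [w for w in samples.weights]
    else:
        total = len(samples.alignments)
        weights = [1] * len(samples.alignments)

    columns: dict[ColumnCode, DagColumn] = {}
    pair_counts: dict[tuple, float] = {}
    for aln, w in zip(samples.alignments, weights):
        codes = encode_alignment(aln)
        for code in codes:
            col = columns.get(code)
            if col is None:
                columns[code] = DagColumn(
                    code=code,
                    count=w,
                    pred_key=f_pred(code),
                    succ_key=f_succ(code),
                    plus=plus_code(code),
                )
            else:
                col.count += w
        for pair in zip((BOUNDARY, *codes), (*codes, BOUNDARY)):
            pair_counts[pair] = pair_counts.get(pair, 0) + w

    classes: dict[NodeKey, ClassIndex] = {}
    for code, col in columns.items():
        classes.setdefault(col.pred_key, ClassIndex()).out_members.append(code)
        classes.setdefault(col.succ_key, ClassIndex()).in_members.append(code)
    for idx in classes.values():
        idx.in_members.sort()
        idx.out_members.sort()

    return AlignmentDAG(
        columns=columns,
        classes=classes,
        pair_counts=pair_counts,
        n_samples=total,
        source=src,
        sink=snk,
        sequences=samples.sequences,
    )


def topological_classes(dag: AlignmentDAG) -> list[NodeKey]:
    """DP cells in a valid topological order.

    Coordinate sums strictly increase along every edge, so sorting by
    (coordinate sum, lexicographic key) is a reproducible topological
    order without any graph traversal.
    """
    return sorted(dag.classes, key=lambda k: (sum(k), k))


def _column_topo_order(dag: AlignmentDAG) -> list[ColumnCode]:
    """Columns ordered so that every predecessor precedes its successors."""
    order = []
    for key in topological_classes(dag):
        order.extend(dag.classes[key].out_members)
    return order


def count_paths(dag: AlignmentDAG, allow_crossovers: bool = True) -> int:
    """Exact number of distinct source-to-sink paths (arbitrary precision).

    With crossovers allowed every class-adjacent column pair is
    traversable; otherwise only adjacencies observed in the input samples
    (``pair_counts``) are.
    """
    if allow_crossovers:
        reaching: dict[ColumnCode, int] = {}
        for key in topological_classes(dag):
            idx = dag.classes[key]
            if key == dag.source:
                s = 1
            else:
                s = sum(reaching[c] for c in idx.in_members)
            for c in idx.out_members:
                reaching[c] = s
        if dag.sink not in dag.classes:
            return 0
        return sum(reaching[c] for c in dag.classes[dag.sink].in_members)

    reaching = {}
    for code in _column_topo_order(dag):
        n = 1 if (BOUNDARY, code) in dag.pair_counts else 0
        key = dag.columns[code].pred_key
        if key in dag.classes:
            n += sum(
                reaching.get(prev, 0)
                for prev in dag.classes[key].in_members
                if (prev, code) in dag.pair_counts
            )
        reaching[code] = n
    return sum(
        reaching.get(code, 0)
        for (code, b) in dag.pair_counts
        if b is BOUNDARY and code is not BOUNDARY
    )


def enumerate_paths(
    dag: AlignmentDAG, allow_crossovers: bool = True, cap: int = 10_000
) -> list[tuple[ColumnCode, ...]]:
    """All distinct source-to-sink paths, as code sequences.

    Raises :class:`SizeError` (reporting the exact count) if the DAG
    contains more than *cap* paths.
    """
    n = count_paths(dag, allow_crossovers)
    if n > cap:
        raise SizeError(f"DAG contains {n} paths, more than the cap of {cap}")

    paths: list[tuple[ColumnCode, ...]] = []

    def starts() -> Iterator[ColumnCode]:
        if allow_crossovers:
            yield from dag.classes[dag.source].out_members
        else:
            yield from sorted(dag.observed_successors(BOUNDARY))

    def nexts(code: ColumnCode) -> Iterator[ColumnCode]:
        if allow_crossovers:
            yield from dag.successors(code)
        else:
            yield from sorted(dag.observed_successors(code))

    def ends_here(code: ColumnCode) -> bool:
        if allow_crossovers:
            return dag.columns[code].succ_key == dag.sink
        return (code, BOUNDARY) in dag.pair_counts

    stack: list[ColumnCode] = []

    def walk(code: ColumnCode) -> None:
        stack.append(code)
        if ends_here(code):
            paths.append(tuple(stack))
        if dag.columns[code].succ_key != dag.sink:
            for nxt in nexts(code):
                walk(nxt)
        stack.pop()

    for first in starts():
        walk(first)
    return paths


def sample_path(
    dag: AlignmentDAG,
    weights: "MarginalTable",
    mode: str = "meanfield",
    seed: int | np.random.Generator = 0,
) -> tuple[ColumnCode, ...]:
    """Draw one source-to-sink path from the factored distribution.

    This is a stochastic traceback run forwards: because the factored
    conditionals out of every DP cell (mean-field mode) or out of every
    column (pair mode) sum to one, sequential sampling of the conditionals
    draws a path with probability exactly equal to its factored
    probability.  Deterministic given the seed.
    """
    from .marginals import meanfield_conditional  # noqa: F401  (doc reference)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    path: list[ColumnCode] = []
    if mode == "meanfield":
        key = dag.source
        while key != dag.sink:
            members = dag.classes[key].out_members
            probs = np.array([dag.columns[c].count for c in members], dtype=float)
            probs /= probs.sum()
            code = members[rng.choice(len(members), p=probs)]
            path.append(code)
            key = dag.columns[code].succ_key
    elif mode == "pair":
        succ_table: dict = {}
        for (a, b), w in dag.pair_counts.items():
            succ_table.setdefault(a, []).append((b, w))
        prev: Optional[ColumnCode] = BOUNDARY
        while True:
            options = succ_table.get(prev, [])
            if not options:
                raise DagAlignError(
                    f"column {prev} has no observed successor"
                )  # impossible by construction for DAGs built from samples
            options.sort(key=lambda t: (t[0] is BOUNDARY, t[0]))
            probs = np.array([w for _, w in options], dtype=float)
            probs /= probs.sum()
            nxt = options[rng.choice(len(options), p=probs)][0]
            if nxt is BOUNDARY:
                break
            path.append(nxt)
            prev = nxt
    else:
        raise ContractError(f"unknown mode {mode!r}")
    return tuple(path)


def dag_stats(dag: AlignmentDAG) -> dict:
    """Size and shape statistics of the DAG.

    ``mean_in_degree`` is the ratio |columns| / |classes| (the density
    factor d-bar, satisfying |columns| = mean_in_degree x n_classes by
    construction); ``mean_class_size`` averages membership over
    predecessor classes; ``max_class_size`` is the largest P- or S-class,
    the quantity bounded by ``2^N - 1``.
    """
    n_columns = len(dag.columns)
    n_classes = len(dag.classes)
    pred_classes = [k for k, idx in dag.classes.items() if idx.out_members]
    sizes = [
        max(len(idx.in_members), len(idx.out_members))
        for idx in dag.classes.values()
    ]
    return {
        "n_columns": n_columns,
        "n_classes": n_classes,
        "mean_in_degree": n_columns / n_classes,
        "mean_class_size": (
            n_columns / len(pred_classes) if pred_classes else 0.0
        ),
        "max_class_size": max(sizes) if sizes else 0,
        "n_samples": dag.n_samples,
    }


def to_dot(dag: AlignmentDAG) -> str:
    """GraphViz DOT rendering of a small DAG (debugging aid)."""
    from .msa_io import code_to_str

    lines = ["digraph alignment_dag {", "  rankdir=LR;"]
    for code, col in sorted(dag.columns.items()):
        lines.append(
            f'  "{code_to_str(code)}" [label="{code_to_str(code)}\\n'
            f'n={col.count}"];'
        )
    for code, col in sorted(dag.columns.items()):
        for nxt in dag.successors(code):
            observed = (code, nxt) in dag.pair_counts
            style = "solid" if observed else "dashed"
            lines.append(
                f'  "{code_to_str(code)}" -> "{code_to_str(nxt)}" '
                f"[style={style}];"
            )
    lines.append("}")
    return "\n".join(lines)
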
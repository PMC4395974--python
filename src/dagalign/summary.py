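"""Summary alignments from the DAG: MAP path and minimum-risk path.

The MAP path maximises the factored log-posterior (mean-field or pair
mode) by a max-sum DP over the DAG.  The minimum-risk summary minimises
the posterior expected loss for column-additive loss functions: up to a
constant, the risk of an alignment is the sum over its columns of
``g - p_f(X)``, where ``p_f`` is the column marginal (C mapping) or the
gap-agnostic grouped marginal (C+ mapping) and ``g = lambda_FP /
(rho_TP + lambda_FP)`` penalises longer alignments in proportion to the
penalty on false positives.  Minimising the risk is a maximum-weight-path
problem with column weight ``p_f(X) - g``, solved in time linear in the
number of DAG columns via per-class partial maxima; crossovers are always
allowed because the risk is additive over columns.

Ties between equal-scoring predecessors are broken towards the
lexicographically smallest column code, so results are deterministic;
exact ties do occur in practice (distinct paths can share a C+ score).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import pandas as pd

from .coding import ColumnCode, decode_path
from .dag import BOUNDARY, AlignmentDAG, topological_classes, _column_topo_order
from .errors import ContractError, DagAlignError
from .marginals import MarginalTable, meanfield_conditional
from .msa_io import Alignment, code_to_str


@dataclass(frozen=True)
class LossConfig:
    """Column-additive loss family.

    mapping: "C" scores exact columns (gap positions distinguished),
    "Cplus" scores the gap-agnostic image.  g in [0, 1] is the
    false-positive penalty; g = 0.5 (the default) penalises false
    positives and false negatives equally and is a good all-round
    setting.  column_weight optionally scales the per-column loss (e.g.
    by the number of non-gap characters).
    """

    mapping: str = "Cplus"
    g: float = 0.5
    column_weight: Optional[Callable[[ColumnCode], float]] = None

    def __post_init__(self) -> None:
        if self.mapping not in ("C", "Cplus"):
            raise ContractError(f"unknown mapping {self.mapping!r}")
        if not 0.0 <= self.g <= 1.0:
            raise ContractError(f"g must lie in [0, 1], got {self.g}")

    def weight(self, code: ColumnCode) -> float:
        if self.column_weight is None:
            return 1.0
        w = self.column_weight(code)
        if w <= 0:
            raise ContractError(f"column weight must be positive, got {w}")
        return w

    def p_f(self, table: MarginalTable, code: ColumnCode) -> float:
        return (
            table.p_column(code) if self.mapping == "C" else table.p_plus(code)
        )


@dataclass
class SummaryResult:
    """A summary path with its decoded alignment and per-column annotations."""

    path: tuple[ColumnCode, ...]
    alignment: Alignment
    score: float
    per_column: pd.DataFrame = field(repr=False)


def _annotations(
    path: Sequence[ColumnCode], table: MarginalTable
) -> pd.DataFrame:
    rows = [
        {
            "code": code_to_str(code),
            "p_C": table.p_column(code),
            "p_Cplus": table.p_plus(code),
            "count": table.counts[code],
        }
        for code in path
    ]
    return pd.DataFrame(rows, columns=["code", "p_C", "p_Cplus", "count"])


def _best(candidates):
    """Max by score; ties towards the lexicographically smallest code."""
    return max(candidates, key=lambda t: (t[0], tuple(-c for c in t[1])))


def map_alignment(
    dag: AlignmentDAG, table: MarginalTable, mode: str = "meanfield"
) -> SummaryResult:
    """The path maximising the factored log-posterior.

    In pair mode the optimisation runs over observed adjacencies only
    (unobserved pairs carry weight zero).
    """
    back: dict[ColumnCode, Optional[ColumnCode]] = {}
    score: dict[ColumnCode, float] = {}

    if mode == "meanfield":
        for key in topological_classes(dag):
            idx = dag.classes[key]
            if key == dag.source:
                prev_best, prev_code = 0.0, None
            elif idx.in_members:
                prev_best, prev_code = _best(
                    [(score[c], c) for c in idx.in_members]
                )
            else:  # class with no incoming columns other than source
                continue
            for code in idx.out_members:
                score[code] = prev_best + math.log(
                    meanfield_conditional(table, dag, code)
                )
                back[code] = prev_code
        final, last = _best(
            [(score[c], c) for c in dag.classes[dag.sink].in_members]
        )
    elif mode == "pair":
        for code in _column_topo_order(dag):
            candidates = []
            start = table.pair_counts.get((BOUNDARY, code), 0)
            if start:
                candidates.append((math.log(start / dag.n_samples), None))
            for prev in dag.classes[dag.columns[code].pred_key].in_members:
                pair = table.pair_counts.get((prev, code), 0)
                if pair and prev in score:
                    candidates.append(
                        (
                            score[prev] + math.log(pair / table.counts[prev]),
                            prev,
                        )
                    )
            if not candidates:
                continue
            score[code], back[code] = _best(
                [(s, c if c is not None else ()) for s, c in candidates]
            )
            if back[code] == ():
                back[code] = None
        finals = []
        for code in dag.classes[dag.sink].in_members:
            end = table.pair_counts.get((code, BOUNDARY), 0)
            if end and code in score:
                finals.append(
                    (score[code] + math.log(end / table.counts[code]), code)
                )
        if not finals:
            raise DagAlignError("no observed path reaches the sink")
        final, last = _best(finals)
    else:
        raise ContractError(f"unknown mode {mode!r}")

    path = _traceback(back, last)
    return SummaryResult(
        path=path,
        alignment=decode_path(path, dag.sequences),
        score=final,
        per_column=_annotations(path, table),
    )


def min_risk_alignment(
    dag: AlignmentDAG,
    table: MarginalTable,
    loss: LossConfig = LossConfig(),
) -> SummaryResult:
    """The path minimising the posterior risk of a column-additive loss.

    Equivalently maximises ``sum of weight(X) * (p_f(X) - g)`` over all
    source-to-sink paths, crossovers included; linear time in the number
    of DAG columns.
    """
    back: dict[ColumnCode, Optional[ColumnCode]] = {}
    score: dict[ColumnCode, float] = {}
    for key in topological_classes(dag):
        idx = dag.classes[key]
        if key == dag.source:
            prev_best, prev_code = 0.0, None
        elif idx.in_members:
            prev_best, prev_code = _best([(score[c], c) for c in idx.in_members])
        else:
            continue
        for code in idx.out_members:
            gain = loss.weight(code) * (loss.p_f(table, code) - loss.g)
            score[code] = prev_best + gain
            back[code] = prev_code
    final, last = _best([(score[c], c) for c in dag.classes[dag.sink].in_members])
    path = _traceback(back, last)
    return SummaryResult(
        path=path,
        alignment=decode_path(path, dag.sequences),
        score=final,
        per_column=_annotations(path, table),
    )


def risk_score(
    path: Sequence[ColumnCode], table: MarginalTable, loss: LossConfig = LossConfig()
) -> float:
    """Reported risk of a path: ``sum of weight(X) * (g - p_f(X))``."""
    total = 0.0
    for code in path:
        if code not in table.counts:
            raise ContractError(f"code {code} not present in the marginal table")
        total += loss.weight(code) * (loss.g - loss.p_f(table, code))
    return total


def _traceback(
    back: dict[ColumnCode, Optional[ColumnCode]], last: ColumnCode
) -> tuple[ColumnCode, ...]:
    path = [last]
    while back[path[-1]] is not None:
        path.append(back[path[-1]])
    return tuple(reversed(path))
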
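"""Marginal probabilities on the alignment DAG and factored reconstructions.

The column marginal of a coded column is the fraction of sampled
alignments containing it; the pair marginal of an adjacency is the
fraction of samples in which the two columns occur side by side.  These
drive two first-order factorisations of the alignment distribution:

* *pair* mode uses the empirical conditional ``p(X | X') = p(X', X) /
  p(X')`` and is exact for first-order HMM alignment models, but assigns
  weight zero to adjacencies never observed (no crossovers);
* *mean-field* mode replaces the conditional with an average over all
  predecessors, ``p(X) / sum of p over the columns feeding X's predecessor
  cell``, which needs only single-column marginals and makes every
  crossover path traversable.

Counts are kept as exact integers (or input weights) and turned into
probabilities lazily, so flow-conservation checks are exact.
No pseudocounts are applied anywhere: pair mode simply restricts support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .coding import ColumnCode, PlusCode, plus_code
from .dag import BOUNDARY, AlignmentDAG, topological_classes, _column_topo_order
from .errors import ContractError, SupportError
from .msa_io import code_to_str


@dataclass
class MarginalTable:
    """Column, pair and plus-grouped marginal probabilities.

    Internally stores counts (exact under uniform weighting) plus the
    total sample mass; probabilities are formed on access.
    """

    counts: dict[ColumnCode, float]
    pair_counts: dict[tuple[Optional[ColumnCode], Optional[ColumnCode]], float]
    n_samples: float
    plus_counts: dict[PlusCode, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.plus_counts:
            for code, n in self.counts.items():
                key = plus_code(code)
                self.plus_counts[key] = self.plus_counts.get(key, 0) + n

    def p_column(self, code: ColumnCode) -> float:
        return self.counts[code] / self.n_samples

    def p_pair(
        self, prev: Optional[ColumnCode], nxt: Optional[ColumnCode]
    ) -> float:
        return self.pair_counts.get((prev, nxt), 0) / self.n_samples

    def p_plus(self, code: ColumnCode) -> float:
        """Summed marginal of all columns sharing this code's plus image."""
        return self.plus_counts[plus_code(code)] / self.n_samples

    def to_frame(self) -> pd.DataFrame:
        """Per-column table with code, p_C, p_Cplus and count columns."""
        rows = [
            {
                "code": code_to_str(code),
                "p_C": self.p_column(code),
                "p_Cplus": self.p_plus(code),
                "count": n,
            }
            for code, n in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["code", "p_C", "p_Cplus", "count"])


def estimate_marginals(dag: AlignmentDAG) -> MarginalTable:
    """Empirical marginals from the DAG's multiset counts."""
    return MarginalTable(
        counts={code: col.count for code, col in dag.columns.items()},
        pair_counts=dict(dag.pair_counts),
        n_samples=dag.n_samples,
    )


def meanfield_conditional(
    table: MarginalTable, dag: AlignmentDAG, code: ColumnCode
) -> float:
    """Mean-field conditional: p(X) / sum of p over X's possible predecessors.

    For columns leaving the source cell the denominator is the total mass
    entering the source, i.e. one (every sample starts with exactly one
    such column).
    """
    key = dag.columns[code].pred_key
    if key == dag.source:
        denom = dag.n_samples
    else:
        denom = sum(table.counts[c] for c in dag.classes[key].in_members)
    return table.counts[code] / denom


def path_log_prob(
    path: Sequence[ColumnCode],
    table: MarginalTable,
    dag: AlignmentDAG,
    mode: str = "meanfield",
) -> float:
    """Log-probability of a source-to-sink path under a factorisation.

    Pair mode includes the boundary conditionals against the virtual
    source and sink, and raises :class:`SupportError` on any adjacency not
    observed in the input samples (the factorisation gives it weight
    zero).
    """
    if mode == "meanfield":
        return sum(
            math.log(meanfield_conditional(table, dag, code)) for code in path
        )
    if mode == "pair":
        logp = 0.0
        for prev, nxt in zip((BOUNDARY, *path), (*path, BOUNDARY)):
            pair = table.pair_counts.get((prev, nxt), 0)
            if pair == 0:
                raise SupportError(
                    f"adjacency ({prev}, {nxt}) not observed in the samples"
                )
            denom = dag.n_samples if prev is BOUNDARY else table.counts[prev]
            logp += math.log(pair / denom)
        return logp
    raise ContractError(f"unknown mode {mode!r}")


def total_probability(
    dag: AlignmentDAG, table: MarginalTable, mode: str = "meanfield"
) -> float:
    """Forward DP summing factored path probabilities over the whole DAG.

    Equals one (to rounding) in both modes over their respective supports,
    a direct consequence of flow conservation; exposed as a diagnostic.
    """
    if mode == "meanfield":
        mass: dict[ColumnCode, float] = {}
        for key in topological_classes(dag):
            idx = dag.classes[key]
            incoming = (
                1.0
                if key == dag.source
                else sum(mass[c] for c in idx.in_members)
            )
            for code in idx.out_members:
                mass[code] = incoming * meanfield_conditional(table, dag, code)
        return sum(mass[c] for c in dag.classes[dag.sink].in_members)
    if mode == "pair":
        mass = {}
        total = 0.0
        for code in _column_topo_order(dag):
            m = table.pair_counts.get((BOUNDARY, code), 0) / dag.n_samples
            for prev in dag.classes[dag.columns[code].pred_key].in_members:
                pair = table.pair_counts.get((prev, code), 0)
                if pair:
                    m += mass[prev] * pair / table.counts[prev]
            mass[code] = m
            end = table.pair_counts.get((code, BOUNDARY), 0)
            if end:
                total += m * end / table.counts[code]
        return total
    raise ContractError(f"unknown mode {mode!r}")


def external_mass(
    dag: AlignmentDAG,
    scorer: Callable[[Optional[ColumnCode], Optional[ColumnCode]], float],
    log_normaliser: float,
) -> float:
    """Probability mass, under a true model, of all paths in the DAG.

    *scorer* assigns a log-weight to each (predecessor, column) adjacency,
    with ``None`` standing for the virtual source (as predecessor) or the
    sink (as column); *log_normaliser* is the true total log-probability
    over all alignments.  Crossovers are always traversable.  Returns a
    value in (0, 1]: how much of the model's posterior the DAG covers.
    """
    logz: dict[ColumnCode, float] = {}
    for code in _column_topo_order(dag):
        key = dag.columns[code].pred_key
        if key == dag.source:
            logz[code] = scorer(None, code)
        else:
            terms = [
                logz[prev] + scorer(prev, code)
                for prev in dag.classes[key].in_members
            ]
            logz[code] = _logsumexp(terms)
    finals = [
        logz[code] + scorer(code, None)
        for code in dag.classes[dag.sink].in_members
    ]
    return float(np.exp(_logsumexp(finals) - log_normaliser))


def _logsumexp(terms: Sequence[float]) -> float:
    if not terms:
        return -math.inf
    m = max(terms)
    if m == -math.inf:
        return m
    return m + math.log(sum(math.exp(t - m) for t in terms))


def log_mse(estimated: Sequence[float], truth: Sequence[float]) -> float:
    """Mean squared difference between two sets of log-probabilities."""
    if len(estimated) != len(truth):
        raise ContractError(
            f"length mismatch: {len(estimated)} vs {len(truth)}"
        )
    e = np.asarray(estimated, dtype=float)
    t = np.asarray(truth, dtype=float)
    return float(np.mean((e - t) ** 2))
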
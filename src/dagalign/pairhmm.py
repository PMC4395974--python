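"""Exact affine-gap pair-HMM over two sequences.

Three emitting states: match M (emits a residue pair), insert X (emits a
residue of the first sequence against a gap) and insert Y (the mirror).
Transitions: gap open M->X/Y with probability delta each, gap extension
X->X / Y->Y with epsilon, direct gap switch X<->Y with sigma, and a
shared termination probability tau from every state; the start behaves
like M.  Setting delta = epsilon = sigma makes every state's outgoing
distribution identical, i.e. a completely site-independent
(non-affine) process.

Match emissions are the reversible joint ``pi_a P(b | a, t)`` of a
substitution model at divergence t; gap states emit the equilibrium
frequency of the single residue.

This model is the exact ground truth against which DAG-based posterior
reconstructions are judged: the forward recursion gives the total
probability over all global alignments, forward-backward gives exact
column marginals, and stochastic traceback draws i.i.d. alignments from
the exact posterior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .coding import ColumnCode, encode_alignment
from .errors import ContractError
from .msa_io import Alignment, SampleSet, SequenceRecord
from .treelik import SubstModel

_M, _X, _Y = 0, 1, 2
NEG_INF = float("-inf")


@dataclass
class PairHMMParams:
    """Affine-gap pair-HMM parameters.

    delta: gap open; epsilon: gap extend; sigma: gap switch; tau:
    termination.  substitution: the emission model; t: divergence time for
    the match joint.
    """

    delta: float = 0.05
    epsilon: float = 0.5
    sigma: float = 0.02
    tau: float = 0.01
    substitution: SubstModel = field(default_factory=lambda: SubstModel.jc())
    t: float = 1.0

    def __post_init__(self) -> None:
        for name in ("delta", "epsilon", "sigma", "tau"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ContractError(f"{name} must lie in (0, 1), got {v}")
        if 1.0 - 2 * self.delta - self.tau <= 0:
            raise ContractError("match-state transitions do not sum below 1")
        if 1.0 - self.epsilon - self.sigma - self.tau <= 0:
            raise ContractError("gap-state transitions do not sum below 1")
        m2m = 1.0 - 2 * self.delta - self.tau
        g2m = 1.0 - self.epsilon - self.sigma - self.tau
        self.log_trans = np.log(
            np.array(
                [
                    [m2m, self.delta, self.delta],
                    [g2m, self.epsilon, self.sigma],
                    [g2m, self.sigma, self.epsilon],
                ]
            )
        )
        self.log_start = self.log_trans[_M].copy()  # start behaves like M
        self.log_tau = math.log(self.tau)
        joint = self.substitution.freqs[:, None] * self.substitution.transition(
            self.t
        )
        self.log_joint = np.log(joint)
        self.log_single = np.log(self.substitution.freqs)

    @classmethod
    def site_independent(cls, rate: float = 0.1, **kwargs) -> "PairHMMParams":
        """delta = epsilon = sigma: a column-independent indel process."""
        return cls(delta=rate, epsilon=rate, sigma=rate, **kwargs)


def _residue_indices(params: PairHMMParams, seq: SequenceRecord) -> np.ndarray:
    return np.array([params.substitution.index(c) for c in seq.residues])


class _ForwardDP:
    """Log-space forward matrices F[state, i, j] for two sequences."""

    def __init__(
        self, params: PairHMMParams, seq_a: SequenceRecord, seq_b: SequenceRecord
    ):
        if not seq_a.residues or not seq_b.residues:
            raise ContractError("sequences must be non-empty")
        self.params = params
        self.seq_a, self.seq_b = seq_a, seq_b
        ia = _residue_indices(params, seq_a)
        ib = _residue_indices(params, seq_b)
        n, m = len(ia), len(ib)
        self.n, self.m = n, m
        self.em_m = params.log_joint[np.ix_(ia, ib)]  # (n, m)
        self.em_x = params.log_single[ia]  # (n,)
        self.em_y = params.log_single[ib]  # (m,)
        lt = params.log_trans
        ls = params.log_start
        F = np.full((3, n + 1, m + 1), NEG_INF)
        for i in range(n + 1):
            for j in range(m + 1):
                if i == 0 and j == 0:
                    continue
                # match: emitted (a_i, b_j), came from (i-1, j-1)
                if i >= 1 and j >= 1:
                    F[_M, i, j] = self.em_m[i - 1, j - 1] + self._into(
                        F, ls, lt, _M, i - 1, j - 1
                    )
                if i >= 1:
                    F[_X, i, j] = self.em_x[i - 1] + self._into(
                        F, ls, lt, _X, i - 1, j
                    )
                if j >= 1:
                    F[_Y, i, j] = self.em_y[j - 1] + self._into(
                        F, ls, lt, _Y, i, j - 1
                    )
        self.F = F
        self.log_total = (
            _lse3(F[_M, n, m], F[_X, n, m], F[_Y, n, m]) + params.log_tau
        )

    @staticmethod
    def _into(F, log_start, log_trans, state, i, j) -> float:
        if i == 0 and j == 0:
            return log_start[state]
        return _lse3(
            F[_M, i, j] + log_trans[_M, state],
            F[_X, i, j] + log_trans[_X, state],
            F[_Y, i, j] + log_trans[_Y, state],
        )

    def backward(self) -> np.ndarray:
        """B[state, i, j]: log prob of the remainder given state at (i, j)."""
        n, m = self.n, self.m
        lt = self.params.log_trans
        B = np.full((3, n + 1, m + 1), NEG_INF)
        B[:, n, m] = self.params.log_tau
        for i in range(n, -1, -1):
            for j in range(m, -1, -1):
                if i == n and j == m:
                    continue
                terms = [NEG_INF, NEG_INF, NEG_INF]
                out = []
                if i < n and j < m:
                    out.append((_M, self.em_m[i, j] + B[_M, i + 1, j + 1]))
                if i < n:
                    out.append((_X, self.em_x[i] + B[_X, i + 1, j]))
                if j < m:
                    out.append((_Y, self.em_y[j] + B[_Y, i, j + 1]))
                for s in range(3):
                    vals = [lt[s, s2] + v for s2, v in out]
                    B[s, i, j] = _logsumexp_list(vals)
        return B


def _lse3(a: float, b: float, c: float) -> float:
    m = max(a, b, c)
    if m == NEG_INF:
        return NEG_INF
    return m + math.log(
        math.exp(a - m) + math.exp(b - m) + math.exp(c - m)
    )


def _logsumexp_list(vals) -> float:
    if not vals:
        return NEG_INF
    m = max(vals)
    if m == NEG_INF:
        return NEG_INF
    return m + math.log(sum(math.exp(v - m) for v in vals))


def forward_total(
    params: PairHMMParams, seq_a: SequenceRecord, seq_b: SequenceRecord
) -> float:
    """Log of the summed probability over all global pairwise alignments."""
    return _ForwardDP(params, seq_a, seq_b).log_total


def _state_of(code: ColumnCode) -> int:
    odd_a, odd_b = code[0] % 2 == 1, code[1] % 2 == 1
    if odd_a and odd_b:
        return _M
    if odd_a:
        return _X
    return _Y


def alignment_log_prob(params: PairHMMParams, alignment: Alignment) -> float:
    """Joint log-probability of one pairwise alignment (path + emissions)."""
    if alignment.n_rows != 2:
        raise ContractError("pair-HMM requires exactly 2 rows")
    seq_a, seq_b = alignment.sequences()
    ia = _residue_indices(params, seq_a)
    ib = _residue_indices(params, seq_b)
    logp = 0.0
    prev: Optional[int] = None
    for code in encode_alignment(alignment):
        s = _state_of(code)
        logp += (
            params.log_start[s] if prev is None else params.log_trans[prev, s]
        )
        if s == _M:
            logp += params.log_joint[
                ia[(code[0] + 1) // 2 - 1], ib[(code[1] + 1) // 2 - 1]
            ]
        elif s == _X:
            logp += params.log_single[ia[(code[0] + 1) // 2 - 1]]
        else:
            logp += params.log_single[ib[(code[1] + 1) // 2 - 1]]
        prev = s
    return logp + params.log_tau


def alignment_log_posterior(
    params: PairHMMParams, alignment: Alignment
) -> float:
    """Exact log posterior of a pairwise alignment: path joint minus total."""
    seq_a, seq_b = alignment.sequences()
    return alignment_log_prob(params, alignment) - forward_total(
        params, seq_a, seq_b
    )


def sample_alignments(
    params: PairHMMParams,
    seq_a: SequenceRecord,
    seq_b: SequenceRecord,
    n: int,
    seed: int | np.random.Generator = 0,
) -> SampleSet:
    """Draw n i.i.d. alignments from the exact posterior (stochastic traceback)."""
    if n < 1:
        raise ContractError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dp = _ForwardDP(params, seq_a, seq_b)
    F, lt = dp.F, params.log_trans
    nn, mm = dp.n, dp.m

    alignments = []
    for _ in range(n):
        # final state given termination
        final = F[:, nn, mm]
        probs = np.exp(final - _lse3(*final))
        probs /= probs.sum()
        s = int(rng.choice(3, p=probs))
        i, j = nn, mm
        codes_rev: list[ColumnCode] = []
        while True:
            if s == _M:
                codes_rev.append((2 * i - 1, 2 * j - 1))
                pi, pj = i - 1, j - 1
            elif s == _X:
                codes_rev.append((2 * i - 1, 2 * j))
                pi, pj = i - 1, j
            else:
                codes_rev.append((2 * i, 2 * j - 1))
                pi, pj = i, j - 1
            if pi == 0 and pj == 0:
                break
            weights = F[:, pi, pj] + lt[:, s]
            w = np.exp(weights - _logsumexp_list(list(weights)))
            w /= w.sum()
            s = int(rng.choice(3, p=w))
            i, j = pi, pj
        codes = codes_rev[::-1]
        rows_a, rows_b = [], []
        for c0, c1 in codes:
            rows_a.append(seq_a.residues[(c0 + 1) // 2 - 1] if c0 % 2 else "-")
            rows_b.append(seq_b.residues[(c1 + 1) // 2 - 1] if c1 % 2 else "-")
        alignments.append(
            Alignment(
                ids=(seq_a.id, seq_b.id),
                rows=("".join(rows_a), "".join(rows_b)),
            )
        )
    return SampleSet.from_alignments(alignments)


def exact_column_marginals(
    params: PairHMMParams, seq_a: SequenceRecord, seq_b: SequenceRecord
):
    """Exact posterior probability of every possible coded column.

    Forward-backward: the marginal of the column emitted by state s at
    cell (i, j) is F[s,i,j] + B[s,i,j] - log total.  Returned as a
    :class:`MarginalTable` with probabilities as counts and a unit sample
    mass (pair marginals are not populated).
    """
    from .marginals import MarginalTable

    dp = _ForwardDP(params, seq_a, seq_b)
    B = dp.backward()
    counts: dict[ColumnCode, float] = {}
    for i in range(dp.n + 1):
        for j in range(dp.m + 1):
            if i >= 1 and j >= 1:
                p = math.exp(dp.F[_M, i, j] + B[_M, i, j] - dp.log_total)
                if p > 0:
                    counts[(2 * i - 1, 2 * j - 1)] = p
            if i >= 1:
                p = math.exp(dp.F[_X, i, j] + B[_X, i, j] - dp.log_total)
                if p > 0:
                    counts[(2 * i - 1, 2 * j)] = p
            if j >= 1:
                p = math.exp(dp.F[_Y, i, j] + B[_Y, i, j] - dp.log_total)
                if p > 0:
                    counts[(2 * i, 2 * j - 1)] = p
    return MarginalTable(counts=counts, pair_counts={}, n_samples=1.0)


def true_edge_scorer(
    params: PairHMMParams, seq_a: SequenceRecord, seq_b: SequenceRecord
) -> Callable[[Optional[ColumnCode], Optional[ColumnCode]], float]:
    """Log transition-times-emission weight for each column adjacency.

    ``prev is None`` marks the virtual source; ``code is None`` the sink
    (termination).  Suitable for :func:`dagalign.marginals.external_mass`
    with ``forward_total`` as the normaliser.
    """
    ia = _residue_indices(params, seq_a)
    ib = _residue_indices(params, seq_b)

    def scorer(
        prev: Optional[ColumnCode], code: Optional[ColumnCode]
    ) -> float:
        if code is None:
            return params.log_tau
        s = _state_of(code)
        trans = (
            params.log_start[s]
            if prev is None
            else params.log_trans[_state_of(prev), s]
        )
        if s == _M:
            em = params.log_joint[
                ia[(code[0] + 1) // 2 - 1], ib[(code[1] + 1) // 2 - 1]
            ]
        elif s == _X:
            em = params.log_single[ia[(code[0] + 1) // 2 - 1]]
        else:
            em = params.log_single[ib[(code[1] + 1) // 2 - 1]]
        return float(trans + em)

    return scorer
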
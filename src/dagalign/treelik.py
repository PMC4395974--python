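"""Phylogenetic likelihoods on alignment columns and DAG-marginalised trees.

Column likelihoods follow Felsenstein pruning under a reversible
substitution model; rows holding a gap are treated as missing data (a
partial-likelihood vector of ones).  On a single alignment the tree
posterior factorises over columns.  Over a whole DAG, a forward dynamic
program accumulates, per column, the likelihood-weighted mass of all
partial paths, yielding the tree likelihood summed over every alignment
the DAG encodes, each weighted by its factored probability.  Topology
posteriors group candidate trees by their unrooted topology, average the
marginal likelihoods within a group, and normalise across groups
(uniform prior over topologies).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import dendropy
import numpy as np
from scipy.linalg import expm

from ._dayhoff import AMINO_ACIDS, DAYHOFF_EXCHANGEABILITIES, DAYHOFF_FREQUENCIES
from .coding import ColumnCode
from .dag import BOUNDARY, AlignmentDAG, topological_classes, _column_topo_order
from .errors import ConsistencyError, ContractError
from .marginals import MarginalTable, _logsumexp, meanfield_conditional
from .msa_io import SequenceRecord


@dataclass
class SubstModel:
    """Reversible substitution model: rate matrix Q and equilibrium freqs.

    Q rows sum to zero and the expected substitution rate at equilibrium
    is normalised to one, so branch lengths are expected substitutions
    per site.
    """

    alphabet: str
    rate_matrix: np.ndarray
    freqs: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        k = len(self.alphabet)
        if self.rate_matrix.shape != (k, k):
            raise ContractError("rate matrix shape does not match alphabet")
        if abs(self.freqs.sum() - 1.0) > 1e-8:
            raise ContractError("equilibrium frequencies must sum to 1")
        if np.abs(self.rate_matrix.sum(axis=1)).max() > 1e-8:
            raise ContractError("rate matrix rows must sum to 0")

    @classmethod
    def from_exchangeabilities(
        cls, alphabet: str, s_lower: Sequence[float], freqs: Sequence[float]
    ) -> "SubstModel":
        k = len(alphabet)
        s = np.zeros((k, k))
        it = iter(s_lower)
        for i in range(1, k):
            for j in range(i):
                s[i, j] = s[j, i] = next(it)
        pi = np.asarray(freqs, dtype=float)
        pi = pi / pi.sum()
        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        rate = -(pi * np.diag(q)).sum()
        return cls(alphabet=alphabet, rate_matrix=q / rate, freqs=pi)

    @classmethod
    def dayhoff(cls) -> "SubstModel":
        """Dayhoff (1978) amino-acid model (PAML dayhoff.dat constants)."""
        return cls.from_exchangeabilities(
            AMINO_ACIDS, DAYHOFF_EXCHANGEABILITIES, DAYHOFF_FREQUENCIES
        )

    @classmethod
    def jc(cls, alphabet: str = "ACGT") -> "SubstModel":
        """Jukes-Cantor-type model: uniform rates and frequencies."""
        k = len(alphabet)
        q = np.full((k, k), 1.0 / (k - 1))
        np.fill_diagonal(q, -1.0)
        return cls(
            alphabet=alphabet,
            rate_matrix=q,
            freqs=np.full(k, 1.0 / k),
        )

    def transition(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt), cached per branch length."""
        p = self._cache.get(t)
        if p is None:
            p = expm(self.rate_matrix * t)
            self._cache[t] = p
        return p

    def index(self, residue: str) -> int:
        try:
            return self.alphabet.index(residue.upper())
        except ValueError:
            raise ConsistencyError(
                f"residue {residue!r} not in model alphabet {self.alphabet!r}"
            )


class TreeLikelihood:
    """Batch Felsenstein pruning for one (tree, sequence set, model) triple."""

    def __init__(
        self,
        tree: dendropy.Tree,
        sequences: Sequence[SequenceRecord],
        model: SubstModel,
    ):
        self.model = model
        self.sequences = list(sequences)
        self.row_of = {s.id: i for i, s in enumerate(self.sequences)}
        leaf_labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
        if leaf_labels != sorted(self.row_of):
            raise ConsistencyError(
                "tree leaf labels do not match the sequence ids"
            )
        # postorder node list; each internal node stores (child, P-matrix)
        self._nodes = list(tree.postorder_node_iter())
        self._p = {}
        for node in self._nodes:
            if node.parent_node is not None:
                t = node.edge.length if node.edge.length is not None else 0.0
                self._p[id(node)] = model.transition(float(t))
        # residue index per leaf per sequence position (1-based positions)
        self._leaf_residues = {
            s.id: np.array([model.index(ch) for ch in s.residues])
            for s in self.sequences
        }

    def column_log_likelihoods(
        self, codes: Sequence[ColumnCode]
    ) -> np.ndarray:
        """Log-likelihood of each coded column (gaps as missing data)."""
        k = len(self.model.alphabet)
        n_cols = len(codes)
        codes_arr = np.asarray(codes, dtype=int)
        partials: dict[int, np.ndarray] = {}
        for node in self._nodes:
            if node.is_leaf():
                label = node.taxon.label
                row = self.row_of[label]
                part = np.ones((n_cols, k))
                col_codes = codes_arr[:, row]
                is_char = col_codes % 2 == 1
                if is_char.any():
                    res_idx = self._leaf_residues[label][
                        (col_codes[is_char] + 1) // 2 - 1
                    ]
                    part[is_char] = 0.0
                    part[np.nonzero(is_char)[0], res_idx] = 1.0
                partials[id(node)] = part
            else:
                part = np.ones((n_cols, k))
                for child in node.child_nodes():
                    p = self._p[id(child)]
                    part *= partials.pop(id(child)) @ p.T
                partials[id(node)] = part
        root = partials[id(self._nodes[-1])]
        lik = root @ self.model.freqs
        return np.log(lik)


def column_log_likelihood(
    code: ColumnCode,
    sequences: Sequence[SequenceRecord],
    tree: dendropy.Tree,
    model: SubstModel,
) -> float:
    """Pruning log-likelihood of a single coded column."""
    return float(
        TreeLikelihood(tree, sequences, model).column_log_likelihoods([code])[0]
    )


def alignment_tree_log_posterior(
    alignment,
    tree: dendropy.Tree,
    model: SubstModel,
    prior: Optional[Callable[[dendropy.Tree], float]] = None,
) -> float:
    """Unnormalised log-posterior of a tree given one fixed alignment."""
    from .coding import encode_alignment

    tl = TreeLikelihood(tree, alignment.sequences(), model)
    codes = encode_alignment(alignment)
    log_prior = prior(tree) if prior is not None else 0.0
    return log_prior + float(tl.column_log_likelihoods(codes).sum())


def dag_tree_log_marginal(
    dag: AlignmentDAG,
    table: MarginalTable,
    tree: dendropy.Tree,
    model: SubstModel,
    mode: str = "meanfield",
) -> float:
    """Log of the tree likelihood summed over all alignments in the DAG.

    Forward recursion: the partial mass of a column is its column
    likelihood times its factored conditional times the summed mass of
    its predecessors.  At the sink this equals
    ``log sum over paths of p(A) * product of column likelihoods``.
    """
    codes = list(dag.columns)
    tl = TreeLikelihood(tree, dag.sequences, model)
    log_lik = dict(zip(codes, tl.column_log_likelihoods(codes)))

    if mode == "meanfield":
        logz: dict[ColumnCode, float] = {}
        for key in topological_classes(dag):
            idx = dag.classes[key]
            if key == dag.source:
                incoming = 0.0
            elif idx.in_members:
                incoming = _logsumexp([logz[c] for c in idx.in_members])
            else:
                continue
            for code in idx.out_members:
                logz[code] = (
                    incoming
                    + log_lik[code]
                    + math.log(meanfield_conditional(table, dag, code))
                )
        return _logsumexp([logz[c] for c in dag.classes[dag.sink].in_members])
    if mode == "pair":
        logz = {}
        for code in _column_topo_order(dag):
            terms = []
            start = table.pair_counts.get((BOUNDARY, code), 0)
            if start:
                terms.append(math.log(start / dag.n_samples))
            for prev in dag.classes[dag.columns[code].pred_key].in_members:
                pair = table.pair_counts.get((prev, code), 0)
                if pair and prev in logz:
                    terms.append(
                        logz[prev] + math.log(pair / table.counts[prev])
                    )
            if not terms:
                continue
            logz[code] = log_lik[code] + _logsumexp(terms)
        finals = [
            logz[code] + math.log(end / table.counts[code])
            for (code, b), end in table.pair_counts.items()
            if b is BOUNDARY and code is not BOUNDARY and code in logz
        ]
        return _logsumexp(finals)
    raise ContractError(f"unknown mode {mode!r}")


def topology_key(tree: dendropy.Tree) -> frozenset:
    """Canonical unrooted topology: the set of non-trivial bipartitions."""
    labels = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    bipartitions = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        other = labels - side
        if len(side) > 1 and len(other) > 1:
            bipartitions.add(frozenset({side, other}))
    return frozenset(bipartitions)


def topology_posterior(
    dag: AlignmentDAG,
    table: MarginalTable,
    trees: Sequence[dendropy.Tree],
    model: SubstModel,
    mode: str = "meanfield",
) -> dict[frozenset, float]:
    """Posterior over unrooted topologies, marginalised over the DAG.

    Trees are grouped by topology; each group's score is the mean of its
    trees' DAG-marginal likelihoods (uniform prior), then scores are
    normalised across groups.
    """
    if not trees:
        raise ContractError("empty tree collection")
    groups: dict[frozenset, list[float]] = {}
    for tree in trees:
        key = topology_key(tree)
        groups.setdefault(key, []).append(
            dag_tree_log_marginal(dag, table, tree, model, mode=mode)
        )
    log_scores = {
        key: _logsumexp(vals) - math.log(len(vals))
        for key, vals in groups.items()
    }
    total = _logsumexp(list(log_scores.values()))
    return {key: math.exp(s - total) for key, s in log_scores.items()}
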
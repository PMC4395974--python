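"""Seeded synthetic fixtures: evolved sequences with a known true alignment,
and perturbed alternative alignments standing in for posterior samples.

``simulate_msa`` evolves a root sequence down a tree with per-site
substitutions (Jukes-Cantor-type, probability ``1 - exp(-rate * t)`` per
branch) and indels (per-branch Poisson counts, geometric lengths, uniform
positions; insertions create new homology columns).  The recorded
homology structure is returned as the true alignment.

``perturb_samples`` applies seeded local gap-shift moves to the truth:
a random gap/character boundary within one row is swapped, which
preserves the row's ungapped content by construction while moving the
homology statement.  Repeated shifts merge and split gap runs.  The
resulting sample sets are structurally valid and diverse (they contain
interchanges and crossovers); they make no claim of statistical
faithfulness to any posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import dendropy
import numpy as np

from .errors import ContractError
from .msa_io import GAP, Alignment, SampleSet, SequenceRecord

#: Indel-rate presets (events per site per unit branch length).
INDEL_RATES = {"low": 0.02, "medium": 0.05, "high": 0.10}


@dataclass
class SimConfig:
    n_sequences: int = 5
    mean_length: int = 100
    substitution_rate: float = 1.0
    indel_rate: float = INDEL_RATES["medium"]
    mean_indel_length: float = 3.0
    alphabet: str = "ACGT"
    tree: Optional[dendropy.Tree] = None  # None -> random topology
    seed: int = 0
    n_samples: int = 100
    perturbation_strength: float = 0.3

    def __post_init__(self) -> None:
        if self.n_sequences < 2:
            raise ContractError("need at least 2 sequences")
        if self.n_samples < 1:
            raise ContractError("need at least 1 sample")
        if not 0.0 <= self.perturbation_strength <= 1.0:
            raise ContractError("perturbation_strength must lie in [0, 1]")


@dataclass
class SimResult:
    sequences: tuple[SequenceRecord, ...]
    truth: Alignment
    tree: dendropy.Tree


def random_tree(
    n_leaves: int,
    rng: np.random.Generator,
    labels: Optional[list[str]] = None,
    min_branch: float = 0.05,
    max_branch: float = 0.3,
) -> dendropy.Tree:
    """A random binary tree built by sequential joining, with uniform
    branch lengths in [min_branch, max_branch]."""
    if labels is None:
        labels = [f"seq{i + 1}" for i in range(n_leaves)]
    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes = []
    for label in labels:
        node = dendropy.Node(taxon=tns.get_taxon(label))
        node.edge.length = float(rng.uniform(min_branch, max_branch))
        nodes.append(node)
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = float(rng.uniform(min_branch, max_branch))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    for n in nodes:
        tree.seed_node.add_child(n)
    return tree


def _evolve_branch(
    state: list[tuple[int, str]],
    t: float,
    config: SimConfig,
    rng: np.random.Generator,
    order: list[int],
    next_id: list[int],
) -> list[tuple[int, str]]:
    """Evolve one lineage along a branch of length t.

    *state* is a list of (homology column id, character); *order* is the
    shared global column order, mutated in place when insertions create
    new columns.
    """
    alphabet = config.alphabet
    state = list(state)

    # substitutions: Jukes-Cantor-type, uniform replacement
    p_sub = 1.0 - np.exp(-config.substitution_rate * t)
    for k in range(len(state)):
        if rng.random() < p_sub:
            cid, ch = state[k]
            others = [c for c in alphabet if c != ch]
            state[k] = (cid, others[rng.integers(len(others))])

    # indels: Poisson count, geometric length, uniform position
    n_events = rng.poisson(config.indel_rate * t * max(len(state), 1))
    for _ in range(n_events):
        length = int(rng.geometric(1.0 / config.mean_indel_length))
        if rng.random() < 0.5 and state:  # deletion
            start = int(rng.integers(len(state)))
            del state[start : start + length]
        else:  # insertion after position k (0 = before first character)
            k = int(rng.integers(len(state) + 1))
            new_cols = []
            for _ in range(length):
                cid = next_id[0]
                next_id[0] += 1
                new_cols.append((cid, alphabet[rng.integers(len(alphabet))]))
            # splice the new ids into the global column order
            if k == 0:
                anchor_pos = (
                    order.index(state[0][0]) if state else len(order)
                )
            else:
                anchor_pos = order.index(state[k - 1][0]) + 1
            order[anchor_pos:anchor_pos] = [cid for cid, _ in new_cols]
            state[k:k] = new_cols
    return state


def simulate_msa(config: SimConfig) -> SimResult:
    """Evolve sequences along a tree; return them with the true alignment."""
    rng = np.random.default_rng(config.seed)
    tree = (
        config.tree
        if config.tree is not None
        else random_tree(config.n_sequences, rng)
    )
    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    if len(leaves) != config.n_sequences and config.tree is None:
        raise ContractError("random tree generation failed")

    root_len = max(2, int(rng.poisson(config.mean_length)))
    order = list(range(root_len))
    next_id = [root_len]
    root_state = [
        (cid, config.alphabet[rng.integers(len(config.alphabet))])
        for cid in order
    ]

    leaf_states: dict[str, list[tuple[int, str]]] = {}

    def descend(node, state):
        children = node.child_nodes()
        if not children:
            leaf_states[node.taxon.label] = state
            return
        for child in children:
            t = child.edge.length if child.edge.length is not None else 0.1
            descend(
                child,
                _evolve_branch(state, float(t), config, rng, order, next_id),
            )

    descend(tree.seed_node, root_state)

    used = set()
    for state in leaf_states.values():
        used.update(cid for cid, _ in state)
    columns = [cid for cid in order if cid in used]
    col_pos = {cid: k for k, cid in enumerate(columns)}
    rows = []
    ids = []
    for label in leaves:
        row = [GAP] * len(columns)
        for cid, ch in leaf_states[label]:
            row[col_pos[cid]] = ch
        ids.append(label)
        rows.append("".join(row))
    truth = Alignment(ids=tuple(ids), rows=tuple(rows))
    return SimResult(sequences=truth.sequences(), truth=truth, tree=tree)


def _gap_shift_once(rows: list[list[str]], rng: np.random.Generator) -> None:
    """Swap one random gap/character boundary inside one row (in place)."""
    n_rows = len(rows)
    length = len(rows[0])
    for _ in range(20):  # retries in case a draw has no legal boundary
        r = int(rng.integers(n_rows))
        c = int(rng.integers(length - 1))
        a, b = rows[r][c], rows[r][c + 1]
        if (a == GAP) != (b == GAP):
            rows[r][c], rows[r][c + 1] = b, a
            return


def perturb_samples(truth: Alignment, config: SimConfig) -> SampleSet:
    """Seeded alternative alignments via local gap-shift moves on the truth.

    Strength 0 returns n_samples exact copies of the truth.  Every output
    de-gaps to the true sequences by construction.
    """
    rng = np.random.default_rng(config.seed + 1)
    samples = []
    for _ in range(config.n_samples):
        rows = [list(row) for row in truth.rows]
        n_moves = (
            rng.poisson(config.perturbation_strength * truth.length)
            if config.perturbation_strength > 0
            else 0
        )
        for _ in range(n_moves):
            _gap_shift_once(rows, rng)
        joined = ["".join(r) for r in rows]
        keep = [
            c
            for c in range(len(joined[0]))
            if any(row[c] != GAP for row in joined)
        ]
        joined = ["".join(row[c] for c in keep) for row in joined]
        samples.append(Alignment(ids=truth.ids, rows=tuple(joined)))
    return SampleSet.from_alignments(samples)
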
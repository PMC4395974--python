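"""Shared fixtures and independent test oracles.

The random-alignment generator here is deliberately independent of the
package's own path machinery: it aligns fixed sequences by a random merge
walk (each column advances a random non-empty subset of rows), which
produces valid global alignments without touching column codes.
Likewise `brute_force_paths` rebuilds the adjacency relation from raw
codes by quadratic scanning, independent of the equivalence-class
bookkeeping it is used to check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dagalign.coding import f_pred, f_succ
from dagalign.msa_io import Alignment, SampleSet

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def random_alignment(
    ids: list[str], residues: list[str], rng: np.random.Generator
) -> Alignment:
    """A uniform-ish random global alignment of fixed sequences."""
    pointers = [0] * len(ids)
    rows: list[list[str]] = [[] for _ in ids]
    while any(p < len(r) for p, r in zip(pointers, residues)):
        live = [i for i, p in enumerate(pointers) if p < len(residues[i])]
        k = int(rng.integers(1, len(live) + 1))
        chosen = set(rng.choice(live, size=k, replace=False).tolist())
        for i in range(len(ids)):
            if i in chosen:
                rows[i].append(residues[i][pointers[i]])
                pointers[i] += 1
            else:
                rows[i].append("-")
    return Alignment(ids=tuple(ids), rows=tuple("".join(r) for r in rows))


def random_sample_set(
    rng: np.random.Generator,
    n_seqs: int = 2,
    length: tuple[int, int] = (3, 6),
    n_samples: int = 3,
    alphabet: str = "ACGT",
) -> SampleSet:
    ids = [f"s{i + 1}" for i in range(n_seqs)]
    residues = [
        "".join(rng.choice(list(alphabet), size=int(rng.integers(*length))))
        for _ in ids
    ]
    return SampleSet.from_alignments(
        [random_alignment(ids, residues, rng) for _ in range(n_samples)]
    )


def brute_force_paths(dag) -> list[tuple]:
    """All source-to-sink paths via quadratic adjacency scanning (oracle)."""
    codes = list(dag.columns)
    succ = {
        a: [b for b in codes if f_succ(a) == f_pred(b)] for a in codes
    }
    starts = [c for c in codes if f_pred(c) == dag.source]
    paths = []

    def walk(code, acc):
        acc.append(code)
        if f_succ(code) == dag.sink:
            paths.append(tuple(acc))
        else:
            for nxt in succ[code]:
                walk(nxt, acc)
        acc.pop()

    for s in starts:
        walk(s, [])
    return paths


@pytest.fixture
def interchange_samples() -> SampleSet:
    """Two 2-row alignments of ABC/ABC sharing one middle column with
    different neighbours in each sample (four recombinable paths)."""
    a1 = Alignment(ids=("s1", "s2"), rows=("ABC", "ABC"))
    a2 = Alignment(ids=("s1", "s2"), rows=("-AB-C", "A-BC-"))
    return SampleSet.from_alignments([a1, a2])


@pytest.fixture
def crossover_samples() -> SampleSet:
    """The ungapped and the fully-gapped alignment of AB/AB: the paths
    cross at a DP cell without sharing a column."""
    a1 = Alignment(ids=("s1", "s2"), rows=("AB", "AB"))
    a2 = Alignment(ids=("s1", "s2"), rows=("A-B-", "-A-B"))
    return SampleSet.from_alignments([a1, a2])


def quartet_tree():
    import dendropy

    return dendropy.Tree.get(
        data="((seq1:0.15,seq2:0.15):0.1,(seq3:0.15,seq4:0.15):0.1);",
        schema="newick",
    )
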
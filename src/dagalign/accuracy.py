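"""Alignment accuracy scores, rank scores, and tree distances.

The C-score is the proportion of reference columns reproduced exactly
(gap positions distinguished); the C+-score ignores gap placement by
comparing the gap-agnostic column images.  The "modeller" variants divide
by the predicted alignment's length instead of the reference's, so they
penalise over-long predictions.  AMA is the proportion of correct
residue-level homology statements: for every ordered pair of sequences
and every residue of the first, the statement "aligned to residue j of
the second" or "aligned to a gap" must match the reference.

The rank score places a candidate's accuracy within the distribution of
the individual samples' accuracies: 1 means better than every sample, 0
worse than all, ties counted at half weight (midrank).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
from dendropy.calculate import treecompare

from .coding import encode_alignment, plus_code
from .errors import ConsistencyError
from .msa_io import GAP, Alignment


@dataclass(frozen=True)
class AccuracyReport:
    c_score: float
    modeller_c: float
    cplus_score: float
    modeller_cplus: float
    ama: float
    predicted_length: int
    reference_length: int


def _pair_statements(alignment: Alignment) -> dict:
    """Residue-level homology statements per ordered sequence pair.

    Maps (row_a, row_b, residue_index_in_a) -> residue index in b or None
    (aligned to a gap).
    """
    n = alignment.n_rows
    statements = {}
    consumed = [0] * n
    for col in range(alignment.length):
        chars = [row[col] != GAP for row in alignment.rows]
        for i in range(n):
            if chars[i]:
                consumed[i] += 1
        for a in range(n):
            if not chars[a]:
                continue
            for b in range(n):
                if b == a:
                    continue
                statements[(a, b, consumed[a])] = (
                    consumed[b] if chars[b] else None
                )
    return statements


def score_alignment(predicted: Alignment, reference: Alignment) -> AccuracyReport:
    """Score a predicted alignment against a reference over the same sequences."""
    try:
        predicted = predicted.reordered(reference.ids)
    except ConsistencyError:
        raise ConsistencyError("predicted and reference sequence sets differ")
    if predicted.sequences() != reference.sequences():
        raise ConsistencyError(
            "predicted and reference de-gapped sequences differ"
        )

    pred_codes = set(encode_alignment(predicted))
    ref_codes = set(encode_alignment(reference))
    shared_c = len(pred_codes & ref_codes)
    pred_plus = {plus_code(c) for c in pred_codes}
    ref_plus = {plus_code(c) for c in ref_codes}
    shared_plus = len(pred_plus & ref_plus)

    pred_statements = _pair_statements(predicted)
    ref_statements = _pair_statements(reference)
    agree = sum(
        1 for k, v in ref_statements.items() if pred_statements.get(k, "NA") == v
    )

    return AccuracyReport(
        c_score=shared_c / reference.length,
        modeller_c=shared_c / predicted.length,
        cplus_score=shared_plus / reference.length,
        modeller_cplus=shared_plus / predicted.length,
        ama=agree / len(ref_statements) if ref_statements else 1.0,
        predicted_length=predicted.length,
        reference_length=reference.length,
    )


def rank_score(candidate: float, sample_accuracies: Sequence[float]) -> float:
    """Midrank of a candidate accuracy among the samples' accuracies."""
    if not sample_accuracies:
        raise ConsistencyError("empty sample accuracy collection")
    below = sum(1 for a in sample_accuracies if a < candidate)
    ties = sum(1 for a in sample_accuracies if a == candidate)
    return (below + 0.5 * ties) / len(sample_accuracies)


def rf_distance(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> int:
    """Unrooted Robinson-Foulds distance: bipartitions in exactly one tree.

    Bounded by 2(n-3) for binary trees on n leaves.
    """
    labels_a = sorted(l.taxon.label for l in tree_a.leaf_node_iter())
    labels_b = sorted(l.taxon.label for l in tree_b.leaf_node_iter())
    if labels_a != labels_b:
        raise ConsistencyError("trees have different leaf sets")
    tns = dendropy.TaxonNamespace()
    a = tree_a.clone(depth=1)
    b = tree_b.clone(depth=1)
    a.migrate_taxon_namespace(tns)
    b.migrate_taxon_namespace(tns)
    for t in (a, b):
        t.is_rooted = False
        t.encode_bipartitions()
    return int(treecompare.symmetric_difference(a, b))
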
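"""Model/Results facade over the alignment-DAG machinery.

``AlignmentPosterior`` is built from a set of sampled alignments of the
same sequences; ``fit`` combines the samples into the column DAG and
estimates the empirical column, pair and plus-grouped marginals.  The
returned ``AlignmentPosteriorResults`` carries the fitted factored
posterior and exposes the downstream quantities: MAP and minimum-risk
summary alignments, per-alignment log-posteriors, path sampling,
DAG-marginalised tree and topology posteriors, and a summary() table of
the DAG's size and shape.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from . import dag as _dag
from . import marginals as _marginals
from . import summary as _summary
from . import treelik as _treelik
from .msa_io import Alignment, SampleSet, read_sample_set


class AlignmentPosterior:
    """Factored posterior over alignments, estimated from sampled MSAs."""

    def __init__(self, samples: SampleSet, mode: str = "meanfield"):
        self.samples = samples
        self.mode = mode

    @classmethod
    def from_path(cls, path: str | Path, mode: str = "meanfield"):
        """Build from a directory of FASTA samples or a multi-MSA file."""
        return cls(read_sample_set(path), mode=mode)

    def fit(self) -> "AlignmentPosteriorResults":
        dag = _dag.build_dag(self.samples)
        table = _marginals.estimate_marginals(dag)
        return AlignmentPosteriorResults(self, dag, table)


class AlignmentPosteriorResults:
    def __init__(self, model: AlignmentPosterior, dag, table):
        self.model = model
        self.dag = dag
        self.marginals = table
        self.mode = model.mode

    # -- summaries ---------------------------------------------------------
    def map_alignment(self) -> _summary.SummaryResult:
        return _summary.map_alignment(self.dag, self.marginals, mode=self.mode)

    def min_risk(
        self, mapping: str = "Cplus", g: float = 0.5, column_weight=None
    ) -> _summary.SummaryResult:
        loss = _summary.LossConfig(mapping=mapping, g=g, column_weight=column_weight)
        return _summary.min_risk_alignment(self.dag, self.marginals, loss)

    # -- probabilities -----------------------------------------------------
    def log_posterior(self, alignment: Alignment) -> float:
        """Reconstructed log posterior of one alignment under the fit."""
        from .coding import encode_alignment

        aln = alignment.reordered(tuple(s.id for s in self.dag.sequences))
        return _marginals.path_log_prob(
            encode_alignment(aln), self.marginals, self.dag, mode=self.mode
        )

    def sample_paths(self, n: int, seed: int = 0) -> list[tuple]:
        rng = np.random.default_rng(seed)
        return [
            _dag.sample_path(self.dag, self.marginals, mode=self.mode, seed=rng)
            for _ in range(n)
        ]

    # -- downstream --------------------------------------------------------
    def topology_posterior(
        self,
        trees: Sequence[dendropy.Tree],
        subst_model: Optional[_treelik.SubstModel] = None,
    ) -> dict:
        if subst_model is None:
            subst_model = _treelik.SubstModel.dayhoff()
        return _treelik.topology_posterior(
            self.dag, self.marginals, trees, subst_model, mode=self.mode
        )

    # -- reporting ---------------------------------------------------------
    def stats(self) -> dict:
        return _dag.dag_stats(self.dag)

    def summary(self) -> str:
        """Human-readable fit summary."""
        s = self.stats()
        n_paths = _dag.count_paths(self.dag, allow_crossovers=True)
        log10_paths = math.log10(n_paths) if n_paths > 0 else float("-inf")
        mean_marginal = float(
            np.mean(
                [self.marginals.p_column(c) for c in self.dag.columns]
            )
        )
        rows = [
            ("No. sequences", len(self.dag.sequences)),
            ("No. samples", s["n_samples"]),
            ("Factorisation", self.mode),
            ("Columns in DAG", s["n_columns"]),
            ("Equivalence classes", s["n_classes"]),
            ("Mean class size", round(s["mean_class_size"], 3)),
            ("Max class size", s["max_class_size"]),
            ("log10 paths (crossovers)", round(log10_paths, 2)),
            ("Mean column marginal", round(mean_marginal, 4)),
        ]
        frame = pd.DataFrame(rows, columns=["", ""])
        title = "Alignment DAG posterior"
        body = frame.to_string(index=False, header=False)
        return f"{title}\n{'=' * len(title)}\n{body}"
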
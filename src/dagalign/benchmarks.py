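"""Seeded benchmark experiments exercising the whole pipeline.

Each function runs a self-contained, reproducible experiment at desk
scale and returns plain numbers: posterior-reconstruction error against
the exact pair-HMM oracle, DAG posterior-mass coverage, summary-alignment
rank scores on synthetic benches, topology recovery on quartets, and the
scaling of the minimum-risk DP with DAG size.  The problem sizes are
deliberate package defaults chosen to finish in seconds to minutes on a
single core; see docs/methods.md for the rationale.
"""

from __future__ import annotations

import time
from typing import Optional, Sequence

import dendropy
import numpy as np

from .accuracy import rank_score, score_alignment
from .coding import encode_alignment
from .dag import build_dag, count_paths
from .errors import SupportError
from .marginals import (
    estimate_marginals,
    external_mass,
    log_mse,
    path_log_prob,
)
from .msa_io import Alignment, SampleSet
from .pairhmm import (
    PairHMMParams,
    alignment_log_prob,
    forward_total,
    sample_alignments,
    true_edge_scorer,
)
from .simulate import INDEL_RATES, SimConfig, perturb_samples, simulate_msa
from .summary import LossConfig, min_risk_alignment
from .treelik import SubstModel, topology_key, topology_posterior

QUARTET_NEWICK = "((seq1:0.15,seq2:0.15):0.1,(seq3:0.15,seq4:0.15):0.1);"


def _pair_of_sequences(seed: int, length: int):
    """Two homologous sequences from the tree simulator."""
    cfg = SimConfig(
        n_sequences=2, mean_length=length, seed=seed, indel_rate=INDEL_RATES["medium"]
    )
    res = simulate_msa(cfg)
    return res.sequences


def reconstruction_mse(
    seed: int,
    length: int = 100,
    n_small: int = 100,
    n_large: int = 2000,
    n_replicates: int = 5,
    params: Optional[PairHMMParams] = None,
    max_eval: int = 40,
) -> dict[str, list[float]]:
    """Log-MSE of DAG-reconstructed alignment posteriors vs the exact oracle.

    For each replicate, alignments are sampled from the exact pair-HMM
    posterior; DAGs built from the first `n_small` and from all `n_large`
    samples reconstruct the log posterior of a fixed evaluation set of
    alignments (distinct alignments among the first `n_small` draws, so
    both factorisations cover them at both sizes), compared to the exact
    values.  Returns per-replicate MSEs keyed by ``{mode}_{size}``.
    """
    if params is None:
        params = PairHMMParams()
    out: dict[str, list[float]] = {
        f"{mode}_{n}": []
        for mode in ("meanfield", "pair")
        for n in (n_small, n_large)
    }
    rng = np.random.default_rng(seed)
    for rep in range(n_replicates):
        a, b = _pair_of_sequences(int(rng.integers(2**31 - 1)), length)
        ss = sample_alignments(
            params, a, b, n=n_large, seed=int(rng.integers(2**31 - 1))
        )
        ft = forward_total(params, a, b)
        seen: dict = {}
        for aln in ss.alignments[:n_small]:
            seen.setdefault(aln.rows, aln)
        evals = list(seen.values())[:max_eval]
        truth = [alignment_log_prob(params, al) - ft for al in evals]
        for n in (n_small, n_large):
            dag = build_dag(SampleSet.from_alignments(ss.alignments[:n]))
            table = estimate_marginals(dag)
            for mode in ("meanfield", "pair"):
                est = [
                    path_log_prob(encode_alignment(al), table, dag, mode)
                    for al in evals
                ]
                out[f"{mode}_{n}"].append(log_mse(est, truth))
    return out


def posterior_mass_curve(
    seed: int,
    length: int = 60,
    sizes: Sequence[int] = (10, 30, 100, 300),
    params: Optional[PairHMMParams] = None,
) -> list[float]:
    """DAG coverage of the true posterior as samples accumulate."""
    if params is None:
        params = PairHMMParams()
    a, b = _pair_of_sequences(seed, length)
    scorer = true_edge_scorer(params, a, b)
    norm = forward_total(params, a, b)
    ss = sample_alignments(params, a, b, n=max(sizes), seed=seed + 1)
    return [
        external_mass(
            dag=build_dag(SampleSet.from_alignments(ss.alignments[:k])),
            scorer=scorer,
            log_normaliser=norm,
        )
        for k in sizes
    ]


def summary_rank_bench(
    seed: int,
    n_replicates: int = 10,
    n_sequences: int = 5,
    mean_length: int = 100,
    n_samples: int = 200,
    perturbation_strength: float = 0.3,
    mapping: str = "Cplus",
    g: float = 0.0,
) -> list[float]:
    """Rank of the min-risk summary's C+ accuracy among the samples'.

    One rank score per seeded replicate (1 = the summary beats every
    individual sample against the known true alignment).
    """
    ranks = []
    for rep in range(n_replicates):
        cfg = SimConfig(
            n_sequences=n_sequences,
            mean_length=mean_length,
            indel_rate=INDEL_RATES["medium"],
            seed=seed + rep,
            n_samples=n_samples,
            perturbation_strength=perturbation_strength,
        )
        res = simulate_msa(cfg)
        samples = perturb_samples(res.truth, cfg)
        dag = build_dag(samples)
        table = estimate_marginals(dag)
        summary = min_risk_alignment(dag, table, LossConfig(mapping=mapping, g=g))
        candidate = score_alignment(summary.alignment, res.truth).cplus_score
        sample_scores = [
            score_alignment(aln, res.truth).cplus_score
            for aln in samples.alignments
        ]
        ranks.append(rank_score(candidate, sample_scores))
    return ranks


def quartet_topology_bench(
    seed: int,
    n_replicates: int = 5,
    mean_length: int = 200,
    n_samples: int = 100,
    n_trees: int = 51,
) -> list[tuple[bool, float]]:
    """Topology recovery on seeded quartet benches.

    Sequences evolve on a fixed, resolvable quartet; candidate trees span
    all three resolved topologies with varied branch lengths.  Returns
    (true topology ranked first?, posterior of the true topology) per
    replicate.
    """
    results = []
    model = SubstModel.jc()
    for rep in range(n_replicates):
        tree = dendropy.Tree.get(data=QUARTET_NEWICK, schema="newick")
        cfg = SimConfig(
            n_sequences=4,
            mean_length=mean_length,
            seed=seed + rep,
            n_samples=n_samples,
            perturbation_strength=0.4,
            tree=tree,
        )
        res = simulate_msa(cfg)
        samples = perturb_samples(res.truth, cfg)
        dag = build_dag(samples)
        table = estimate_marginals(dag)
        rng = np.random.default_rng(seed + rep + 10_000)
        labels = [s.id for s in res.sequences]
        splits = [
            ((labels[0], labels[1]), (labels[2], labels[3])),
            ((labels[0], labels[2]), (labels[1], labels[3])),
            ((labels[0], labels[3]), (labels[1], labels[2])),
        ]
        trees = []
        for i in range(n_trees):
            (x, y), (z, w) = splits[i % 3]
            bl = rng.uniform(0.05, 0.3, size=5)
            trees.append(
                dendropy.Tree.get(
                    data=(
                        f"(({x}:{bl[0]},{y}:{bl[1]}):{bl[4]},"
                        f"({z}:{bl[2]},{w}:{bl[3]}):0.0);"
                    ),
                    schema="newick",
                )
            )
        post = topology_posterior(dag, table, trees, model)
        true_key = topology_key(res.tree)
        best = max(post, key=post.get)
        results.append((best == true_key, post.get(true_key, 0.0)))
    return results


def minrisk_scaling(
    seed: int,
    lengths: Sequence[int] = (1000, 2000, 4000, 8000),
    n_samples: int = 30,
    repeats: int = 5,
) -> dict:
    """Wall-work of the min-risk DP across doubling DAG sizes.

    Returns column counts, per-size best-of-`repeats` timings, and the
    fitted log-log slope (1.0 = linear in the number of DAG columns).
    """
    columns, times = [], []
    for k, length in enumerate(lengths):
        cfg = SimConfig(
            n_sequences=2,
            mean_length=length,
            seed=seed + k,
            n_samples=n_samples,
            perturbation_strength=0.3,
        )
        res = simulate_msa(cfg)
        samples = perturb_samples(res.truth, cfg)
        dag = build_dag(samples)
        table = estimate_marginals(dag)
        loss = LossConfig(mapping="C", g=0.5)
        best = float("inf")
        for _ in range(repeats):
            t0 = time.perf_counter()
            min_risk_alignment(dag, table, loss)
            best = min(best, time.perf_counter() - t0)
        columns.append(len(dag.columns))
        times.append(best)
    slope = float(
        np.polyfit(np.log(columns), np.log(times), 1)[0]
    )
    return {"columns": columns, "times": times, "slope": slope}
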
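"""DAG construction, path counting/enumeration, sampling, statistics."""

import numpy as np
import pytest
from scipy import stats as sstats

from dagalign.coding import f_pred, f_succ
from dagalign.dag import (
    build_dag,
    count_paths,
    dag_stats,
    enumerate_paths,
    sample_path,
    to_dot,
    topological_classes,
)
from dagalign.errors import SizeError
from dagalign.marginals import estimate_marginals, path_log_prob
from dagalign.msa_io import Alignment, SampleSet

from .conftest import brute_force_paths, random_sample_set


def single(rows):
    return SampleSet.from_alignments(
        [Alignment(ids=tuple(f"s{i}" for i in range(len(rows))), rows=rows)]
    )


class TestBuildDag:
    def test_single_alignment_single_path(self):
        ss = single(("AC", "AC"))
        dag = build_dag(ss)
        assert count_paths(dag) == 1
        assert enumerate_paths(dag) == [((1, 1), (3, 3))]

    def test_duplicate_alignments_double_counts(self):
        aln = Alignment(ids=("a", "b"), rows=("AC", "AC"))
        dag1 = build_dag(SampleSet.from_alignments([aln]))
        dag2 = build_dag(SampleSet.from_alignments([aln, aln]))
        assert set(dag1.columns) == set(dag2.columns)
        assert dag2.n_samples == 2
        assert all(c.count == 2 for c in dag2.columns.values())

    def test_interchange_fixture_shared_column(self, interchange_samples):
        dag = build_dag(interchange_samples)
        shared = dag.columns[(3, 3)]
        assert shared.count == 2
        assert len(dag.classes[shared.pred_key].in_members) == 2
        assert len(dag.classes[shared.succ_key].out_members) == 2

    def test_flow_conservation_at_interior_cells(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            dag = build_dag(random_sample_set(rng, n_seqs=3, n_samples=4))
            for key, idx in dag.classes.items():
                if key in (dag.source, dag.sink):
                    continue
                inflow = sum(dag.columns[c].count for c in idx.in_members)
                outflow = sum(dag.columns[c].count for c in idx.out_members)
                assert inflow == outflow  # exact integers


class TestTopologicalClasses:
    def test_single_path_order(self):
        dag = build_dag(single(("ACG", "ACG")))
        order = topological_classes(dag)
        assert len(order) == 4
        sums = [sum(k) for k in order]
        assert sums == sorted(sums)
        assert order[0] == dag.source and order[-1] == dag.sink

    def test_against_networkx_topological_order(self):
        import networkx as nx

        rng = np.random.default_rng(3)
        for _ in range(100):
            dag = build_dag(random_sample_set(rng, n_seqs=2, n_samples=3))
            order = {k: i for i, k in enumerate(topological_classes(dag))}
            g = nx.DiGraph()
            g.add_nodes_from(order)
            for col in dag.columns.values():
                g.add_edge(col.pred_key, col.succ_key)
            assert nx.is_directed_acyclic_graph(g)
            for a, b in g.edges:
                assert order[a] < order[b]


class TestCountPaths:
    def test_interchange_fixture_four_paths(self, interchange_samples):
        dag = build_dag(interchange_samples)
        assert count_paths(dag, allow_crossovers=True) == 4
        assert count_paths(dag, allow_crossovers=False) == 4

    def test_crossover_fixture(self, crossover_samples):
        dag = build_dag(crossover_samples)
        assert count_paths(dag, allow_crossovers=True) == 4
        assert count_paths(dag, allow_crossovers=False) == 2

    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            dag = build_dag(
                random_sample_set(rng, n_seqs=int(rng.integers(2, 4)), n_samples=3)
            )
            paths = brute_force_paths(dag)
            assert count_paths(dag, True) == len(paths)
            n_obs = count_paths(dag, False)
            assert len(dag.pair_counts) >= 0
            assert n_obs <= len(paths)
            # at least the distinct input alignments survive
            assert n_obs >= 1

    def test_monotone_in_samples(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            ss = random_sample_set(rng, n_seqs=2, n_samples=4)
            for flag in (True, False):
                prev = None
                for k in range(1, 5):
                    sub = SampleSet.from_alignments(ss.alignments[:k])
                    n = count_paths(build_dag(sub), flag)
                    if prev is not None:
                        assert n >= prev
                    prev = n


class TestEnumeratePaths:
    def test_crossover_unobserved_adjacencies(self, crossover_samples):
        dag = build_dag(crossover_samples)
        paths = enumerate_paths(dag, allow_crossovers=True)
        assert len(paths) == 4
        unobserved = [
            p
            for p in paths
            if any(pair not in dag.pair_counts for pair in zip(p, p[1:]))
        ]
        assert len(unobserved) == 2

    def test_every_path_decodes_to_the_sequences(self):
        from dagalign.coding import decode_path

        rng = np.random.default_rng(6)
        for _ in range(30):
            ss = random_sample_set(rng, n_seqs=2, n_samples=3)
            dag = build_dag(ss)
            for p in enumerate_paths(dag, cap=50_000):
                aln = decode_path(p, dag.sequences)
                assert aln.sequences() == dag.sequences

    def test_cap_exceeded(self, crossover_samples):
        dag = build_dag(crossover_samples)
        with pytest.raises(SizeError, match="4"):
            enumerate_paths(dag, cap=3)


class TestSamplePath:
    def test_single_path_dag_is_deterministic(self):
        dag = build_dag(single(("ACG", "ACG")))
        table = estimate_marginals(dag)
        for seed in (0, 1, 99):
            assert sample_path(dag, table, "meanfield", seed) == (
                (1, 1),
                (3, 3),
                (5, 5),
            )

    def test_meanfield_frequencies_match_factored_probabilities(
        self, crossover_samples
    ):
        dag = build_dag(crossover_samples)
        table = estimate_marginals(dag)
        paths = enumerate_paths(dag, True)
        expected = np.array(
            [np.exp(path_log_prob(p, table, dag, "meanfield")) for p in paths]
        )
        rng = np.random.default_rng(7)
        counts = dict.fromkeys(paths, 0)
        n = 10_000
        for _ in range(n):
            counts[sample_path(dag, table, "meanfield", rng)] += 1
        observed = np.array([counts[p] for p in paths])
        res = sstats.chisquare(observed, expected * n)
        assert res.pvalue > 0.01

    def test_pair_mode_stays_on_observed_support(self, crossover_samples):
        dag = build_dag(crossover_samples)
        table = estimate_marginals(dag)
        observed = {
            tuple(np.ravel(codes).tolist())
            for codes in (
                ((1, 1), (3, 3)),
                ((1, 0), (2, 1), (3, 2), (4, 3)),
            )
        }
        rng = np.random.default_rng(8)
        for _ in range(200):
            p = sample_path(dag, table, "pair", rng)
            assert tuple(np.ravel(p).tolist()) in observed


class TestDagStats:
    def test_single_pairwise_alignment(self):
        dag = build_dag(single(("AC", "AC")))
        s = dag_stats(dag)
        assert s["n_columns"] == 2
        assert s["n_classes"] == 3  # source, middle, sink

    def test_crossover_fixture_counts(self, crossover_samples):
        dag = build_dag(crossover_samples)
        s = dag_stats(dag)
        assert s["n_columns"] == 6
        assert s["max_class_size"] == 2
        assert s["n_columns"] == pytest.approx(
            s["mean_in_degree"] * s["n_classes"]
        )

    def test_class_size_bound(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            n_seqs = int(rng.integers(2, 5))
            dag = build_dag(random_sample_set(rng, n_seqs=n_seqs, n_samples=5))
            assert dag_stats(dag)["max_class_size"] <= 2**n_seqs - 1

    def test_dot_export_mentions_unobserved_edges(self, crossover_samples):
        dag = build_dag(crossover_samples)
        dot = to_dot(dag)
        assert "digraph" in dot and "dashed" in dot
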
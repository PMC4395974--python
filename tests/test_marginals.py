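"""Marginal estimation, factored reconstructions, diagnostics."""

import math

import numpy as np
import pytest

from dagalign.dag import BOUNDARY, build_dag, enumerate_paths
from dagalign.errors import ContractError, SupportError
from dagalign.marginals import (
    estimate_marginals,
    external_mass,
    log_mse,
    meanfield_conditional,
    path_log_prob,
    total_probability,
)
from dagalign.msa_io import Alignment, SampleSet

from .conftest import random_sample_set


class TestEstimateMarginals:
    def test_frequencies(self):
        a1 = Alignment(ids=("a", "b"), rows=("AC", "AC"))
        a2 = Alignment(ids=("a", "b"), rows=("A-C-", "-A-C"))
        ss = SampleSet.from_alignments([a1] * 3 + [a2])
        table = estimate_marginals(build_dag(ss))
        assert table.p_column((1, 1)) == 0.75
        assert table.p_column((1, 0)) == 0.25
        assert table.n_samples == 4

    def test_single_sample_all_ones(self):
        ss = SampleSet.from_alignments(
            [Alignment(ids=("a", "b"), rows=("ACG", "ACG"))]
        )
        table = estimate_marginals(build_dag(ss))
        assert all(table.p_column(c) == 1.0 for c in table.counts)

    def test_plus_grouping_sums_codes_with_equal_image(self):
        # (3,2) and (3,4): same non-gap content (char 2 of a vs gaps in b)
        a1 = Alignment(ids=("a", "b"), rows=("AC", "A-"))  # (1,1),(3,2)
        a2 = Alignment(ids=("a", "b"), rows=("A-C", "-A-"))  # (1,0),(2,1),(3,2)->?
        ss = SampleSet.from_alignments([a1, a2])
        table = estimate_marginals(build_dag(ss))
        from dagalign.coding import encode_alignment

        codes2 = encode_alignment(a2)
        assert codes2 == ((1, 0), (2, 1), (3, 2))
        # column (3,2) occurs in both samples
        assert table.p_column((3, 2)) == 1.0

    def test_plus_at_least_column(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            table = estimate_marginals(
                build_dag(random_sample_set(rng, n_seqs=3, n_samples=5))
            )
            for code in table.counts:
                assert table.p_plus(code) >= table.p_column(code)


class TestMeanfieldConditional:
    def test_crossover_branches_are_half(self, crossover_samples):
        dag = build_dag(crossover_samples)
        table = estimate_marginals(dag)
        assert meanfield_conditional(table, dag, (1, 1)) == 0.5
        assert meanfield_conditional(table, dag, (1, 0)) == 0.5
        assert meanfield_conditional(table, dag, (3, 3)) == 0.5

    def test_single_path_dag_all_ones(self):
        ss = SampleSet.from_alignments(
            [Alignment(ids=("a", "b"), rows=("ACG", "ACG"))]
        )
        dag = build_dag(ss)
        table = estimate_marginals(dag)
        assert all(
            meanfield_conditional(table, dag, c) == 1.0 for c in dag.columns
        )

    def test_outgoing_conditionals_sum_to_one(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            dag = build_dag(random_sample_set(rng, n_seqs=3, n_samples=4))
            table = estimate_marginals(dag)
            for key, idx in dag.classes.items():
                if not idx.out_members:
                    continue
                total = sum(
                    meanfield_conditional(table, dag, c) for c in idx.out_members
                )
                assert total == pytest.approx(1.0, abs=1e-12)


class TestPathLogProb:
    def test_single_sample_own_path_probability_one(self):
        aln = Alignment(ids=("a", "b"), rows=("AC-G", "-CAG"))
        ss = SampleSet.from_alignments([aln])
        dag = build_dag(ss)
        table = estimate_marginals(dag)
        from dagalign.coding import encode_alignment

        path = encode_alignment(aln)
        for mode in ("meanfield", "pair"):
            assert path_log_prob(path, table, dag, mode) == pytest.approx(0.0)

    def test_crossover_meanfield_quarter_each(self, crossover_samples):
        dag = build_dag(crossover_samples)
        table = estimate_marginals(dag)
        for p in enumerate_paths(dag, True):
            assert math.exp(
                path_log_prob(p, table, dag, "meanfield")
            ) == pytest.approx(0.25)

    def test_pair_mode_rejects_recombined_paths(self, crossover_samples):
        dag = build_dag(crossover_samples)
        table = estimate_marginals(dag)
        recombined = [
            p
            for p in enumerate_paths(dag, True)
            if any(pair not in dag.pair_counts for pair in zip(p, p[1:]))
        ]
        assert recombined
        with pytest.raises(SupportError):
            path_log_prob(recombined[0], table, dag, "pair")


class TestTotalProbability:
    def test_normalisation_both_modes(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            dag = build_dag(
                random_sample_set(rng, n_seqs=int(rng.integers(2, 4)), n_samples=4)
            )
            table = estimate_marginals(dag)
            assert total_probability(dag, table, "meanfield") == pytest.approx(
                1.0, abs=1e-9
            )
            assert total_probability(dag, table, "pair") == pytest.approx(
                1.0, abs=1e-9
            )

    def test_matches_enumeration(self, crossover_samples):
        dag = build_dag(crossover_samples)
        table = estimate_marginals(dag)
        total = sum(
            math.exp(path_log_prob(p, table, dag, "meanfield"))
            for p in enumerate_paths(dag, True)
        )
        assert total == pytest.approx(total_probability(dag, table, "meanfield"))

    def test_single_path_exact_one(self):
        ss = SampleSet.from_alignments(
            [Alignment(ids=("a", "b"), rows=("AC", "AC"))]
        )
        dag = build_dag(ss)
        table = estimate_marginals(dag)
        assert total_probability(dag, table, "meanfield") == 1.0


class TestKLOptimality:
    def test_empirical_pair_conditionals_minimise_kl(self):
        """Among first-order factored distributions on the observed support,
        the empirical pair conditionals are KL-closest to the empirical
        path distribution (checked against perturbed conditional tables)."""
        rng = np.random.default_rng(3)
        ss = random_sample_set(rng, n_seqs=2, length=(3, 5), n_samples=6)
        dag = build_dag(ss)
        table = estimate_marginals(dag)

        from dagalign.coding import encode_alignment

        # empirical path distribution
        counts: dict = {}
        for aln in ss.alignments:
            p = encode_alignment(aln)
            counts[p] = counts.get(p, 0) + 1
        n = len(ss.alignments)
        empirical = {p: c / n for p, c in counts.items()}

        def kl(cond_fn):
            tot = 0.0
            for p, w in empirical.items():
                logq = 0.0
                for prev, nxt in zip((BOUNDARY, *p), (*p, BOUNDARY)):
                    logq += math.log(cond_fn(prev, nxt))
                tot += w * (math.log(w) - logq)
            return tot

        def empirical_cond(prev, nxt):
            num = dag.pair_counts.get((prev, nxt), 0)
            denom = dag.n_samples if prev is BOUNDARY else table.counts[prev]
            return num / denom

        base_kl = kl(empirical_cond)
        assert base_kl >= -1e-12

        # perturbed conditional tables, renormalised over observed successors
        succs: dict = {}
        for (a, b), _ in dag.pair_counts.items():
            succs.setdefault(a, []).append(b)
        for _ in range(100):
            noisy = {}
            for a, bs in succs.items():
                w = np.array(
                    [dag.pair_counts[(a, b)] for b in bs], dtype=float
                ) * rng.uniform(0.3, 3.0, size=len(bs))
                w /= w.sum()
                for b, v in zip(bs, w):
                    noisy[(a, b)] = v

            assert kl(lambda p_, n_: noisy[(p_, n_)]) >= base_kl - 1e-9


class TestLogMse:
    def test_identical_zero(self):
        assert log_mse([-1.0, -2.0], [-1.0, -2.0]) == 0.0

    def test_unit_shift(self):
        assert log_mse([-1.0, -2.0], [-2.0, -3.0]) == 1.0

    def test_hand_example(self):
        assert log_mse([-2.0, -3.0], [-1.0, -3.0]) == 0.5

    def test_length_mismatch(self):
        with pytest.raises(ContractError):
            log_mse([-1.0], [-1.0, -2.0])


class TestExternalMass:
    def test_single_path_dag_equals_exp_posterior(self):
        from dagalign.msa_io import SequenceRecord
        from dagalign.pairhmm import (
            PairHMMParams,
            alignment_log_posterior,
            forward_total,
            true_edge_scorer,
        )

        params = PairHMMParams(delta=0.1, epsilon=0.3, sigma=0.05, tau=0.05)
        aln = Alignment(ids=("a", "b"), rows=("AC-G", "-CAG"))
        dag = build_dag(SampleSet.from_alignments([aln]))
        a, b = aln.sequences()
        mass = external_mass(
            dag,
            true_edge_scorer(params, a, b),
            forward_total(params, a, b),
        )
        assert mass == pytest.approx(
            math.exp(alignment_log_posterior(params, aln)), rel=1e-9
        )
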
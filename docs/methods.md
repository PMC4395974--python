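# Methods

## The problem

Multiple sequence alignments are usually treated as fixed inputs, but for
diverged sequences the alignment itself is highly uncertain, and errors
propagate into everything estimated from it (trees in particular).
Bayesian alignment samplers produce a set of plausible alignments instead
of one, but the raw sample set is hard to use: the alignment space is so
large that each sampled alignment is typically seen once, so sample
frequencies say nothing about posterior probabilities.

`dagalign` addresses this by combining the samples into an *alignment
column DAG*. Columns — not whole alignments — are the unit of estimation:
a column recurs across many samples, so its marginal probability can be
estimated well even when whole-alignment frequencies cannot.

## Column coding and the DAG

A column over N sequences is coded as an N-tuple: entry `2j-1` when the
row holds its sequence's j-th character, `2j` when it holds a gap sitting
after character j (0 before the first character). Gaps are therefore
distinguished by position; this is what keeps the graph sparse and
acyclic (treating all gaps as equivalent would make it maximally dense).
Each column sits between two DP cells, `f_pred` (entries rounded down to
even) and `f_succ` (rounded up), and column X' may immediately precede X
iff `f_succ(X') = f_pred(X)`. Every source-to-sink path is a valid global
alignment of the same sequences. The code is recovered from its cells as
`(f_pred + f_succ)/2`.

Columns store only their two flanking cells ("equivalence classes"), so
storage is O(number of columns) and every DP below runs in linear time
via per-class partial sums/maxima. A class holds at most `2^N − 1`
columns. Topological order is obtained by sorting cells by coordinate sum
(which strictly increases along edges), with lexicographic tie-break for
reproducibility — no graph traversal needed.

Two sampled alignments that share a column with different neighbours
create an *interchange* (recombined paths through the shared column);
two alignments that pass through the same DP cell without sharing a
column create a *crossover* (recombined paths containing adjacencies
never observed). Both multiply the number of alignments encoded in the
DAG far beyond the number of samples.

## Marginals and factored posteriors

With n samples, the column marginal is `count/n` (duplicated samples
count independently; optional per-alignment weights replace the uniform
weighting). Two first-order factorisations reconstruct alignment
probabilities:

* **pair mode** uses empirical adjacent-pair conditionals
  `p(X|X') = p(X',X)/p(X')`. It is exact for first-order HMM alignment
  models, and among all first-order factorisations on the observed
  support it minimises the KL divergence from the empirical path
  distribution — but it assigns weight zero to unobserved adjacencies,
  so crossover paths are excluded and pair counts need many samples.
* **mean-field mode** averages the conditional over all possible
  predecessors: `p(X) / Σ p(X')` over columns X' feeding X's predecessor
  cell. Only single-column marginals are needed, crossovers become
  traversable, and the one-step recursion is cheaper. It is exact for
  site-independent models (e.g. a pair-HMM with equal gap-open, extend
  and switch probabilities), and in practice more accurate at small
  sample sizes because column marginals are estimable long before pair
  marginals are.

Boundary convention: the virtual source and sink cells are never
materialised as columns. In pair mode the first factor is the observed
frequency of starting with the path's first column, and a final
conditional step to the sink is included; in mean-field mode the source
class has unit mass and no sink factor is needed. With these conventions
both factorisations sum exactly to one over their supports — a direct
consequence of integer flow conservation at every interior cell, which
holds exactly because counts are kept as integers and probabilities are
formed lazily. No pseudocounts are used anywhere; pair mode simply
restricts support.

The quality of a reconstruction is measured by the mean squared error of
log posteriors over an evaluation set of alignments, against the exact
values from the pair-HMM oracle.

## Summary alignments

The **MAP path** maximises the factored log posterior by a max-sum DP.

The **minimum-risk summary** minimises posterior expected loss for
column-additive losses. Up to a constant the risk of an alignment is
`Σ_j [g − p_f(X_j)]`, where `p_f` is the column marginal (`C` mapping,
gap positions distinguished) or the gap-agnostic grouped marginal
(`C+` mapping, the marginal summed over all columns with the same
non-gap characters, hence `p_C+ ≥ p_C`), and
`g = λ_FP/(ρ_TP + λ_FP) ∈ [0,1]` penalises alignment length in
proportion to the false-positive penalty. Minimising the risk is a
maximum-weight-path problem with column weight `p_f − g`, solved in time
linear in the number of DAG columns; crossovers are always allowed since
the objective is column-additive. A per-column weight hook supports
penalties that depend on the column (e.g. its number of non-gap
characters); no default weighting is claimed beyond uniform.

Defaults: `C+` mapping with `g = 0.5`, the all-round setting that
penalises false positives and negatives equally. `g = 0` maximises the
expected plain (non-modeller) accuracy scores. Modeller-style objectives
(normalised by predicted length) are deliberately not offered as
optimisation targets — their per-column contribution depends on the
unknown final length, so the DP cannot optimise them — but are reported
as evaluation metrics. Ties between equal-scoring predecessors are real
(distinct paths can share a C+ score) and broken towards the
lexicographically smallest column code.

## Accuracy metrics

C-score: fraction of reference columns reproduced exactly. C+-score: the
same on gap-agnostic column images (the classic "column score").
Modeller variants divide by predicted rather than reference length. AMA:
fraction of residue-level homology statements (aligned-to-residue-k or
aligned-to-gap, over all ordered sequence pairs) agreeing with the
reference. The rank score places a summary's accuracy within the
samples' accuracy distribution — 1 means better than every sample; ties
take midrank (only the endpoints are pinned by convention; midrank is
this package's choice). Robinson-Foulds distances are computed by
dendropy (bipartitions in exactly one tree, max `2(n−3)`).

## The pair-HMM oracle

A three-state affine-gap pair-HMM (match M, inserts X/Y) provides exact
ground truth for pairwise experiments: gap open δ (M→X, M→Y), extension
ε, direct switch σ (X↔Y), shared termination τ, with the start state
behaving like M. δ = ε = σ makes every state's outgoing distribution
identical, i.e. a fully site-independent process — the regime in which
the mean-field factorisation is exact. Match emissions are the
time-reversible joint `π_a P(b|a, t)` of a substitution model (uniform
nucleotide by default; Dayhoff amino-acid preset); gap states emit
equilibrium frequencies.

Forward recursion gives the total probability over all global
alignments (verified against exhaustive enumeration for short
sequences); forward-backward gives exact column marginals;
stochastic traceback draws i.i.d. posterior alignments. The
`true_edge_scorer` assigns every DAG adjacency its exact
transition-times-emission log weight, so a forward DP over the DAG
(crossovers included) measures exactly how much of the true posterior
mass the DAG covers.

All DP is in log space; column states are read off code parity
(odd/odd = M, odd/even = X, even/odd = Y).

## Substitution models

The Dayhoff (1978) amino-acid model is built from the published
exchangeability coefficients and equilibrium frequencies as distributed
with PAML (`dayhoff.dat`) and phangorn, embedded as constants in
`_dayhoff.py`; the rate matrix is normalised to one expected substitution
per site. A Jukes-Cantor-type uniform model over any alphabet is
provided for nucleotide work. Transition matrices are matrix
exponentials, cached per branch length.

## Tree posteriors over the DAG

Column log-likelihoods come from Felsenstein pruning with gaps treated
as missing data (partial-likelihood vectors of ones); no gap-as-extra-
state option is offered. On one alignment the tree posterior factorises
over columns. Over the DAG, a forward recursion accumulates per column
the product of its likelihood, its factored conditional (mean-field by
default, for the larger effective sample size), and the summed mass of
its predecessors; the value at the sink is the tree likelihood summed
over every alignment in the DAG, weighted by its reconstructed
probability. Computation is in log space with per-class log-sum-exp;
normalisation happens only at the topology level. Topology posteriors
group candidate trees by their unrooted topology (set of non-trivial
bipartitions), average marginal likelihoods within each group (uniform
prior), and normalise across groups. Trees are inputs throughout; no
tree search or branch-length optimisation is attempted.

## Synthetic data generator

`simulate_msa` evolves a root sequence (Poisson length around
`mean_length`) down a tree: per branch of length t, each site
substitutes with probability `1 − exp(−rate·t)` to a uniformly chosen
different character, and indel events arrive with Poisson count
`indel_rate · t · L`, geometric lengths (mean `mean_indel_length`),
uniform positions; insertions create fresh homology columns, spliced
into a global column order so the true alignment is known exactly.
Defaults, chosen once as plausible for a desk-scale nucleotide study:
5 sequences, mean length 100, substitution rate 1.0 per site per unit
branch, indel regimes low/medium/high = 0.02/0.05/0.10 events per site
per unit branch, mean indel length 3, random trees with uniform
(0.05, 0.3) branch lengths.

`perturb_samples` stands in for an MCMC sampler: seeded local gap-shift
moves (swapping a random gap/character boundary within a row) applied to
the truth, `Poisson(strength · L)` moves per sample. Row contents are
preserved by construction, so every sample is a valid alignment of the
true sequences; repeated shifts merge and split gap runs, and across
samples the moves produce interchanges and crossovers. What this
emulates is the *structure* of a posterior sample set (valid, diverse,
centred on the truth); it is *not* statistically faithful to any
model's posterior — it has no column-dependent uncertainty profile, no
autocorrelation, and perturbation intensity is uniform along the
alignment. Tests passing on these fixtures therefore demonstrate
correctness of the DAG machinery and the qualitative behaviour of the
summaries, not calibrated performance on real MCMC output.

## Benchmarks and problem sizes

The seeded experiments in `dagalign.benchmarks` (used by the test suite
and `scripts/acceptance.py`) run at deliberate desk scale so a full
reproduction takes about a minute on one core:

* posterior reconstruction: pairwise sequences of length ~100, DAGs from
  100 vs 2000 exact pair-HMM samples, 5 replicates, both factorisations,
  affine and site-independent parameter settings;
* posterior-mass coverage: length-60 pair, DAGs from 10–300 samples;
* summary quality: 10 benches of 5 sequences (medium indel rate,
  200 perturbed samples), min-risk (C+, g = 0) rank-scored against the
  samples under the C+ metric;
* topology recovery: 5 quartet benches on a fixed resolvable quartet
  (internal branch 0.1, external 0.15, length 200), 51 candidate trees
  spanning all three resolved topologies with varied branch lengths;
* scaling: min-risk timed on DAGs of roughly 1.5k–12k columns from
  doubling sequence lengths, log-log slope fitted.

## Numerical choices

Counts are exact integers; probabilities are formed lazily, so
conservation checks are exact. Path counting uses Python's
arbitrary-precision integers (counts beyond 10^100 arise quickly).
Log-sum-exp with max-shift everywhere a sum of exponentials is needed;
normalisation diagnostics use a 1e−9 tolerance. Ties in the DPs break
towards the lexicographically smallest code. All randomness flows
through `numpy.random.default_rng` seeded explicitly; sampling routines
accept either a seed or a Generator.

## Known limitations

* Local-alignment conditional marginals are out of scope; only global
  alignments are handled.
* The DAG is rebuilt from scratch when samples are added (no streaming).
* Pair mode cannot score paths containing unobserved adjacencies (by
  design — that is the factorisation's support).
* The perturbation generator is structural, not calibrated (see above);
  rank-score results on it say nothing quantitative about StatAlign-style
  samplers.
* Topology averaging within a group assumes the supplied tree set is a
  reasonable sample of branch lengths per topology; uniform averaging of
  marginal likelihoods is used regardless of how the trees were obtained.
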
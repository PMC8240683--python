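# Methods

`commfit` detects overlapping communities in a weighted undirected network
(the motivating case: protein complexes in confidence-weighted
protein-interaction networks) by *learning* what a community looks like from
known examples, instead of assuming it is a dense subgraph.

## Model and procedure

**Community fitness function.** The classical fitness of a subgraph C is the
density difference f(C) = δ_int(C) − δ_ext(C) with δ_int = m_c / (n_c(n_c−1)/2)
and δ_ext = (# boundary edges) / (n_c(n − n_c)), where n_c and m_c are the node
and induced-edge counts of C and n the network size. Real communities are not
always dense (stars, chains, and hybrids occur), so the package replaces the
fixed formula with the positive-class probability of a binary classifier
trained to separate known communities from random walks, each represented by
an 18-dimensional topological embedding. The density baseline is retained as
`fitness.DensityScorer` (rescaled to [0, 1] via (f + 1)/2 so the search's 0.5
threshold corresponds to a positive density difference).

**Embedding.** The 18 features are computed on the induced subgraph only:
node count, edge count, unweighted density, total / mean / max / variance of
edge weights, mean weighted degree, max / median / variance of degree,
mean / max / variance of local clustering, degree assortativity, largest
eigenvalue of the weighted adjacency, unweighted diameter, and transitivity.
This list is this package's canonical definition, fixed and versioned
(`features.FEATURE_VERSION`); models embed the manifest they were trained with
and refuse to score under a mismatch. Degenerate statistics (variance of one
value, assortativity of a regular graph) are defined as 0 so every connected
community embeds to a finite vector. Boundary-based features are deliberately
excluded: the classifier replaces the δ_ext term, and keeping the embedding
internal makes it independent of the rest of the network.

**Data preparation.** Known communities are induced on the network; members
absent from it are dropped, then communities with fewer than 3 nodes,
internally disconnected ones, and duplicates are removed. Highly similar
communities (Jaccard ≥ j, default 0.6) are merged by an in-order pass
algorithm that always merges a community with its highest-overlap partner and
appends the union to the end of the list, repeating passes until a pass makes
no merge (guard: 100 passes). The survivors are split 70–30 into *edge
independent* train and test sets: rounds of two-direction transfers (a
community sharing an induced edge with the other set moves there immediately)
followed by end-of-list rebalancing toward the target ratio. Our rebalancing
only moves a community whose move preserves independence; the unguarded
variant can oscillate forever on a two-community counterexample, while the
guarded one converges on the same inputs and still errors out (advising a new
random split) when no independent split is reachable.

**Negatives.** Non-communities are random walks grown by repeatedly adding a
uniformly random member of the subgraph's boundary, scale_factor (> 1, default
1.1) times the number of positives, with target sizes spread (almost) equally
over the positive size range (or matched to the positive histogram). Walks
with Jaccard ≥ 0.5 against any positive are removed; this threshold is this
package's stand-in for "walks resembling communities" and is configurable.
Negatives are split 70–30 at random; the positive size range is computed from
all positives before splitting.

**Training.** The default `grid` backend fits three scaled pipelines —
regularized logistic regression, random forest, gradient boosting, each behind
a standardizing scaler, class-weighted for the scale-factor imbalance — and
keeps the one with the best mean 5-fold cross-validated average precision
(area under the PR curve), refit on the full training matrix. An `automl`
backend delegates the same contract to TPOT (population and generations 50)
when installed and falls back to the grid with a warning otherwise. The native
probability output is used without extra calibration.

**Search.** Each seed (every node by default; known-community nodes, N random
nodes, or maximal cliques are alternatives) grows independently. The first
step always adds the neighbor with the highest connecting edge weight.
Later steps use one of four heuristics: greedy edge weight (model consulted
only for the stopping rule, and that check can be disabled); ε-greedy (with
probability ε a uniformly random neighbor, else the candidate whose addition
the model scores highest); and ε-greedy plus a stage-two accept/reject rule —
iterative simulated annealing (ISA), which accepts a score-worsening addition
with probability exp((S_new − S_old)/T) at T = T0·αⁱ (α > 1 heats rather than
cools; the temperature updates every iteration regardless of acceptance), or
pseudo-metropolis, which accepts with constant probability k. A rejected or
below-threshold addition removes exactly the last-added node, so the subgraph
is connected at all times. Stopping: no boundary neighbors; model score below
0.5 (remove last node first); no score improvement for `improvement_window`
(default 10) iterations (stage-two heuristics); or `max_steps` additions.
`max_steps` is interpreted as the number of additions per seed; the "smart"
default is the largest known-community size at or below the Tukey fence
Q3 + 1.5·IQR, which ignores outlier sizes. Candidate pruning for large
boundaries: a uniform sample of t1 (default 500) neighbors, and in the greedy
branch the t2 (default 50) with the largest max connecting edge weight, so the
sort stays O(t1 log t1) and model evaluation dominates.

Per-seed random substreams are keyed by (global seed, CRC-32 of the sorted
seed node set), so results are byte-identical for any worker count; workers
are joblib threads (the per-step scikit-learn predictions release the GIL, and
threads avoid per-process model/graph serialization).

**Post-processing.** Two-node candidates are removed. Overlapping candidates
are merged with the same pass structure as data cleaning, except that the two
originals and their union are scored and only the single best-scoring of the
three survives (ties favor the union). The overlap measure is either Jaccard
or the neighborhood-affinity form |A∩B|²/(|A|·|B|) — the latter is this
package's concrete definition of the Qi-style overlap, default threshold
0.375. In the non-overlapping regime (threshold → 0) no two outputs can merge
into a higher-scoring community when unions score no better than their parts.

**Evaluation.** Besides the thresholded match F1 (a pair matches when both the
learned-node precision and known-node recall reach t, default 0.5), MMR, and
Sn/PPV/SPA, the package computes three matching-based measures built on the
F-similarity sim_F(C_k, C_l) (harmonic mean of node precision and recall):

- **FMMF** — exact maximum-weight one-to-one matching of known to learned
  communities (`scipy.optimize.linear_sum_assignment`); matching weight W
  gives recall W/|K|, precision W/|L|. One-to-one matching penalizes both
  redundancy (duplicates halve precision, recall unchanged) and splitting a
  known community (only one fragment is matched).
- **CMFF** — mean over each set of the best F-similarity against the other
  set, combined harmonically; an instance of a pluggable best-match framework
  (`sensitive_prf`) that accepts any pair similarity.
- **UnSPA** — Sn/PPV with every community weighted equally: Sn_u averages
  max_l |C_k∩C_l|/|C_k| over known communities (removing the big-community
  bias of Sn), PPV_u averages max_k |C_k∩C_l|/|C_l| over learned communities
  (so spurious nodes, invisible to PPV, lower it).

A co-membership edge PR curve scores each node pair by the maximum fitness of
a learned community containing it, with recall measured against all known
co-membership pairs.

## Synthetic benchmarks

The **clique toy** is 10 disjoint unit-weight cliques (sizes 3–8), each a
known community; a correct pipeline must recover them exactly. On this graph
every connected subgraph is itself a clique, so random-walk negatives coincide
with sub-communities and a discriminative classifier is ill-posed; the toy
preset therefore searches with the density baseline, and the pipeline skips
classifier training only when the negative set degenerates *and* the density
scorer was requested (otherwise it raises).

The **planted benchmark** embeds 50 communities (sizes 4–9; 40 % cliques,
20 % stars, 20 % chains, 20 % hybrids = path plus 0.5-probability chords)
among 100 background nodes with noise edges at probability 0.03. Intra
weights ~ truncated normal(0.8, 0.1), background ~ (0.1, 0.05), mimicking the
separation between confident and incidental interaction scores; communities
share a node with an earlier one with probability 0.1. These defaults were
chosen once as a realistic desk-scale stand-in. What it does *not* emulate:
heavy-tailed degree distributions, correlated noise, missing edges inside true
communities, or communities of a size the model never saw — so a high average
precision here shows the pipeline is correct and the features informative, not
that real-network performance will match.

Reported problem sizes (10 cliques; 50 planted communities; 20 search seeds;
200 matching-oracle pairs; 10,000 acceptance-rule trials) keep the whole suite
and the acceptance script in the minutes range on one core.

## Numerical choices and edge cases

- Duplicate input edges keep the maximum weight (conservative for
  confidence-weighted edges); self-loops and non-positive weights are dropped.
- Tie-breaks are deterministic everywhere: equal-scoring candidate neighbors
  and equal-weight first steps pick the lexicographically smallest node id;
  equal-overlap merge partners pick the earliest list position; merge-variant
  score ties favor the union.
- Quartiles for the outlier-robust step cap use linear interpolation.
- The assignment solver's optimum is unique in value, not in matching; the
  returned matching is sorted by index for reproducibility.
- `accept_step` errors on non-positive temperature; `SearchParams` validates
  ε ∈ [0,1], t2 ≤ t1, max_steps ≥ 1.

## Known limitations

- The 18-feature list is this implementation's definition; swapping in an
  alternative list is a versioned, config-level change.
- The AutoML backend is untested offline (TPOT absent); its contract is
  covered by the fallback path.
- `parameter_sweep` re-runs the pipeline per grid point; with a fixed seed the
  deterministic grid backend retrains an identical model each time, which is
  wasteful at scale but simple and correct at desk scale.
- Real-data experiments (human/yeast interactomes with curated complex
  catalogs) need externally downloaded inputs: run `prepare-graph` with the
  published edge-weight cutoff, `prepare` with merge j = 0.6, then train,
  search (ε = 0.01 with ISA T0 = 1.75, α = 0.005, or pseudo-metropolis
  k = 0.1), merge at the published overlap threshold, and `evaluate`; expect
  a few points of F1 variation from the stochastic search.
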
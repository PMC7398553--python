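# Methods

## Model and target quantity

The epidemic model is the continuous-time Markovian SIR process on a simple
undirected connected graph. Time is measured in units of the mean recovery
time, fixing the recovery rate at ν = 1 and leaving the transmission rate β
(per S–I edge) as the only epidemic parameter. Because final outbreak size
depends only on the *order* of events, not their timing, the solver works
with the embedded jump chain: from configuration C (an S/I/R assignment to
all nodes), each of the M_SI S–I edges fires an infection with probability
β/(βM_SI + N_I) and each of the N_I infected nodes recovers with
probability 1/(βM_SI + N_I).

The target is the expected outbreak size Ω_i(β): the expected number of
ever-infected nodes when node i is the sole initial infective. It is
computed exactly by breadth-first unfolding of the configuration tree with
merging: the frontier is a hash map from configuration to probability mass;
identical configurations reached along different paths are merged by
summing mass. Merging at equal depth is sound because a configuration fixes
its own event count (N_I + 2N_R − 1), which the solver asserts. Absorbing
configurations (N_I = 0) contribute mass × N_R to Ω immediately and leave
the frontier. All nine β values ride through one traversal as a per-β mass
vector, since the reachable set does not depend on β.

Assumptions inherited from the model: static contact network, exponential
waiting times, no reinfection, single seed. Seeds in the same automorphism
orbit provably give equal Ω, so the solver runs once per orbit.

## Ensemble

The "graph model" is the set of all nonisomorphic connected simple
undirected graphs of fixed N, each class counted once with equal weight.
Enumeration proceeds by extending every (N−1)-node graph with a new node
joined to each subset of old nodes, deduplicating by canonical label, then
filtering to connected graphs; the result is sorted by canonical label so
downstream seeds fully determine every split. Canonical labels come from
iterated neighbourhood colour refinement followed by exhaustive
minimisation of the adjacency bitstring over the orderings the refinement
permits — exact for all graphs, and fast because refinement leaves few
symmetric cells at these sizes. In-process enumeration is supported to
N = 8 (11 117 classes); the N = 9 and N = 10 ensembles (261 080 and
11.7 million classes) are meant to be generated externally and imported as
graph6, which the solver and featurizer consume unchanged. Tests
cross-check class counts against labeled brute-force enumeration (N ≤ 6)
and the published graph atlas (N = 7).

## Predictors and normalization

Eight predictors per record: degree/(N−1); the principal adjacency
eigenvector (power iteration on A + I so bipartite spectra converge; unit
2-norm); PageRank x = D(D − αA)⁻¹1 with α = 0.85, normalized to unit sum;
Katz x = (I − αA)⁻¹1 with α = 0.1 (validity αλ₁ < 1 checked per graph),
unit 2-norm; closeness (N−1)/Σd; betweenness divided by (N−1)(N−2)/2;
coreness/(N−1); edge density 2M/(N(N−1)). PageRank is implemented as the
printed matrix formula above (a dense linear solve), not the teleportation
random-surfer recursion — the two differ in general and the matrix form is
the definition this package reproduces. Betweenness and coreness are
scaled by their theoretical maxima rather than per-graph maxima: per-graph
scaling would force a 1.0 into every graph and destroy the cross-graph
comparability of raw values that is the entire point of the analysis.

## Records, duplicates and the learning protocol

A record is one node of one graph: eight features plus Ω at each of the
nine β values (672 records at N = 6). Before a regression on a selected
feature subset and one Ω(β) target, exact duplicate rows are removed
(first occurrence kept) so no test row can equal a training row; rows equal
on features but differing in Ω are retained — they are the irreducible
error of that feature set. Duplicate equality is evaluated after rounding
to 12 decimals: records of automorphically equivalent nodes are
mathematically identical but spectral centralities can differ in the last
floating-point digit, and bit-exact comparison would silently leak such
twins across the split. 12 decimals is orders of magnitude below any
difference of scientific interest here (solver agreement is 1e-10, feature
differences of interest are ≥ 1e-6).

Each experiment: a seeded uniform dev/test split (default development
fraction 0.75, appropriate in the scarce-data regime of small N; the
development size can instead be tuned from a ten-point learning curve —
chosen as the smallest size whose validation score is within 0.005 of its
maximum while the train–validation gap is under 0.02, an operationalization
of "close and levelled off"); ten-fold cross-validated grid search on the
development data; refit on all development data; R² = 1 − S_res/S_tot on
the held-out test rows. Grids: random forest with trees ∈ {5, 10, 15, 20}
and minimum leaf fraction ∈ {10⁻², 3·10⁻³, 10⁻³, 3·10⁻⁴, 10⁻⁴}; SVR with
kernel ∈ {linear, RBF}, C ∈ {0.1, 1, 10, 100}, ε = 0.01, γ scaled from
feature count and variance. Grids are ordered simple-to-complex so exact
score ties resolve toward the simpler model. Permutation significance uses
the (1 + C)/(1 + n) estimator over ten-fold cross-validated scores with
permuted targets; with 100 permutations the smallest attainable p is 1/101.

All randomness in an experiment derives from one integer via a seed
sequence (split, fold shuffling, forest bootstrap, permutations), so forest
results are bit-reproducible and SVR results reproducible to numerical
tolerance.

## Prediction maps

Maps evaluate a tuned SVR (the smooth, interpretable regressor) trained on
a feature pair at every centre of a default 100 × 100 grid over [0, 1]².
The achievability mask marks a cell attainable iff at least one observed
(feature₁, feature₂) record falls inside it — the simplest faithful
reading of "regions devoid of data points"; the mask depends only on the
deterministic dataset, not on the regressor seed. Size series plot Ω/N so
different N are comparable.

## Numerical choices

Probability mass is float64; the state space at desk scale (≤ 3^N
configurations) keeps accumulated rounding far below the 1e-10 oracle
tolerance, and an exact-rational mode (Fractions, dyadic β exact) exists
for closed-form checks on tiny graphs. The solver asserts conservation
(active + absorbed mass = 1 per β, 1e-12) at every depth. No mass pruning
is ever applied — every configuration is retained regardless of
probability, keeping the computation exact. Eigenvector iteration runs to
1e-14 with the Perron sign convention. The absorbing-Markov oracle builds
all 3^N configurations and solves the value equations sparsely; it is
restricted to N ≤ 6.

## Problem sizes

The test suite and the acceptance script run the full pipeline at N = 6
(112 graphs, 672 records), centrality invariants over every connected
graph to N = 7 (995 graphs), solver-vs-oracle equivalence over every
connected graph to N = 5 at all nine β, and a 9-node graph6-import
demonstration. These sizes give exhaustive coverage of the claims the
package tests while keeping a complete run in the minutes range on one
CPU; the identical code paths accept larger graph6 inputs, where full
N = 10 sweeps are a matter of compute, not code.

## Limitations

Desk-scale qualitative findings (which features predict best, how
predictability moves with β) are demonstrated at N = 6–7; absolute R²
values shift with N, so they are indicative, not equal to the large-N
values. The ensemble weights every isomorphism class equally — it is an
exploration of the space of possible contact structures, not a model of
empirically sampled networks, and says nothing about noisy or incomplete
network data. SIS/SEIR dynamics, non-Markovian recovery, weighted or
directed graphs, and temporal networks are out of scope.
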
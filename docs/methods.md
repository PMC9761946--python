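# Methods

This note documents the models, algorithms and design choices behind
`bnmiss`, in the spirit of a package methods appendix.  It states no
empirical result that the test suite or `scripts/acceptance.py` do not
themselves compute.

## Data model

The universal data currency is the `CategoricalTable`: an n x p matrix of
integer level codes with declared level sets per column and a boolean
missingness mask.  When a table is produced by amputation, the true code is
retained underneath the mask so imputation accuracy can later be scored
against ground truth; learners only ever see the observed view
(`observed_codes()`, masked cells coded -1), and the ground truth is exposed
through a single privileged accessor used by the evaluation layer.  Tables
serialise to CSV with missing cells as empty fields (`NA` also accepted on
read); networks serialise to GraphML, adjacency JSON, and the bracketed
modelstring form (`[A][B|A][C|A:B]`) used in the R ecosystem.

## Random networks and sampling

`generate_random_dag` draws a uniformly random topological order, then for
each node an in-degree uniform on {0, ..., min(3, #predecessors)} and a
uniform parent subset.  This guarantees acyclicity and the in-degree cap by
construction and is exactly reproducible from a seed; the generator name is
recorded in `GENERATOR_NAME` so a different DAG sampler can be swapped in.
Connectivity is not enforced by default (a 2-node network may legitimately
have no edge); `connected=True` enables rejection sampling.  All simulation
nodes share 3 levels.

CPT rows are symmetric Dirichlet draws: concentration 0.5 for nodes with
parents (skewed rows, hence strong parent-child dependence) and 5 for root
nodes (near-uniform marginals).  Sampling is ancestral: nodes are drawn in
topological order given their parents' sampled values, vectorised via
row-wise inverse-CDF lookup.

## Amputation

`ampute` follows the multivariate-amputation scheme: a pattern matrix (one
row per pattern, default one-variable-per-pattern), a pattern frequency
vector (default uniform), and per-pattern weight vectors.  Each data row is
assigned one pattern; within a pattern subset a row becomes incomplete

* with constant probability equal to the target proportion (MCAR), or
* with probability `expit(shift + z(score))` where the score is the
  weighted sum of standardized level codes — weights 1 on all *other*
  variables (MAR) or 1 on the variable's *own* value (MNAR) — and the shift
  is solved by bisection so the mean probability equals the target within
  1e-6 (the "higher score, higher missingness" allocation).

Consequences worth knowing: the target proportion is the expected fraction
of *incomplete rows*, so with p one-variable patterns each variable loses
about proportion/p of its cells; level codes enter the score in declared
level order; a zero-variance column contributes nothing to the score.

## Scores and search

BDe is the BDeu marginal likelihood with the imaginary sample size (default
1) split uniformly over the q_i * r_i cells of each family.  BDs replaces
q_i by the number of parent configurations actually observed.  BIC is the
multinomial log-likelihood minus `0.5 * log(n)` per free parameter (the
coefficient is configurable).  Unobserved parent configurations contribute
nothing to any score, so sufficient statistics are only materialised for
observed configurations — this keeps large candidate parent sets cheap.

Tabu search climbs over single-edge additions, deletions and reversals that
preserve acyclicity, re-scoring only the one or two families a move touches
(family scores are memoized).  The tabu list holds the last 10 *structures*
visited; a move recreating one is forbidden unless it beats the best score
seen (aspiration).  A move-based list (forbidding recently undone moves) was
tried first and cycled on small problems, missing the exhaustively
enumerated optimum on a few percent of 3-variable datasets; the
structure-based list fixes this and matches the exhaustive optimum on all
tested datasets.  Up to 10 consecutive worsening moves are taken past a
local optimum; the best structure visited is returned.  Move enumeration and
tie-breaking are lexicographic, so the search is deterministic.

CPDAG conversion orients v-structures and closes under the standard
orientation-propagation rules; partially directed inputs are first extended
to a consistent DAG (Dor-Tarsi), making the conversion idempotent.
Skeletons drop orientation entirely.

## Missing-data strategies

*Complete-case*: listwise deletion, then tabu search.  Zero remaining rows
raises a dedicated error that batch runners record as a missing result.

*MICE*: missing cells are initialised by draws from each variable's observed
marginal; then for 5 cycles, in column order, each variable's imputed cells
are re-drawn from a multinomial logistic regression of that variable on
one-hot encodings of all other (currently completed) variables, fitted on
rows where the variable is observed.  Fits are ridge-stabilised (C=1) to
tame separation; degenerate fits (single observed level, solver failure)
fall back to marginal draws for that cycle and are logged.  One completed
dataset feeds structure learning; pooling across multiple imputations is out
of scope.

*Structural EM* (hard assignment): start from the empty network with
available-case marginal parameters; iterate (at most 5 times) an E-step that
fills each missing cell from its parents' values under the current network —
nodes visited in topological order so parents are filled first; parentless
nodes take the marginal — and an M-step that re-learns structure by tabu
search *warm-started from the previous structure* and refits parameters by
maximum likelihood (unobserved parent configurations get uniform rows).
Iteration stops early when the structure repeats.  The E-step prediction is
the conditional mode with ties to the lowest level index, making SEM
deterministic given the data; a seedable `e_step_method="draw"` variant
samples from the conditional instead and is what the survey stage's repeated
runs use, since averaging identical runs would be vacuous.  The per-iteration
network score on the iteration's own completed table is recorded; hard
assignment does not guarantee monotonicity, so decreases are flagged in the
diagnostics rather than asserted.

## Evaluation and aggregation

Structure recovery is scored on skeletons: TP/FP/FN set arithmetic with
precision TP/(TP+FP) and recall TP/(TP+FN).  An empty learned skeleton has
undefined precision, recorded as missing and excluded from means with
exclusion counts reported (a 0 or 1 convention would be arbitrary).
Imputation accuracy is the Hamming distance over masked cells between the
completed table and the ground truth.

The aggregation layer groups replicates into cells (variable-count group x
proportion x sample size x mechanism; the six variable groups partition
2-20), runs a one-way ANOVA across methods per cell, Bonferroni-corrects
within each (metric, sample size, mechanism) panel, follows significant
cells with Tukey HSD, and compares Hamming distances with t-tests.

## Survey fixture and consensus stage

The synthetic survey fixture emulates the shape of linked biomedical/social
data on older adults: 29 categorical variables (2-4 levels) in five planted
thematic blocks, densely linked within blocks (chains plus skip edges) and
bridged by single between-block edges, sampled at 5726 rows by default.
Missingness is planted under MAR per variable and the masks combined —
income-like variables lose ~33% and ~10%, the rest 0.8% — because
one-variable-per-pattern row-wise amputation cannot realise per-variable
targets summing past 1.  The low target was chosen so the complete-case
fraction lands in the realistic 0.40-0.55 band.  The fixture emulates the
*shape* of real survey data, not its content: real data has mixed variable
types, hierarchical structure and attrition that the fixture does not
attempt, so passing tests demonstrate pipeline correctness on this planted
regime, not performance guarantees on any particular survey.

The consensus stage learns many SEM structures under derived seeds, converts
each to its CPDAG, and scores each variable pair by the fraction of runs
containing the link in any orientation — the final presentation is the
skeleton, avoiding causal claims.  The retention threshold is detected from
the strength distribution: split at the largest gap if it is at least 0.5;
a single cluster lying in the upper half counts as the upper mode; otherwise
the distribution is flagged non-bimodal and a configured default (0.87) is
used.  Communities come from Girvan-Newman edge-betweenness divisive
clustering with the dendrogram cut at maximum modularity (the standard cut
rule); isolated nodes become singletons.  Agreement with the planted blocks
is measured by adjusted Rand index against a label-permutation null.

## Orchestration, seeding, problem sizes

Scenario grids are Cartesian products enumerated in deterministic order; the
default grid is 19 variable counts x 6 proportions x 3 mechanisms x 3 sample
sizes = 1026 scenarios, 102,600 datasets at 100 replicates.  Every replicate
seed is derived from (master seed, scenario, replicate index) via a seed
sequence, so results are independent of execution order and safe to
parallelise; sub-seeds for structure, CPTs, sampling, amputation and the
learners are spawned from the replicate seed.  All derived seeds stay below
2^31.

The shipped tests and the acceptance script run reduced problem sizes chosen
to exercise every pipeline stage at meaningful signal: 50 exhaustive-search
comparisons at 3 variables, calibration at 10,000 rows, the three-method
comparison at 15 variables / proportion 0.5 / 1000 rows with 20 replicates
per mechanism, imputation accuracy on 10 datasets per mechanism at 20
variables, and a 20-repeat consensus run on the full-size fixture.
`configs/reduced_grid.yaml` ships a small grid for the `benchmark` CLI.

## Known limitations

* Hard-assignment SEM feeds back its own structure: a dependence absent from
  the current network is diluted by the E-step completion, which can slow
  its discovery.  The classic soft-EM expected-statistics variant is noted
  as an extension, not implemented.
* At the reduced benchmark sizes used here, the synthetic networks are easy
  enough that skeleton recall saturates above 0.9 for all methods at 1000
  rows; the complete-case deficit is large and stable, while the SEM-MICE
  recall difference is below the replicate noise floor (their Hamming
  difference is not: SEM completions are consistently closer to the truth).
* MNAR is generated and evaluated, but no MNAR-aware imputation model (for
  instance selection-model extensions of chained equations) is included.
* Amputation supports arbitrary pattern matrices in the spec type, but the
  benchmark exercises only the default one-variable-per-pattern setting.
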
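# Methods

## The model

All analyses operate on the pairwise Ising model for binary item
responses x ∈ {0,1}^p:

    P(x) ∝ exp( Σ_i τ_i x_i + Σ_{i<j} w_ij x_i x_j )

Nodes are questionnaire items (here: 20 mental-health-knowledge items
coded correct = 1 and 12 dichotomized stigma items coded endorsement
= 1); τ_i is the item's threshold (under 0/1 coding, more negative ⇒
lower endorsement probability) and w_ij the pairwise interaction after
conditioning on all other items.  The 0/1 domain (rather than ±1) is
deliberate: the strongly negative thresholds typical of rarely-endorsed
items (≈ −4 for an 18%-endorsed item) are only interpretable under 0/1
coding, and the conditional distribution of one item given the rest is
then exactly a logistic regression,

    P(x_i = 1 | x_−i) = logistic(τ_i + Σ_j w_ij x_j),

which is the identity all estimation and simulation code relies on.

## Recoding

Yes/no and know/don't-know items map the keyed *correct* pole to 1 and
everything else — including "don't know" — to 0.  Four-point Likert
stigma items are dichotomized with agree/strongly-agree as endorsement;
the numeric convention (which codes mean "agree") is configuration, with
default 1 = strongly agree … 4 = strongly disagree, i.e. {1,2} → 1,
because published tables state the verbal rule but not the numeric
coding.  Per-item keying is explicit in the codebook: stigma scales mix
stigma-consistent and stigma-inconsistent wordings and published reports
do not always say which items were reversed, so the package never
guesses.  Missing responses are a hard error (the emulated survey
enforced complete responses); zero-variance items are rejected at load
because nodewise logistic regression is undefined for them.  Descriptive
tables round percentages half-up to 2 decimals, matching the printed
style of survey tables.

## Estimation (eLasso)

Each node's neighbourhood is estimated by ℓ1-penalized logistic
regression of its column on all p−1 others, along a geometric path of
100 penalties from λ_max (the smallest penalty that zeroes every
coefficient, computed from the KKT condition at the intercept-only fit)
down to 0.01·λ_max.  Each path point is scored by the Extended Bayesian
Information Criterion

    EBIC(λ) = −2ℓ + k·log n + 2γ·k·log(p−1),

k being the number of nonzero neighbour coefficients and γ = 0.25 the
default sparsity weight; ties prefer the larger λ (sparser model, and a
deterministic rule).

Selection is **relaxed** by default: the log-likelihood entering the
EBIC is the unpenalized maximum-likelihood refit of each path point's
active set (one small Newton solve per distinct support, cached), and
the refit coefficients are what the network reports.  Evaluating the
EBIC at the shrunken path coefficients instead (available as
``refit=False``) inflates −2ℓ for sparse supports and, on some
realizations, tips selection toward supersets of the true
neighbourhood; the relaxed criterion agrees with exhaustive best-subset
EBIC search whenever the best subset appears on the path, which the
validation suite checks node-by-node on chain graphs.  Supports larger
than 16 keep their penalized values — their EBIC is dominated by the
k·log n term regardless.

The p selected neighbourhoods are symmetrized by
the AND rule — an edge survives only if both incident regressions select
it, with weight the mean of the two coefficients (the OR rule is
available).  Thresholds are each node's own selected-model intercept,
also under the AND rule.  Predictors enter raw and unstandardized, so
thresholds stay on the endorsement-probability scale.

The path solver is written in-house (numba-compiled coordinate descent:
IRLS outer loop, soft-threshold inner loop with active-set cycling, warm
starts along the path) because the bootstrap and permutation stages
re-estimate the network on the order of 10⁵ times, which rules out
per-fit solver overhead.  Two exactness devices matter:

- **Pattern collapsing.**  Binary rows are collapsed to unique (y, x)
  patterns with multiplicities before fitting.  This is an exact
  sufficient-statistics reduction (identical likelihood), and for small
  p it caps the working size at 2^p rows regardless of n.
- **Numerical guards.**  The path anchor is nudged 1e-8 above the exact
  λ_max so the first path point is the empty model despite floating-point
  wobble; selected coefficients below 1e-7 are treated as zeros; a
  coefficient magnitude above 15 (odds ratio > 3·10⁶) truncates the path
  as quasi-separated, with a warning and the valid prefix returned.

The solver is validated in the test suite against scikit-learn's saga
solver at matched penalties (agreement ~1e-6) and against an exhaustive
best-subset EBIC oracle (unpenalized statsmodels refits of all 2^(p−1)
neighbour subsets) on 6-node chain graphs.

## Centrality

Strength Σ_j |w_ij|, one-step expected influence Σ_j w_ij, and bridge
expected influence (the signed sum restricted to edges crossing to the
other community).  One-step definitions only; two-step variants are out
of scope.  z-scores standardize each metric across nodes with the
sample (n−1) standard deviation; a constant metric yields a zero column
plus a warning rather than NaNs.

## Stability

Case-dropping bootstrap: for drop proportions q on a grid (default
0.10–0.75 by 0.05) and replicates r (default 500), ⌈(1−q)·n⌉ rows are
drawn without replacement, the network re-estimated, and the Pearson
correlation between subsample and full-sample centrality vectors
recorded (nodes as units).  The CS coefficient per metric is the largest
q at which ≥ 95% of replicates correlate ≥ 0.7 with the full sample
(> 0.25 conventionally acceptable, > 0.5 good).  Replicates whose
subsample loses a response category are dropped and counted, never
imputed; undefined correlations (constant vectors) are recorded as NaN
and count as failures.  Each (q, replicate) cell draws from its own seed
substream, so results are independent of evaluation order.  Edge-weight
uncertainty uses a separate nonparametric bootstrap (resample n rows
with replacement; 2.5/97.5 percentile CIs per node pair).

## Intervention simulation

For each node and direction, the node's threshold is shifted by
± magnitude·SD(τ̂), where the SD is the **sample standard deviation of
the full estimated threshold vector** — not a per-node standard error;
published descriptions of the procedure do not disambiguate, and the
vector-SD reading keeps the shift on the common scale of the network's
thresholds.  Magnitude defaults to 2.  Respondents are sampled from each
altered model (one independent Gibbs chain per person, 1,000 burn-in
sweeps), and the per-person sum score S = Σ_i x_i is summarized by its
mean and a normal-approximation 95% CI (percentile CIs available).
Raising a threshold makes the item easier to endorse; nodes are ranked
by mean sum score, descending for aggravation and ascending for
alleviation.  The whole-network sum score is used (per-community
subscores are an option, not a claim).  With all-non-negative weights
the Ising measure is stochastically monotone in each τ_i, so aggravation
can never lower — nor alleviation raise — the exact expected sum score;
this enumeration-checkable property anchors the validation suite.

## Group comparison

Two-group permutation test: networks are estimated separately per group;
statistics are the absolute global-strength difference
(Σ_{i<j}|w_ij| per network), the maximum absolute edge difference
(structure test), per-edge differences, and per-node expected-influence
differences.  The null distribution re-assigns respondents to
pseudo-groups of the original sizes and **re-runs the full estimation on
both pseudo-groups** each permutation — the reference distribution must
reflect selection and estimation noise, not just weight resampling.
p-values use the add-one estimator (#{perm ≥ obs}+1)/(n_perm+1), which
cannot return 0; per-edge and per-node families get Holm correction by
default; n_perm defaults to 1,000.  Two implementation details make
p-values exactly invariant to swapping the group labels: the pooled
rows are put in canonical (lexicographic) order before permuting, and
the smaller group size is always carved out first.  Permutations that
produce a zero-variance column in either pseudo-group are redrawn and
counted, capped at 10·n_perm.

## Synthetic data

The generator plants a two-community network (20 + 12 nodes by default):
each within-community pair gets an edge independently with probability
`intra_density` (default 0.15), exactly `n_bridges` (default 3)
cross-community edges are planted uniformly at random, edge weights are
uniform on [0.3, 1.2] (optionally signed), and thresholds are then
calibrated by damped logit-offset iteration until simulated marginals
match the published per-item endorsement rates of the emulated survey
(13.61%–92.10%) within 0.02.  Sampling is exact (full 2^p enumeration)
for p ≤ 16 and by Gibbs otherwise; every respondent is an independent
chain with fair-coin initialization, so rows are i.i.d. draws.  The
demo bundle writes raw-format responses (Yes/No, Know/Don't know,
Likert 1–4) so the full recoding path is exercised, plus binary group
labels with a 61.1% / 38.9% split emulating the survey's sex ratio —
drawn from the *same* model, so group comparisons on demo data should
find invariance.

What the generator does **not** emulate: item-level missingness,
inattentive response patterns, ordinal dependence beyond pairwise Ising
interactions, latent-trait (monotone unidimensional) structure, and
demographic covariate effects.  Passing recovery tests therefore show
that the pipeline inverts its own generating model at realistic sizes —
not that real questionnaire data satisfy the Ising assumptions.

## Numerical and design choices

- Solver tolerances: coefficient-change 1e-6 (default fits); the
  replication-heavy simulation studies use a documented fast profile
  (30-point λ path down to 0.05·λ_max, tol 1e-5).  In permutation tests
  the same config is applied to observed and permuted statistics, so
  test validity is unaffected by the profile.
- Seeds: one global seed per run; stages, replicates and simulation
  conditions derive named substreams (numpy SeedSequence), so toggling
  one stage never shifts another's draws, and identical configs
  reproduce outputs byte-for-byte.
- Gibbs burn-in: 1,000 fixed-order sweeps per chain for data generation
  and intervention simulation; 200–500 for calibration inner loops and
  agreement checks, where the 3-SE acceptance margin dwarfs residual
  mixing bias (verified against enumeration on p ≤ 10).
- Threshold calibration: damped (0.8) logit-offset updates, ≤ 40
  iterations, tolerance 0.02 on every marginal; non-convergence warns
  and returns the best iterate, flagged.
- Degenerate inputs: zero-variance columns are errors at load,
  skip-and-count events inside resampling loops, and redraw events
  inside permutation loops.

## Validation problem sizes

The validation suite (tests and `scripts/acceptance.py`) uses: exact
agreement checks at n = 20,000 samples on p ≤ 10 toys; edge recovery on
the calibrated 32-node network at n = 12,000 (single run, full default
path) plus an accuracy curve over n ∈ {500, 2,000, 8,000} × 5 seeds;
EBIC-oracle comparison on a 6-node chain at n = 2,000; intervention
monotonicity by enumeration plus rank agreement at 50,000 simulated
persons on a 6-node fixture whose exact effect gaps (> 0.03) exceed
Monte-Carlo noise by design; permutation-test calibration with 200
null trials × 200 permutations at n = 500/group and power with 50
trials at n = 1,000/group against a single Δw = 1.5 edge; stability
fixtures at 100 replicates.  The two-disjoint-edge base network in the
power study is chosen so the differing edge is not swamped by
nuisance-edge estimation noise in the global-strength statistic.

## Known limitations

- The AND rule with EBIC is conservative by design; weak true edges
  (|w| ≲ 0.3 at n ≲ 2,000) are often omitted, which the accuracy curve
  quantifies.
- The permutation comparison re-estimates ~2·n_perm networks and is the
  most expensive stage at survey scale; the documented fast estimation
  profile keeps it tractable.
- Normal-approximation CIs on sum scores are slightly narrow for very
  skewed score distributions (percentile option available).
- The intervention simulation perturbs one node at a time; sequential or
  combined interventions and any dynamic (time-series) reading are out
  of scope.
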
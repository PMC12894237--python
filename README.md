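# isingnet

Network psychometrics for binary questionnaire data: estimate an Ising
model over items, find the hubs and the bridges between constructs,
quantify how stable those findings are, simulate node-level
interventions, and test whether two groups share one network.

The package was built around a concrete study design — a large
school-based survey measuring mental-health knowledge (20 binary items,
correct = 1) and perceived stigma (12 four-point Likert items,
dichotomized to endorsement = 1) in ~12,500 adolescents — and ships a
synthetic-data generator that emulates that design (two communities,
dense within-construct connectivity, a few planted knowledge→stigma
bridges, endorsement rates spanning ~13%–92%), so the entire pipeline is
testable against known ground truth.  It is aimed at researchers doing
item-level network analysis on binary scales who want a reproducible,
seedable, end-to-end pipeline rather than a collection of one-off
scripts.

## The model and the pipeline

Items x ∈ {0,1}^p follow a pairwise Ising model

    P(x) ∝ exp( Σ_i τ_i x_i + Σ_{i<j} w_ij x_i x_j ),

whose conditionals are logistic regressions:
P(x_i = 1 | x_−i) = logistic(τ_i + Σ_j w_ij x_j).  The stages:

1. **Recoding** (`isingnet.codebook`) — yes/no, know/don't-know and
   Likert items to {0,1} per an explicit per-item codebook.
2. **Estimation** (`isingnet.elasso`) — nodewise ℓ1-logistic regression
   along a 100-point λ path, model selection by the Extended BIC
   (EBIC = −2ℓ + k log n + 2γ k log(p−1), γ = 0.25), relaxed
   (refit-based) selection, AND-rule symmetrization.
3. **Centrality** (`isingnet.centrality`) — strength Σ|w_ij|, expected
   influence Σw_ij, bridge expected influence (signed cross-community
   sum), with z-scores.
4. **Stability** (`isingnet.stability`) — case-dropping bootstrap and
   the correlation-stability (CS) coefficient (> 0.25 acceptable,
   > 0.5 good), plus percentile bootstrap CIs on edge weights.
5. **Intervention simulation** (`isingnet.nira`) — perturb each node's
   threshold by ±2 SD of the threshold vector, Gibbs-sample respondents
   from the altered model, rank nodes by mean network sum score.
6. **Group comparison** (`isingnet.nct`) — permutation test of global
   strength, structure, edges and node influence, re-estimating both
   networks under every permuted labelling.

`isingnet.synthetic` generates ground-truth networks and exact
(2^p enumeration, p ≤ 16) or Gibbs samples; `isingnet.pipeline` runs
everything from one config with per-stage seed substreams.  See
`docs/methods.md` for assumptions, numerical choices, and what the
synthetic generator does and does not emulate.

## Worked example

```
python analysis/01_simulate_study.py      # synthetic study, n = 2000
python analysis/02_estimate_network.py    # eLasso fit + centralities
python analysis/03_stability.py           # bootstrap stability
python analysis/04_interventions.py       # threshold perturbations
python analysis/05_compare_groups.py      # two-group permutation test
```

`01` prints (seed 7):

    simulated 2000 respondents x 32 items (seed 7)
    threshold calibration converged=True (max marginal error 0.017)
    endorsement spans 13.80%–91.55% (target design: ~13%–92%)
    ground-truth network: 39 edges (3 cross-community bridges)

i.e. the generator planted a 39-edge two-community network and
calibrated every item's endorsement rate into the survey's observed
range.  `02` then reports

    estimated network: 32 edges (gamma=0.25, rule=AND, n=2000)
    edge-presence accuracy vs ground truth: 0.986 (39 true edges)
    top-3 |bridge EI| nodes: MHKQ6 (+1.320), Stigma9 (+0.893), Stigma4 (+0.555)

so at n = 2,000 the estimator gets 98.6% of edge decisions right and the
highest bridge-expected-influence nodes are endpoints of planted
bridges.  `03` summarizes robustness — CS = 0.50 for strength and
expected influence, CS = 0.25 for the (noisier) bridge metric, and 82%
of estimated edges have bootstrap 95% CIs excluding zero — and `04`
ranks intervention targets by simulated sum scores, e.g. aggravating
MHKQ6 (the most connected knowledge misconception in this synthetic
network) raises the mean sum score furthest above baseline, while `05`
finds the male/female networks statistically invariant
(global-strength |diff| = 4.27, p = 0.159; both groups are drawn from
the same generating model, so invariance is the correct answer).

Numbers vary with `--seed`/`--n`; rerunning with the same seed
reproduces them exactly.

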
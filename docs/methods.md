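# Methods

## Model and coding

Symptoms are binary occurrence indicators coded {0,1}, not ±1. Under this
coding the Ising conditional

    P(x_j = 1 | x_rest) = logistic(τ_j + Σ_k β_jk x_k)

is exactly the logistic regression the nodewise estimator fits, so the
generative couplings and the regression coefficients live on the same scale
and planted-truth comparisons are direct. Note that the two codings are not
parameter-equivalent: a coupling that is moderate under ±1 coding can be
saturating under {0,1} coding, because a node with m active neighbours feels
the full Σβ rather than a signed balance. Threshold choices must offset the
couplings if realistic occurrence rates are wanted (see "Synthetic data").

## Nodewise estimation (eLasso)

Each node j is regressed on the remaining p−1 nodes by l1-penalized logistic
regression with unpenalized intercept, maximizing
`pseudo_loglik − ρ·Σ|β_jk|`. The penalty path has 100 geometric points from
ρ_max (the largest absolute score component at the intercept-only fit, i.e.
the smallest penalty with an all-zero solution) down to 0.01·ρ_max. The
model on the path minimizing EBIC(γ), γ = 0.25 by default, is selected per
node; EBIC ties go to the smaller neighbourhood, then the larger penalty.
Symmetrization uses the OR rule with the mean-with-zero weight convention
(config switch `or_weight="single"` keeps a one-sided estimate unaveraged);
the AND rule is available and always yields a subset of the OR edges.

Solver: proximal-Newton coordinate descent, jit-compiled. Binary rows are
first collapsed to unique patterns with multiplicities — an exact
reformulation that makes every iteration O(#patterns) instead of O(n). Each
outer iteration builds the IRLS working quadratic (weights clipped into
[1e−5, 1−1e−5]); the inner problem is solved by a few soft-thresholding
sweeps followed by exact KKT solves on the active set (with a 1e−12 relative
ridge guarding exact collinearity). Convergence is declared when the
largest parameter change in an outer iteration falls below 1e−8, or — for
degenerate designs with exactly collinear columns, where the l1 solution is
a flat ridge — when the penalized objective stops moving at 1e−12 relative
precision. Steps are trust-capped at 5 log-odds per iteration and all
parameters confined to ±30 log-odds; both guards only bind on tiny or
separated data sets. Coefficients below 1e−8 in magnitude are snapped to
zero so that support counting (|J|) is exact. The solver is deterministic
and agrees with an independent general-purpose optimizer (L-BFGS-B on the
split β⁺/β⁻ formulation) to better than 1e−6 in objective value at every
grid point; the test suite enforces this.

Constant (zero-variance) columns cannot be regressed; they are kept as
isolated nodes so node indexing stays aligned across time points, with a
Haldane-corrected threshold logit((c+0.5)/(n−c+0.5)) to keep the recorded
threshold finite.

## Community detection (Walktrap)

Transition matrix P_jk = |w_jk| / Σ_m |w_jm| on absolute weights (isolated
nodes self-loop). Inside the agglomeration the walk is made lazy,
P ← (I+P)/2, as in the canonical implementation, keeping short-walk profiles
well behaved; walk length t = 4. Community profiles are member-averaged rows
of P^t; the distance between adjacent communities is the degree-weighted
Euclidean distance between profiles, and the pair with the smallest Ward
increment |A||B|/(|A|+|B|)·r² is merged (ties broken on the smallest id
pair). Only adjacent communities merge, so connected components agglomerate
independently and isolated nodes stay singletons. Modularity (on absolute
weights) is recorded after every merge, and the cut maximizing it is
returned. Cross-checks against igraph's `community_walktrap` show exact
membership agreement on block-structured graphs and chosen cuts of equal
quality on random graphs (merge-tie details can differ per graph; neither
implementation dominates).

Negative edges are rare in occurrence networks; they enter walks, modularity
and all centralities through absolute values (a `negative="zero"` switch
drops them instead).

## Centrality

Strength is the absolute row sum of the weight matrix. Closeness and
betweenness use shortest paths with edge length 1/|w| (stronger association
= shorter distance); closeness is 1/Σd and is reported as missing whenever
some node is unreachable — a disconnected network has no finite closeness,
matching how such symptoms are reported in practice. Betweenness counts,
per unordered pair, the fraction of shortest paths through each interior
node (endpoints excluded; ties split fractionally). The node-removal
re-analysis drops the symptom column and re-estimates the p−1 network from
data by default; deleting the node from the fitted graph is available as
`mode="delete"`.

## Stability

Edge accuracy: B nonparametric bootstrap resamples of patients,
percentile 2.5/97.5 bounds per edge; degenerate resamples (fewer than two
non-constant columns) are skipped and counted. Case-dropping (patients) and
node-dropping (symptoms) bootstraps re-estimate the network on subsets and
record the Pearson correlation between subset and full-sample centralities,
per index, over nodes where both are defined. The CS coefficient is the
largest drop proportion q in the tested grid such that at q *and at every
smaller tested level* at least 95% of replicates correlate ≥ 0.7; the
monotone qualifier prevents awarding stability past an unstable
intermediate level. Replicates whose correlation is undefined (constant or
all-missing centralities) are recorded as missing and count as failures in
the CS proportion — conservative by construction. Default grid
{0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.75}; default B = 1000 (tests and the
acceptance script use B = 75–200 to keep runtimes in minutes).

## Synthetic data

`make_planted_model` builds block-constant coupling matrices over near-equal
blocks with uniform thresholds — the ground truth for recovery tests.
`exact_joint_distribution` enumerates all 2^p states (p ≤ 20) and is the
oracle for the Gibbs sampler, which uses systematic single-site sweeps
(burn-in 1000, thinning 10 by default) and is byte-deterministic given a
seed.

The reference synthetic cohort used across examples and the acceptance
script is p=10 symptoms in three unequal clusters (4/3/3), within-cluster
coupling 1.5, thresholds uniform on (−3, −1), n≈1000 patients: occurrence
rates then span roughly 15–85%, mirroring the 8–86% band seen in real
chemotherapy symptom data, and true strengths are heterogeneous across
nodes, as real symptom networks are. Two caveats documented deliberately:
(i) with {0,1} coding, a two-block model with τ = −1 and within-coupling
1.5 saturates (exact marginals ≈ 0.99), leaving almost no information for
edge detection — recovery tests in that regime measure the regime, not the
estimator; (ii) in a *perfectly symmetric* planted model every node has the
same true strength, so subset-vs-original strength correlations are pure
noise and CS is uninformative; the unequal-block cohort avoids both.

Longitudinal designs sample T1 from the stationary chain and initialize
each later assessment from the patient's previous state, applying
round((1−carryover)·10) refresh sweeps: since the chain is stationary, the
per-time-point marginal law is exact for any sweep count, and carryover only
tunes cross-time dependence (carryover 1 copies states unchanged). Whole
assessments are dropped with the design's missingness rate and recorded as
all-missing rows, never as zeros, so the complete-case filter sees them.
What the generator does not emulate: item-level (single-symptom)
missingness, time-varying cluster membership, covariate effects, and
informative dropout.

## What passing tests show — and what they do not

Planted-model recovery, cluster recovery and CS behaviour demonstrate that
the implementation is correct and well-calibrated under the generative
model. Real symptom data differ: dependence is not exactly pairwise,
populations are heterogeneous, and assessments have informative missingness.
Results on real cohorts therefore inherit the usual caveats of network
psychometrics; the stability module exists precisely to quantify which
conclusions (typically the strength ordering) survive resampling.

## Numerical and design choices

- Rounding of printed percentages: half-up (11.3 from 112/987), one decimal
  for rates and consistency, two for density.
- Closeness on disconnected graphs: missing, not component-restricted.
- Cluster naming across networks is explicit anchor-set configuration
  (default anchors: psychological, respiratory, gastrointestinal cores);
  Jaccard-maximal greedy assignment, ties left unnamed with a warning. An
  automatic semantic matching of clusters across nine networks is not
  attempted.
- Layout: Fruchterman–Reingold on absolute weights, seed-deterministic.
- Patient-id columns are mandatory in CSV inputs; matrices without ids are
  rejected rather than auto-numbered, keeping longitudinal joins
  unambiguous.

## Known limitations

- The estimator assumes complete cases; imputation is out of scope.
- No Gaussian/mixed graphical models, no alternative community methods, no
  edge- or centrality-difference significance tests.
- EBIC with γ=0.25 is conservative: in saturated or tiny-sample regimes it
  prefers empty neighbourhoods, which is the intended behaviour of the
  method, not an artifact.
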
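# symptomnet

Network analysis of binary symptom-occurrence data: estimate sparse Ising
(binary pairwise Markov random field) networks from patient × symptom
matrices, detect symptom clusters, rank symptoms by centrality, and quantify
how accurate and stable those results are.

The package targets the workflow used to study co-occurring symptoms in
oncology cohorts — for example, 38 symptoms assessed weekly in ~1000
patients across six chemotherapy assessments — where each symptom is a node,
and an edge means two symptoms still co-occur after conditioning on all
other symptoms. Because such patient-level data are rarely public, the
package ships a first-class synthetic-data module that generates binary
longitudinal cohorts from fully specified Ising models with planted cluster
structure, so every stage of the pipeline can be validated against known
ground truth.

## The model and the estimator

For binary variables `x ∈ {0,1}^p`, the Ising model is

    P(x) ∝ exp( Σ_j τ_j x_j + Σ_{j<k} β_jk x_j x_k )

with node thresholds `τ_j` (the tendency of symptom j to occur on its own)
and pairwise couplings `β_jk`. Its single-site conditional is a logistic
regression, which the estimator (eLasso, as in the IsingFit method)
exploits: each symptom is regressed on all others with an l1 penalty along a
descending penalty path, and the neighbourhood minimizing the extended BIC

    EBIC = −2ℓ + |J|·log n + 2γ·|J|·log(p−1),     γ = 0.25 by default

is selected per node. The two directed estimates per pair are symmetrized
with the OR rule (edge kept if either direction selects it; weight = mean of
the two directed coefficients, a missing one entering as zero).

On top of the estimated network the package provides:

- **Walktrap community detection** — agglomerative clustering of t-step
  random-walk profiles (t=4), cut at maximum modularity; communities are the
  symptom clusters.
- **Centrality** — strength (Σ|w|), closeness (inverse summed shortest-path
  distance with edge lengths 1/|w|), betweenness (shortest paths brokered).
- **Stability** — nonparametric bootstrap 95% CIs for edge weights, plus
  case-dropping and node-dropping subsetting bootstraps summarized by the
  correlation-stability (CS) coefficient: the largest proportion of
  cases/nodes droppable while subset and full-sample centralities correlate
  ≥ 0.7 with 95% probability (CS > 0.25 moderate, > 0.5 strong).

## Worked example

```python
import symptomnet as sn

model = sn.make_planted_model(p=10, n_communities=3, within_coupling=1.5,
                              between_coupling=0.0, tau_range=(-3.0, -1.0),
                              seed=1)
X = sn.gibbs_sample(model, n=1000, seed=2)
net = sn.estimate_network(X)          # gamma=0.25, OR rule
part = sn.walktrap(net)
print(sn.network_density(net), part.n_communities)
print(sn.centrality_table(net).head(3))
```

prints

```
26.67 3
      strength  closeness  betweenness
code
s03      4.199        NaN          0.0
s01      3.934        NaN          0.0
s04      3.805        NaN          0.0
```

26.67% of the 45 possible edges were kept, the three planted clusters are
recovered exactly, and the strength column ranks symptoms by total
conditional association (closeness is undefined here because the three
clusters are mutually disconnected). On this cohort the estimator recovers
every planted edge with no false positives (sensitivity and specificity
1.00; see `examples/01_simulate_and_estimate.py`).

The `examples/` directory holds one short script per capability: simulation
and estimation, communities and centrality, stability bootstraps, and a
longitudinal multi-time-point analysis with cluster-consistency tables. A
thin CLI mirrors the stages (`symptomnet simulate|fit|communities|
centrality|stability|consistency|run`).

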
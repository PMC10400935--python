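# burstscape

Single-cell transcriptional uncertainty analysis with the two-state
(telegraph) model of stochastic gene transcription.

During differentiation, cells appear to pass through transition states of
elevated gene-expression stochasticity before settling into a terminal
fate.  burstscape quantifies this per cell: it fits the telegraph model —
a promoter switching OFF→ON at rate θ_on and ON→OFF at rate θ_off,
transcribing at rate θ_t while ON, with degradation rate θ_d ≡ 1 as the
time unit — to single-cell counts, whose stationary law is the
Poisson-Beta mixture m | p ~ Poisson(θ_t·p), p ~ Beta(θ_on, θ_off).  On top
of that model it provides:

- **likelihood-based clustering** of cells (greedy maximisation of the
  total cell log-likelihood, consensus over many runs, k-medoids
  finalisation, eigengap selection of K);
- **lineage inference**: clusters are connected in ascending order of a
  likelihood-based distance (the mean per-cell log-likelihood drop when two
  clusters are refit as one), giving a spanning tree with root-anchored
  cluster pseudotimes;
- **transcriptional uncertainty**: each cell is placed at the fractional
  position s on an adjacent edge maximising its interpolated likelihood
  under the blended endpoint distributions (1−s)·P_k1,g + s·P_k2,g; its
  uncertainty is the negative log-likelihood NLL_n = Σ_g NLL_{g,n}, and its
  pseudotime interpolates the endpoint clusters' pseudotimes at s;
- **the uncertainty landscape**: NLL as a penalised-least-squares surface
  on a regular 30×30 grid over a 2-D embedding (PCA or t-SNE of the
  z-scored expression) — hills mark transition states, valleys stable
  identities;
- **burst statistics**: per (gene, cluster) burst size S = θ_t/θ_off and
  burst frequency F = θ_on, correlated with the cluster-averaged gene NLL
  (Pearson r with the t score t = r·√((n−2)/(1−r²)));
- **RNA-velocity comparison**: the cell-wise velocity norm is
  cross-correlated with cell-wise mean NLL along pseudotime to measure by
  how many bins velocity leads uncertainty;
- a **synthetic-data generator** that plants lineage-structured telegraph
  counts (linear, bifurcating and doubly bifurcating presets) with
  burst-inflated transition states, a leading velocity proxy, and full
  ground truth.

It is aimed at researchers analysing single-cell RT-qPCR panels or
moderately sized scRNA-seq gene panels along differentiation time courses.

## Worked example

```python
import burstscape as bs
from burstscape import RunConfig, run_pipeline

scenario = bs.preset_scenarios(seed=42)["bifurcation-5"]
matrix, velocity, truth = bs.generate(scenario)
config = RunConfig({"cluster.k": 5, "seed": 42})
result = run_pipeline(config, matrix, "out/bif5", velocity=velocity)

print("clusters:", result.clustering.n_clusters)
print("lineage edges:", sorted(tuple(e) for e in result.lineage.graph_.graph.edges))
for _, row in result.correlations.iterrows():
    print(f"{row['name']}: r={row['r']:.3f} (p={row['p']:.2e})")
print("velocity leads NLL by", result.velocity_lag, "pseudotime bins")
```

prints

```
clusters: 5
lineage edges: [(1, 2), (2, 3), (3, 4), (3, 5)]
burst_frequency_vs_nll: r=0.464 (p=2.04e-17)
burst_size_vs_nll: r=0.182 (p=1.52e-03)
velocity leads NLL by 4 pseudotime bins
```

The generated scenario is a bifurcating lineage 1→2→3 with cluster 3
branching into fates 4 and 5 and carrying a burst-inflated transition gene
module.  The pipeline recovers exactly the planted tree; both burst size
and burst frequency correlate positively with per-gene uncertainty across
all 300 (gene, cluster) pairs at the p ≤ 0.01 reporting level; and the
velocity signal peaks four (of twenty) pseudotime bins before the
uncertainty peak — the planted one-cluster lead.  `out/bif5/` contains the
full bundle: labels, fitted cluster parameters, consensus matrix, lineage
edges, per-cell placements and pseudotimes, per-gene NLLs, moving-average
NLL per differentiation path, high-uncertainty gene sets, the 2-D
embedding, the 30×30 landscape grid, the correlation table, the
velocity summary, and a manifest with config hash and output checksums
(re-running with the same config and seed reproduces every file byte for
byte).

The same analysis is available from the shell:

```bash
burstscape simulate --preset bifurcation-5 --seed 42 --out sim/
burstscape run --input sim/expression.csv --velocity sim/velocity.csv \
    --capture-times sim/capture_times.csv --seed 42 --out out/bif5
```

plus stage-wise subcommands (`preprocess`, `cluster`, `lineage`,
`uncertainty`, `landscape`, `correlate`).  Model internals — the stationary
PMF, exact sampler, grid MLE, placement and surface fitting — are exposed
as library functions and scikit-learn-style estimators
(`TelegraphClustering`, `LineageInference`, `GridSurface`); see
`docs/methods.md` for the model, the algorithms, all tunable parameters and
the generator's design.

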
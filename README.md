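# netfilters

Denoising real-valued node measurements on biological networks with local
**network filters** — smoothing, sharpening, and a module-wise "patchwork"
combination — plus diffusion-kernel baselines, a fully synthetic benchmark
suite, and a weighted KNN regression task for predicting protein-expression
changes.

## The problem

System-wide molecular profiles (protein expression, metabolite levels,
transcript abundances) are noisy. The measurements are not independent: an
interaction network (e.g. a protein–protein interaction network) tells us
which measurements should be related, and whether neighboring values tend to
be correlated (*assortative*, r > 0) or anti-correlated (*disassortative*,
r < 0), where r is the numeric assortativity coefficient

```
r = Σ_ij (A_ij − k_i k_j / 2m) x_i x_j  /  Σ_ij (k_i δ_ij − k_i k_j / 2m) x_i x_j ,
```

the Pearson correlation of the measurement values across the ends of every
edge. Like denoising a pixel from its neighbors in an image, a node's value
can be denoised from its network neighborhood — if the right filter is
matched to the local correlation structure.

## The filters

Given a graph G, values **x**, node degree k_i and neighborhood ν_i, all
applied synchronously (no feedback within one pass):

- **mean (smoothing)**: x̂_i = (x_i + Σ_{j∈ν_i} w_ij x_j) / (1 + k_i)
- **median (smoothing)**: x̂_i = median{x_i, x_{ν_i}}
- **sharp (sharpening / unsharp masking)**: x̂_i = α (x_i − mean-filter_i) + x̄,
  default α = 0.8
- **patchwork**: partition G into modules with a community-detection
  algorithm, drop between-module edges, and per module s apply the sharp
  filter (recentered on the *module* mean) if the module's internal
  assortativity r_s < 0, else the mean filter.

Baselines: the Laplacian exponential diffusion kernel S_β = e^{−βL} and the
personalized-PageRank (netSmooth-style) kernel K_α = (1−α)(I−αB)^{-1}, with
entropy-based automatic smoothing-parameter selection.

Partitioners behind the patchwork filter: Louvain-class modularity
maximization, spectral (normalized-Laplacian k-means), and a degree-corrected
stochastic block model fit by greedy likelihood ascent, optionally
metadata-aware.

## Worked example

```python
from netfilters import (ChungLuConfig, MCMCConfig, ValueDistribution,
                        assign_values_mcmc, chung_lu_graph, permute_noise,
                        mean_filter, assortativity, mae)

# a heavy-tailed random graph (largest component of a 100-node draw)
net = chung_lu_graph(ChungLuConfig(n=100, seed=7))           # 65 nodes, 86 edges

# N(100, 100) node values driven to assortativity r = 0.8
truth = assign_values_mcmc(net, ValueDistribution(mu=100, sigma2=100),
                           MCMCConfig(r_target=0.8, seed=7))
assortativity(net, truth)                                     # 0.7915

# corrupt 25% of nodes by permuting their values, then denoise
noisy, permuted = permute_noise(truth, 0.25, seed=8)          # 16 nodes permuted
denoised = mean_filter(net, noisy)
mae(truth, noisy, permuted)                                   # 10.97
mae(truth, denoised, permuted)                                #  7.19
```

The raw permutation error on the corrupted nodes is 10.97; one pass of the
mean filter cuts it to 7.19 (a 34% reduction on this single draw) because
strongly assortative neighbors carry information about each node's true
value.

The same workflow is available from the shell:

```sh
netfilter synth cl --n 100 --r 0.8 --seed 7 -o graph.tsv -v values.csv
netfilter apply --graph graph.tsv --values values.csv --filter mean -o denoised.csv
netfilter partition --graph graph.tsv --method spectral --kappa 5 -o modules.csv
netfilter bench nonmodular --replicates 50 --seed 1 -o results.csv
netfilter plot results.csv -o fig.png
netfilter predict --panel panel.tsv --graph ppin.tsv --filter mean --k 4 -o mae.csv
```

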
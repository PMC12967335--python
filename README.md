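# schicab

A/B chromatin compartment annotation from **individual single-cell Hi-C
matrices**, without imputation and without using external genomic features
to *derive* the compartments.

Single-cell Hi-C contact maps are extremely sparse — often only a few
hundred to a few thousand contacts per chromosome — which defeats the
classical bulk recipe (PCA on the correlation matrix of the O/E map).
`schicab` instead treats compartment calling as a **2D change-point
detection** problem followed by **graph partitioning**, and uses CpG
density only at the very end, to decide which side of the bipartition is
the active A compartment.

## Model

For a contact matrix `Y` over `n` bins, each entry is modeled as
`Y_ij = R_ij · X_ij` with `X_ij ~ N(μ_kl, σ²)` (the latent contact
intensity) and `R_ij ~ Bernoulli(r_kl)` (dropout). `K` change points tile
the matrix into `(K+1)²` blocks with block-constant `μ_kl` and `r_kl`.
With a uniform prior over the `C(n−1, K)` configurations and the plug-in
estimates `r̂_kl = S_kl/N_kl`, `μ̂_kl`, pooled `σ̂²`, the log-posterior of a
configuration is

```
Σ_kl [ S_kl log r̂_kl + (N_kl − S_kl) log(1 − r̂_kl) ]  −  (1/2σ̂²) Σ_kl S_kl V_kl
```

where `N_kl`/`S_kl` are the total/nonzero pair counts of block `(k,l)` and
`V_kl` the variance of its nonzero entries. The maximizer is found by
Metropolis–Hastings over fixed-`K` configurations (change-point detection
runs on the **raw** matrix, where distance decay has limited influence).

The detected segments become nodes of a weighted graph whose edge weights
are block averages of the **O/E-normalized** matrix (expected profile from
a pseudo-bulk of the dataset). The two compartments are the **normalized
cut** `min R/(κ₁κ₂)`, solved in relaxation by the second-largest
eigenvector `ν₂` of `D^(−1/2) A D^(−1/2)` and rounded at 0. The sign of
the Pearson correlation between `ν₂` and CpG density assigns the A/B
labels. The cut quality `F = (1 − λ₂)/(2m)` gives a per-cell
**compartmental strength** `−log₂(F)` (averaged over 10 repeated runs).

## Worked example

```sh
python examples/01_annotate_single_cell.py
```

simulates a 100-bin chromosome with 8 planted compartment blocks under 70%
dropout and annotates it:

```
simulated cell: 100 bins, 1478 nonzero pairs
CpG correlation of nu2 : 0.997
compartment strength   : 7.04  (-log2 F, mean of 10 repeats)
intersection vs truth  : 1.000  (fraction of bins with the correct A/B label)
first 30 labels        : AAAABBBBBBBBBBBBAAAAAAAAAAAAAA
```

The intersection is the fraction of bins assigned the planted compartment;
1.0 means every A/B call is correct despite 70% of entries being dropped.
The other examples cover strength under shuffle-mix degradation (`02`),
automatic selection of the change-point count `K` and cross-cell
heterogeneity metrics (`03`), and recovery from binomial downsampling at
single-cell rates (`04`).

A thin CLI mirrors the library:

```sh
schicab simulate --n 60 --k-true 3 --cells 2 --out-prefix sim
schicab annotate --triplet sim_cell0.tsv --cpg cpg.bedgraph --k 3 --out-prefix out
schicab select-k --triplet sim_cell0.tsv --cpg cpg.bedgraph
schicab strength --triplet sim_cell0.tsv --cpg cpg.bedgraph --k 3
schicab metrics out.labels.tsv truth.labels.tsv
```

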
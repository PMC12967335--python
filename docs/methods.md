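# Methods

## The statistical model

A single-cell contact matrix `Y` over `n` bins is modeled entry-wise as
`Y_ij = R_ij · X_ij`, where `X_ij` is the latent contact intensity and
`R_ij` a Bernoulli dropout indicator, independent of `X`. `X_ij` is
Gaussian with a mean that is constant within each of the `(K+1)²` blocks
induced by `K` change points (CPs) on the bin axis, and a variance `σ²`
shared across the matrix. `P(R_ij = 1) = r_kl` is likewise
block-constant. Compartment boundaries appear as CPs because both the
contact intensity and the observation rate change across them.

The CP configuration lives in `{0,1}^(n−1)` with exactly `K` ones; the
prior is uniform over the `C(n−1, K)` configurations, so the posterior is
proportional to the likelihood. Plugging in the MLEs per configuration —
`r̂_kl = S_kl/N_kl`, the nonzero-entry block means `μ̂_kl`, and a pooled
`σ̂²` — gives the log-posterior

```
log p(state) = Σ_kl [ S_kl log r̂_kl + (N_kl − S_kl) log(1 − r̂_kl) ]
             − (1/2σ̂²) Σ_kl S_kl V_kl   (+ const)
```

with `N_kl` the block pair count, `S_kl` its nonzero pair count and
`V_kl` the population variance of the nonzero entries. Conventions, all of
which shift every state equally or are standard continuity limits:

- sums run over the full symmetric matrix **including the diagonal**
  (off-diagonal pairs counted twice — affects all states identically);
- `0·log 0 := 0`, covering `r̂ ∈ {0, 1}`;
- `σ̂²` is pooled over all nonzero unmasked entries of the whole matrix and
  **fixed across states** (the single `σ̂` outside the block sum; a
  per-block variance would make the Gaussian term state-trivial);
- variances use the population divisor (plug-in MLE form; the divisor
  choice shifts all states nearly equally);
- blocks with `S ≤ 1` contribute no Gaussian term;
- if every nonzero entry is identical (`σ̂² = 0`) the Gaussian term is 0
  with a warning.

Masked bins (row sum below `min_marginal`, default 1 raw contact) are
excluded from every count; a configuration that isolates a group with no
usable bin has prior mass zero (log-posterior `−inf`), which keeps the MH
kernel symmetric without constraining proposals.

## Inference

Exhaustive maximization is infeasible beyond toy sizes, so the MAP is
found by Metropolis–Hastings over fixed-`K` configurations:

- **Proposal**: pick one occupied gap and one unoccupied gap uniformly at
  random and swap them. The kernel is symmetric and irreducible over the
  fixed-`K` space, so moves are accepted with probability
  `min(1, exp(Δ log-posterior))`.
- **Initialization**: `K` evenly spaced CPs (deterministic, unbiased).
- **Chain length**: default `20·(n−1)` iterations. No burn-in is needed
  because only the best state visited (the MAP), not a posterior
  expectation, is used.
- **Implementation**: block statistics are O(1) rectangle queries on 2D
  prefix-sum tables built once per matrix over the mask-compressed
  entries, so one MH step costs O(K²) regardless of `n`.

`exhaustive_map` enumerates all `C(n−1, K)` states (guarded at 10⁶) and
serves as the correctness oracle for the sampler on small instances.

## Graph partitioning and A/B orientation

CP detection runs on the **raw** matrix, where distance decay has limited
influence on block statistics; partitioning runs on the **O/E-normalized**
matrix. The expected count per genomic separation is estimated from a
pseudo-bulk (sum over cells) rather than the sparse cell itself, which
would amplify noise. Bands with zero expected value map to O/E 0 (kept
finite, excluded from means through the mask).

The `K+1` loci groups become graph nodes; the edge weight between two
nodes is the mean O/E value over their block, with diagonal blocks kept as
self-loops (counted once in degrees and in `m = grand sum / 2`). The
normalized cut `min R/(κ₁κ₂)` is solved in relaxation by the
second-largest eigenvector `ν₂` of `D^(−1/2) A D^(−1/2)`. Numerical
choices:

- the trivial eigenpair (eigenvalue 1, eigenvector `D^(1/2)·1`) is
  deflated explicitly before taking the top remaining eigenpair, which
  also resolves the degenerate `λ₁ = λ₂` case of disconnected graphs;
- `ν₂` is unit length with its first nonzero entry positive, then rounded
  at 0 (the partition is robust to the rounding threshold);
- every bin inherits the `ν₂` value of its group.

If the Pearson correlation of the per-bin values with CpG density over
unmasked bins is negative, the values are negated; bins with value ≥ 0
are labeled A. `|corr| < weak_threshold` (default 0.2 — conservative; the
appropriate value is dataset-dependent, so weakness is surfaced in the
output rather than used to suppress calls) sets `weak_flag`, indicating
weak compartmentalization. Degenerate correlation (zero variance) leaves
the profile unoriented with a warning.

**Compartmental strength** is `−log₂(F)` with `F = (1 − λ₂)/(2m)`. Each
cell is annotated `n_repeats = 10` times from derived seeds; the reported
strength is the mean over repeats, while labels come from the repeat with
the highest MAP log-posterior (mixing labels across incompatible
segmentations would blur boundaries). A reference cutoff of 17.3 is
reported for context by the CLI `strength` command but never filters
results; `F = 0` (disconnected compartments) maps to `+inf`.

## Choosing K

`K` is a per-dataset hyperparameter chosen by a stability scan: for each
of `cells_for_K = 5` probe cells (the first cells in input order —
deterministic and cheap; the choice of subset is otherwise arbitrary),
annotations at consecutive candidates `(K, K_next)` are compared by
Pearson correlation of the real-valued profiles (> 0.8) and intersection
of the binary labels (> 0.9); the first stable `K` wins, with the largest
candidate as a warned fallback. The dataset `K` is the maximum over probe
cells and is then fixed for every cell. The default grid 10…200 step 10
targets 100 kb matrices (≈100 CPs per chromosome is reasonable); at 1 Mb
a 20–40 range fits better. Correlation is computed on the real-valued
profiles because binary agreement is already covered by the intersection
criterion.

The stability rule selects the smallest K at which annotations stop
changing, which can be below the planted boundary count when some planted
blocks are small relative to the chromosome (missing a small block costs
little intersection). This is intended behavior: the object of interest is
the per-bin A/B profile, not the segmentation itself.

## Synthetic data

`make_truth`/`sample_matrix` generate the planted-structure matrices used
throughout the tests: `K_true` boundaries drawn uniformly without
adjacency (no singleton groups), groups labeled A/B alternately, block
means `mu_within` (same-compartment) vs `mu_between` (cross-compartment),
optional exponential distance decay, Gaussian noise truncated at zero and
rounded to integer counts (real contact counts are integers; the inference
model still treats values as Gaussian), and Bernoulli dropout
(`dropout = 1 − P(observed)`).

Default study conditions: `n = 100`, `K_true = 7`, 5:1 mean ratio
(`mu_within = 10`, `mu_between = 2`), `noise_sd = 1`, dropout 0.7 for
single-cell-like matrices; `mu_within = 4000`, `mu_between = 800`,
`noise_sd = 50`, no dropout for pseudo-bulk-like matrices that are then
binomially downsampled at rates 1/400–1/3200 or subsampled to an exact
contact total (250–10 000) via a multivariate hypergeometric draw.

`shuffle_mix` destroys compartment structure while preserving the
distance-decay marginal by permuting entries **within each diagonal band**
(a global shuffle would also destroy distance decay, confounding the
strength statistic), then mixing: `round((1−f)·Y + f·shuffled)`.

What the generator does **not** emulate: genomic-distance-dependent noise
structure, translocations/CNVs, bin-level coverage biases (GC,
mappability), TAD-scale structure nested inside compartments, and
cell-cycle variation. Passing tests therefore demonstrate correctness of
the inference machinery under the stated block model, not performance on
any particular real dataset.

## Problem sizes in the test suite

Tests and the acceptance script run planted instances at `n = 30–100`
bins with 10³–2×10⁵ MH iterations and 20–100 replicate draws per
property — sizes chosen so each property is measured with usable
statistical resolution while the whole suite completes in minutes on one
core. All randomness is seed-derived; chains, generators and pipelines
are pure functions of their seeds.

## Known limitations

- Block-constant parameters are a deliberate simplification; with large
  `K` each block spans a small interval, making locally constant
  parameters a reasonable approximation.
- The MH sampler targets the MAP; posterior uncertainty over boundaries is
  not reported.
- O/E normalization relies on a pseudo-bulk expected profile; for a lone
  cell the package falls back to the cell's own profile with a warning,
  which is noisy at large separations.
- The strength statistic depends on `m` (total edge weight) and is
  comparable across cells within a dataset, not across resolutions.
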
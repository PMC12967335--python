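"""Synthetic single-cell Hi-C matrices with planted compartment structure.

The generator mirrors the inference model: a chromosome of ``n`` bins is
segmented by ``K_true`` change points into alternating A/B groups, giving
a checkerboard of blocks.  The latent signal in block (k,l) is Gaussian
with mean ``mu_within`` when the two groups share a compartment label and
``mu_between`` otherwise (optionally damped by an exponential distance
decay), truncated at zero and rounded to integer counts.  Sparsity enters
as independent Bernoulli dropout per bin pair.

Two downsampling protocols emulate published sparsity benchmarks:
binomial thinning at a fixed rate (pseudo-bulk downsampling, rates around
1/400-1/3200) and drawing an exact total number of contacts (imaging-data
downsampling, 250-10000 contacts per cell).  ``shuffle_mix`` degrades
compartment structure while preserving the distance-decay marginal by
permuting entries within each diagonal band, for permutation tests of the
compartmental-strength statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cp_model import ChangePointState, loci_groups
from .hic_io import ContactMatrix

__all__ = ["GroundTruth", "make_truth", "sample_matrix", "downsample", "shuffle_mix"]


@dataclass
class GroundTruth:
    """Planted compartment structure: boundaries, labels, block parameters."""

    n: int
    cp_state: ChangePointState
    node_labels: np.ndarray  # "A"/"B" per loci group
    mu: np.ndarray  # (K+1)x(K+1) block means of the latent signal
    r: np.ndarray  # (K+1)x(K+1) observation probabilities P(R_ij = 1)
    noise_sd: float
    decay_rate: float
    seed: int

    def bin_labels(self) -> np.ndarray:
        """Expand group labels to one label per bin."""
        out = np.empty(self.n, dtype=object)
        for (a, b), lab in zip(loci_groups(self.cp_state, self.n), self.node_labels):
            out[a:b] = lab
        return out

    def binary_bin_labels(self) -> np.ndarray:
        return (self.bin_labels() == "A").astype(float)


def make_truth(
    n: int,
    K_true: int,
    mu_within: float = 10.0,
    mu_between: float = 2.0,
    dropout_within: float = 0.7,
    dropout_between: float = 0.7,
    noise_sd: float = 1.0,
    decay_rate: float = 0.0,
    seed: int = 0,
) -> GroundTruth:
    """Plant ``K_true`` boundaries with alternating A/B labels.

    ``dropout_*`` are dropout probabilities, so the per-block observation
    probability is ``r = 1 - dropout``.  Boundaries are drawn uniformly
    without creating adjacent change points (no singleton groups),
    deterministically in ``seed``.
    """
    if not 0 <= K_true <= n - 2:
        raise ValueError("K_true must be in [0, n-2]")
    if mu_within < 0 or mu_between < 0 or mu_within < mu_between:
        raise ValueError("need mu_within >= mu_between >= 0 (planted structure)")
    for d in (dropout_within, dropout_between):
        if not 0 <= d <= 1:
            raise ValueError("dropout rates must lie in [0, 1]")
    if noise_sd < 0 or decay_rate < 0:
        raise ValueError("noise_sd and decay_rate must be non-negative")
    rng = np.random.default_rng(seed)
    positions: list = []
    if K_true:
        forbidden: set = set()
        avail = list(range(n - 1))
        for _ in range(K_true):
            choices = [p for p in avail if p not in forbidden]
            if not choices:
                raise ValueError("cannot place that many non-adjacent change points")
            p = int(rng.choice(choices))
            positions.append(p)
            forbidden.update({p - 1, p, p + 1})
        positions.sort()
    state = ChangePointState.from_positions(positions, n)
    G = K_true + 1
    labels = np.array(["A" if i % 2 == 0 else "B" for i in range(G)], dtype=object)
    same = labels[:, None] == labels[None, :]
    mu = np.where(same, mu_within, mu_between).astype(float)
    r = np.where(same, 1.0 - dropout_within, 1.0 - dropout_between).astype(float)
    return GroundTruth(
        n=n, cp_state=state, node_labels=labels, mu=mu, r=r,
        noise_sd=noise_sd, decay_rate=decay_rate, seed=seed,
    )


def _group_index(truth: GroundTruth) -> np.ndarray:
    gi = np.empty(truth.n, dtype=int)
    for g, (a, b) in enumerate(loci_groups(truth.cp_state, truth.n)):
        gi[a:b] = g
    return gi


def sample_matrix(truth: GroundTruth, seed: int = 0) -> ContactMatrix:
    """Draw one contact matrix: Y = R * round(max(X, 0)) per unordered pair."""
    rng = np.random.default_rng(seed)
    n = truth.n
    gi = _group_index(truth)
    mu_bin = truth.mu[np.ix_(gi, gi)]
    r_bin = truth.r[np.ix_(gi, gi)]
    if truth.decay_rate > 0:
        d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        mu_bin = mu_bin * np.exp(-truth.decay_rate * d)
    x = rng.normal(mu_bin, truth.noise_sd) if truth.noise_sd > 0 else mu_bin.copy()
    x = np.rint(np.maximum(x, 0.0))
    obs = rng.random((n, n)) < r_bin
    y = np.where(obs, x, 0.0)
    upper = np.triu(y, 1)  # sample once per unordered pair, then mirror
    y = np.diag(np.diag(y)) + upper + upper.T
    return ContactMatrix(values=y, mask=np.ones(n, dtype=bool))


def downsample(
    m: ContactMatrix,
    rate: float = None,
    target_contacts: int = None,
    seed: int = 0,
) -> ContactMatrix:
    """Thin a raw integer matrix to emulate single-cell sparsity.

    ``rate`` mode: each unordered-pair count is thinned Binomial(count,
    rate).  ``target_contacts`` mode: exactly that many contacts are drawn
    without replacement from the multiset of all contacts (multivariate
    hypergeometric).  Exactly one mode must be given.
    """
    if (rate is None) == (target_contacts is None):
        raise ValueError("give exactly one of rate / target_contacts")
    if m.normalized != "raw":
        raise ValueError("downsample operates on raw counts")
    counts = np.rint(m.values).astype(np.int64)
    if not np.allclose(counts, m.values):
        raise ValueError("downsample requires integer counts")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(m.n)
    vals = counts[iu]
    if rate is not None:
        if not 0 < rate <= 1:
            raise ValueError("rate must lie in (0, 1]")
        new = rng.binomial(vals, rate) if rate < 1 else vals
    else:
        total = int(vals.sum())
        if target_contacts > total:
            raise ValueError(f"target {target_contacts} exceeds total {total}")
        new = rng.multivariate_hypergeometric(vals, target_contacts)
    out = np.zeros_like(m.values)
    out[iu] = new
    out = out + np.triu(out, 1).T
    res = m.copy()
    res.values = out
    return res


def shuffle_mix(m: ContactMatrix, fraction: float, seed: int = 0) -> ContactMatrix:
    """Mix a band-shuffled copy into the matrix to erode compartment structure.

    Entries of each diagonal band of the upper triangle are permuted
    uniformly (preserving the distance-decay marginal), the result is
    mirrored, and the output is ``round((1-fraction)*m + fraction*shuffled)``.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    if m.normalized != "raw":
        raise ValueError("shuffle_mix operates on raw counts")
    rng = np.random.default_rng(seed)
    n = m.n
    shuf = np.zeros_like(m.values)
    for d in range(n):
        i = np.arange(n - d)
        band = m.values[i, i + d]
        shuf[i, i + d] = rng.permutation(band)
    upper = np.triu(shuf, 1)
    shuf = np.diag(np.diag(shuf)) + upper + upper.T
    mixed = np.rint((1.0 - fraction) * m.values + fraction * shuf)
    res = m.copy()
    res.values = mixed
    return res
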
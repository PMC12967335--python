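"""Bayesian 2D change-point detection on a single contact matrix.

The observed count for a bin pair is modeled as ``Y_ij = R_ij * X_ij``:
``X_ij`` is the latent contact intensity, Gaussian with a block-constant
mean and a shared variance, and ``R_ij`` is a Bernoulli dropout indicator
with a block-constant observation probability.  K change points (CPs) on
the bin axis tile the matrix into ``(K+1)^2`` blocks.  With a uniform
prior over the C(n-1, K) configurations, the log-posterior of a CP
configuration (after plugging in the per-block MLEs r-hat, mu-hat and the
pooled nonzero-entry variance sigma2-hat) is

    sum_kl [ S_kl log r_kl + (N_kl - S_kl) log(1 - r_kl) ]
        - (1 / (2 sigma2)) * sum_kl S_kl V_kl

where N_kl / S_kl are the total / nonzero pair counts of block (k,l) and
V_kl the population variance of its nonzero entries.  The maximizer is
found by Metropolis-Hastings over fixed-K configurations (the number of
configurations makes exhaustive search infeasible beyond toy sizes); an
exhaustive enumerator is provided as a small-instance oracle.

All sums run over the full symmetric matrix including the diagonal, so
off-diagonal pairs are counted twice; this scales every state's
log-posterior identically and leaves the ranking unchanged.  Masked bins
are excluded from every count, and any configuration that isolates a
group with no usable bin has prior mass zero (log-posterior -inf).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .hic_io import ContactMatrix

__all__ = [
    "ChangePointState",
    "BlockStats",
    "CPChain",
    "loci_groups",
    "block_stats",
    "log_posterior",
    "mh_sample",
    "map_changepoints",
    "exhaustive_map",
]


@dataclass(frozen=True)
class ChangePointState:
    """One-hot CP configuration over the n-1 inter-bin gaps."""

    gaps: tuple
    K: int

    @classmethod
    def from_positions(cls, positions, n: int) -> "ChangePointState":
        """Build from 0-based gap indices (gap p splits bins p and p+1)."""
        gaps = [0] * (n - 1)
        for p in positions:
            gaps[p] = 1
        return cls(gaps=tuple(gaps), K=len(set(positions)))

    def __post_init__(self):
        if sum(self.gaps) != self.K:
            raise ValueError("gap vector must contain exactly K ones")

    @property
    def positions(self) -> tuple:
        return tuple(i for i, g in enumerate(self.gaps) if g)


@dataclass
class BlockStats:
    """Per-block sufficient statistics of the dropout-aware block model."""

    N: np.ndarray
    S: np.ndarray
    mu_hat: np.ndarray
    V: np.ndarray
    r_hat: np.ndarray
    sigma2_hat: float


@dataclass
class CPChain:
    """Record of an MH run: visited states, log-posteriors, acceptances."""

    states: list
    log_posts: np.ndarray
    accepted: np.ndarray
    seed: int
    n_iter: int

    @property
    def acceptance_rate(self) -> float:
        return float(np.mean(self.accepted))


def loci_groups(state: ChangePointState, n: int):
    """Contiguous half-open bin ranges induced by the CP configuration."""
    if len(state.gaps) != n - 1:
        raise ValueError("state length does not match matrix dimension")
    bounds = [0] + [p + 1 for p in state.positions] + [n]
    return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


class _SuffStats:
    """Prefix-sum tables over the masked-compressed matrix.

    Masked rows/columns are dropped once; group boundaries are mapped into
    the compressed index space so every block statistic is an O(1)
    rectangle query.  sigma2_hat (pooled population variance of all
    nonzero unmasked entries, full matrix) is fixed per matrix and shared
    by every CP state.
    """

    def __init__(self, m: ContactMatrix):
        self.n = m.n
        keep = m.mask
        y = m.values[np.ix_(keep, keep)]
        z = (y != 0).astype(float)
        # cum[i, j] = sum over y[:i, :j]
        self.c_y = np.zeros((y.shape[0] + 1, y.shape[0] + 1))
        self.c_y2 = np.zeros_like(self.c_y)
        self.c_z = np.zeros_like(self.c_y)
        self.c_y[1:, 1:] = y.cumsum(0).cumsum(1)
        self.c_y2[1:, 1:] = (y**2).cumsum(0).cumsum(1)
        self.c_z[1:, 1:] = z.cumsum(0).cumsum(1)
        # bin index -> number of unmasked bins strictly before it
        self.compress = np.concatenate([[0], np.cumsum(keep)])
        nz = y[y != 0]
        s_tot = nz.size
        self.sigma2_hat = float(nz.var()) if s_tot > 0 else 0.0

    def _rect(self, table, r0, r1, c0, c1):
        return table[r1, c1] - table[r0, c1] - table[r1, c0] + table[r0, c0]

    def block_arrays(self, groups):
        """N, S, sum, sumsq per block for compressed group boundaries."""
        b = np.array([self.compress[a] for a, _ in groups] + [self.compress[self.n]])
        sizes = np.diff(b)
        if np.any(sizes == 0):
            return None  # a group holds only masked bins
        N = np.outer(sizes, sizes).astype(float)
        r0, r1 = b[:-1], b[1:]
        S = self._rect(self.c_z, r0[:, None], r1[:, None], r0[None, :], r1[None, :])
        Ysum = self._rect(self.c_y, r0[:, None], r1[:, None], r0[None, :], r1[None, :])
        Y2sum = self._rect(self.c_y2, r0[:, None], r1[:, None], r0[None, :], r1[None, :])
        return N, S, Ysum, Y2sum


def _stats_cache(m: ContactMatrix) -> _SuffStats:
    key = "_schicab_suffstats"
    cached = getattr(m, key, None)
    if cached is None:
        cached = _SuffStats(m)
        setattr(m, key, cached)
    return cached


def block_stats(m: ContactMatrix, state: ChangePointState) -> BlockStats:
    """Sufficient statistics (N, S, mu-hat, V, r-hat, sigma2-hat) per block.

    Sums run over the full symmetric matrix (both triangles plus the
    diagonal) with masked bins excluded.  Variances use the population
    divisor and are defined as 0 for blocks with at most one nonzero entry.
    """
    groups = loci_groups(state, m.n)
    ss = _stats_cache(m)
    arrays = ss.block_arrays(groups)
    if arrays is None:
        raise ValueError("a loci group contains only masked bins")
    N, S, Ysum, Y2sum = arrays
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = np.where(S > 0, Ysum / np.where(S > 0, S, 1), 0.0)
        V = np.where(S > 1, Y2sum / np.where(S > 0, S, 1) - mu**2, 0.0)
        V = np.maximum(V, 0.0)  # guard tiny negative round-off
        r = np.where(N > 0, S / np.where(N > 0, N, 1), 0.0)
    return BlockStats(
        N=N.astype(int), S=S.astype(int), mu_hat=mu, V=V, r_hat=r,
        sigma2_hat=ss.sigma2_hat,
    )


def _log_post_from_arrays(N, S, Ysum, Y2sum, sigma2):
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(N > 0, S / np.where(N > 0, N, 1), 0.0)
        # 0 log 0 := 0 covers r in {0, 1}
        t1 = np.where(S > 0, S * np.log(np.where(r > 0, r, 1)), 0.0)
        t2 = np.where(
            N - S > 0, (N - S) * np.log(np.where(r < 1, 1 - r, 1)), 0.0
        )
        mu = np.where(S > 0, Ysum / np.where(S > 0, S, 1), 0.0)
        SV = np.where(S > 1, Y2sum - S * mu**2, 0.0)
        SV = np.maximum(SV, 0.0)
    bern = float(t1.sum() + t2.sum())
    if sigma2 <= 0:
        return bern
    return bern - float(SV.sum()) / (2.0 * sigma2)


def log_posterior(m: ContactMatrix, state: ChangePointState) -> float:
    """Log-posterior (up to the shared uniform-prior constant) of a CP state."""
    groups = loci_groups(state, m.n)
    ss = _stats_cache(m)
    arrays = ss.block_arrays(groups)
    if arrays is None:
        return -math.inf
    if ss.sigma2_hat <= 0:
        warnings.warn(
            "all nonzero entries identical; Gaussian term undefined, set to 0",
            stacklevel=2,
        )
    return _log_post_from_arrays(*arrays, ss.sigma2_hat)


def _initial_positions(n: int, K: int) -> list:
    """K evenly spaced gap indices over the n-1 available gaps."""
    return [int((i + 1) * n / (K + 1)) - 1 for i in range(K)]


def mh_sample(
    m: ContactMatrix, K: int, n_iter: int = None, seed: int = 0
) -> CPChain:
    """Metropolis-Hastings over fixed-K change-point configurations.

    The proposal moves one CP: an occupied gap and an unoccupied gap are
    chosen uniformly at random and swapped.  The kernel is symmetric, so a
    move is accepted with probability ``min(1, exp(delta log-posterior))``.
    The chain starts from evenly spaced CPs and is reproducible from
    ``seed``.
    """
    n = m.n
    if not (1 <= K <= n - 2):
        raise ValueError(f"K must be in [1, {n - 2}] for n={n}")
    if n_iter is None:
        n_iter = 20 * (n - 1)
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    ss = _stats_cache(m)
    n_gaps = n - 1

    occupied = _initial_positions(n, K)
    occ_set = set(occupied)

    def lp(positions):
        st = ChangePointState.from_positions(sorted(positions), n)
        arrays = ss.block_arrays(loci_groups(st, n))
        if arrays is None:
            return -math.inf, st
        return _log_post_from_arrays(*arrays, ss.sigma2_hat), st

    cur_lp, cur_state = lp(occupied)
    states = [cur_state]
    log_posts = [cur_lp]
    accepted = [True]
    for _ in range(n_iter - 1):
        i = rng.integers(K)
        old = occupied[i]
        # uniform draw from the n_gaps - K unoccupied gaps
        j = int(rng.integers(n_gaps - K))
        new = -1
        cnt = -1
        for g in range(n_gaps):
            if g not in occ_set:
                cnt += 1
                if cnt == j:
                    new = g
                    break
        prop = occupied.copy()
        prop[i] = new
        prop_lp, prop_state = lp(prop)
        delta = prop_lp - cur_lp
        if delta >= 0 or (math.isfinite(delta) and rng.random() < math.exp(delta)):
            occupied = prop
            occ_set.discard(old)
            occ_set.add(new)
            cur_lp, cur_state = prop_lp, prop_state
            accepted.append(True)
        else:
            accepted.append(False)
        states.append(cur_state)
        log_posts.append(cur_lp)
    return CPChain(
        states=states,
        log_posts=np.array(log_posts),
        accepted=np.array(accepted, dtype=bool),
        seed=seed,
        n_iter=n_iter,
    )


def map_changepoints(chain: CPChain) -> ChangePointState:
    """The visited state of maximal log-posterior; ties go to the earliest."""
    if not chain.states:
        raise ValueError("empty chain")
    idx = int(np.argmax(chain.log_posts))
    return chain.states[idx]


def exhaustive_map(m: ContactMatrix, K: int) -> ChangePointState:
    """Global log-posterior maximizer by enumerating all C(n-1, K) states.

    This is feasible only for toy instances and serves as the oracle for
    :func:`mh_sample`; the state count is guarded at 10^6.
    """
    from itertools import combinations

    n = m.n
    if K == 0:
        return ChangePointState.from_positions([], n)
    n_states = math.comb(n - 1, K)
    if n_states > 10**6:
        raise ValueError(
            f"{n_states} states exceed the enumeration guard; use mh_sample"
        )
    ss = _stats_cache(m)
    best, best_lp = None, -math.inf
    for combo in combinations(range(n - 1), K):
        st = ChangePointState.from_positions(list(combo), n)
        arrays = ss.block_arrays(loci_groups(st, n))
        if arrays is None:
            continue
        v = _log_post_from_arrays(*arrays, ss.sigma2_hat)
        if v > best_lp:
            best, best_lp = st, v
    if best is None:
        raise ValueError("no valid state (masking leaves empty groups everywhere)")
    return best
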
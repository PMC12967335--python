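"""Normalized-cut partitioning of the block graph into two compartments.

Once change points segment the chromosome into K+1 loci groups, the O/E
matrix is collapsed to a (K+1)-node weighted graph: the edge weight
between two groups is the mean O/E value over their block (diagonal
blocks become self-loops).  The two-compartment split minimizes the
normalized cut R / (kappa1 * kappa2), where R is the total weight cut and
kappa1, kappa2 the degree sums of the two sides; the relaxed solution is
the second-largest eigenvector nu2 of D^(-1/2) A D^(-1/2), rounded at 0.

The quality of the optimum, F = (1 - lambda2) / (2m), yields the
compartmental-strength statistic -log2(F): sharper bipartitions give
smaller F and larger strength.  A/B orientation (which side is the active
A compartment) is decided post hoc by correlating nu2 with CpG density.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr

from .cp_model import ChangePointState, loci_groups
from .hic_io import ContactMatrix, CpGTrack

__all__ = [
    "WeightedGraph",
    "PartitionResult",
    "CompartmentProfile",
    "block_graph",
    "spectral_ncut",
    "brute_force_ncut",
    "assign_ab",
    "compartment_strength",
]

#: strength threshold the authors of the method use in practice to flag
#: cells with a clear two-compartment structure
STRENGTH_REFERENCE_CUTOFF = 17.3


@dataclass
class WeightedGraph:
    """Symmetric weighted block graph with self-loops kept on the diagonal."""

    weights: np.ndarray
    node_sizes: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(self.weights < 0) or not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite and non-negative")
        self.node_sizes = np.asarray(self.node_sizes, dtype=int)

    @property
    def degrees(self) -> np.ndarray:
        return self.weights.sum(axis=1)

    @property
    def total_weight_m(self) -> float:
        return float(self.weights.sum()) / 2.0


@dataclass
class PartitionResult:
    """Bipartition of the block graph with its spectral quantities.

    ``side`` is 1 where the (sign-fixed) second eigenvector is >= 0.
    ``F = (1 - lambda2) / (2m)`` measures the residual coupling between
    the two sides; brute-force results carry no eigen quantities.
    """

    side: np.ndarray
    cut_R: float
    kappa1: float
    kappa2: float
    objective: float
    nu2: np.ndarray = None
    lambda2: float = None
    F: float = None
    total_weight_m: float = None


@dataclass
class CompartmentProfile:
    """Per-bin A/B calls for one cell: labels, Ncut values, strength."""

    labels: np.ndarray  # "A", "B" or "NA" per bin
    ncut_values: np.ndarray  # oriented nu2 value inherited by each bin
    cpg_corr: float
    strength: float = math.nan
    weak_flag: bool = False
    K_used: int = 0
    seed_list: tuple = ()
    chrom: str = "chr"
    resolution: int = 100_000
    bin_start: int = 0
    log_posterior: float = math.nan

    def binary_labels(self) -> np.ndarray:
        """Labels as floats: A=1, B=0, masked=NaN."""
        out = np.full(len(self.labels), np.nan)
        out[self.labels == "A"] = 1.0
        out[self.labels == "B"] = 0.0
        return out


def block_graph(oe: ContactMatrix, state: ChangePointState) -> WeightedGraph:
    """Collapse an O/E matrix to block means over a CP segmentation.

    Edge weight (k,l) is the mean O/E value over unmasked bin pairs of
    block (k,l); diagonal blocks become self-loop weights.  Empty blocks
    (no unmasked pair) get weight 0.
    """
    if oe.normalized != "oe":
        raise ValueError("block_graph expects an O/E-normalized matrix")
    groups = loci_groups(state, oe.n)
    keep = oe.mask
    sizes = np.array([keep[a:b].sum() for a, b in groups])
    if np.any(sizes == 0):
        raise ValueError("a loci group contains only masked bins")
    G = len(groups)
    w = np.zeros((G, G))
    idx = [np.flatnonzero(keep[a:b]) + a for a, b in groups]
    for k in range(G):
        for l in range(k, G):
            block = oe.values[np.ix_(idx[k], idx[l])]
            w[k, l] = w[l, k] = block.mean() if block.size else 0.0
    return WeightedGraph(weights=w, node_sizes=np.array([b - a for a, b in groups]))


def _cut_quantities(weights: np.ndarray, side: np.ndarray):
    d = weights.sum(axis=1)
    s1 = side == 1
    cut = float(weights[np.ix_(s1, ~s1)].sum())
    k1, k2 = float(d[s1].sum()), float(d[~s1].sum())
    obj = cut / (k1 * k2) if k1 > 0 and k2 > 0 else math.nan
    return cut, k1, k2, obj


def spectral_ncut(g: WeightedGraph) -> PartitionResult:
    """Relaxed normalized cut via the second eigenvector of D^-1/2 A D^-1/2.

    The eigenvector paired with the largest eigenvalue is always
    D^(1/2)·1 (the trivial direction); nu2 is the top eigenvector of the
    orthogonal complement, which handles degenerate lambda1 = lambda2 for
    disconnected graphs.  nu2 is unit length with its first nonzero entry
    positive; nodes with nu2 >= 0 form side 1.
    """
    A = g.weights
    if A.shape[0] < 2:
        raise ValueError("need at least 2 nodes to partition")
    d = g.degrees
    if np.any(d <= 0):
        raise ValueError("zero-degree node; mask or merge empty groups first")
    dinv = 1.0 / np.sqrt(d)
    M = A * np.outer(dinv, dinv)
    triv = np.sqrt(d)
    triv = triv / np.linalg.norm(triv)
    # deflate the trivial eigenpair (eigenvalue 1, eigenvector D^(1/2)·1) so
    # the top remaining eigenpair is well defined even when lambda1 = lambda2
    # (disconnected graphs)
    evals, evecs = np.linalg.eigh(M - 4.0 * np.outer(triv, triv))
    lam2 = float(evals[-1])
    nu2 = evecs[:, -1].copy()
    nu2 -= (nu2 @ triv) * triv  # numerical hygiene
    nu2 /= np.linalg.norm(nu2)
    nz = np.flatnonzero(np.abs(nu2) > 1e-12)
    if nz.size and nu2[nz[0]] < 0:
        nu2 = -nu2
    side = (nu2 >= 0).astype(int)
    m = g.total_weight_m
    F = (1.0 - lam2) / (2.0 * m)
    if side.min() == side.max():
        warnings.warn(
            "second eigenvector does not change sign; bipartition degenerate",
            stacklevel=2,
        )
        return PartitionResult(
            side=side, cut_R=0.0, kappa1=float(d.sum()), kappa2=0.0,
            objective=math.nan, nu2=nu2, lambda2=lam2, F=max(F, 0.0),
            total_weight_m=m,
        )
    cut, k1, k2, obj = _cut_quantities(A, side)
    return PartitionResult(
        side=side, cut_R=cut, kappa1=k1, kappa2=k2, objective=obj,
        nu2=nu2, lambda2=lam2, F=max(F, 0.0), total_weight_m=m,
    )


def brute_force_ncut(g: WeightedGraph) -> PartitionResult:
    """Exact minimizer of R/(kappa1*kappa2) over all nontrivial bipartitions.

    Test oracle for :func:`spectral_ncut`; exponential, guarded at 20 nodes.
    Ties break to the lexicographically smallest side vector.
    """
    V = g.weights.shape[0]
    if V > 20:
        raise ValueError("brute force limited to 20 nodes")
    if V < 2:
        raise ValueError("need at least 2 nodes")
    best = None
    best_key = None
    for mask in range(1, 2 ** (V - 1)):
        side = np.array([(mask >> i) & 1 for i in range(V)], dtype=int)
        cut, k1, k2, obj = _cut_quantities(g.weights, side)
        if math.isnan(obj):
            continue
        key = (obj, tuple(side))
        if best_key is None or key < best_key:
            best_key = key
            best = PartitionResult(
                side=side, cut_R=cut, kappa1=k1, kappa2=k2, objective=obj,
                total_weight_m=g.total_weight_m,
            )
    if best is None:
        raise ValueError("no valid bipartition (isolated zero-degree nodes?)")
    return best


def assign_ab(
    partition: PartitionResult,
    state: ChangePointState,
    cpg: CpGTrack,
    n: int,
    mask: np.ndarray = None,
    weak_threshold: float = 0.2,
) -> CompartmentProfile:
    """Orient the bipartition into A/B labels using CpG density.

    Each bin inherits the nu2 value of its loci group.  If the Pearson
    correlation between the per-bin values and CpG density (over unmasked
    bins) is negative the values are negated, so the A side (value >= 0)
    is the CpG-rich, active side.  A small |correlation| flags weak
    compartmentalization but never suppresses the call.
    """
    if len(cpg.values) != n:
        raise ValueError("CpG track length must equal bin count")
    if mask is None:
        mask = np.ones(n, dtype=bool)
    groups = loci_groups(state, n)
    per_bin = np.empty(n)
    for (a, b), v in zip(groups, partition.nu2):
        per_bin[a:b] = v
    x, y = per_bin[mask], cpg.values[mask]
    corr = math.nan
    if x.size >= 2 and np.std(x) > 0 and np.std(y) > 0:
        corr = float(pearsonr(x, y)[0])
    if math.isnan(corr):
        warnings.warn(
            "CpG correlation undefined; profile left unoriented", stacklevel=2
        )
        weak = True
    else:
        if corr < 0:
            per_bin = -per_bin
        weak = abs(corr) < weak_threshold
    labels = np.where(per_bin >= 0, "A", "B").astype(object)
    labels[~mask] = "NA"
    return CompartmentProfile(
        labels=np.asarray(labels, dtype=object),
        ncut_values=np.where(mask, per_bin, np.nan),
        cpg_corr=corr,
        weak_flag=weak,
        chrom=cpg.chrom,
        resolution=cpg.resolution,
    )


def compartment_strength(results: list) -> float:
    """Mean of -log2(F) over repeated partitions of one cell.

    F = 0 (perfectly disconnected compartments) maps to +inf and
    propagates through the mean.
    """
    if not results:
        raise ValueError("need at least one partition result")
    vals = []
    for r in results:
        if r.F is None:
            raise ValueError("result lacks F (brute-force partitions have none)")
        if r.F < 0:
            raise ValueError("F < 0 violates the eigenvalue bound")
        vals.append(math.inf if r.F == 0 else -math.log2(r.F))
    return float(np.mean(vals))
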
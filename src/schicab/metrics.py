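"""Evaluation metrics and cross-cell heterogeneity summaries.

Label matrices are cells-by-bins arrays with A=1, B=0 and NaN for masked
bins.  Because A/B orientation is anchored externally by CpG density, the
agreement metrics never flip labels.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import pearsonr, spearmanr

__all__ = [
    "intersection",
    "per_locus_accuracy",
    "binary_variance",
    "stable_variable",
    "paired_correlation",
]


def _as_float(v):
    return np.asarray(v, dtype=float)


def intersection(pred, truth) -> float:
    """Fraction of jointly unmasked bins with identical A/B assignment."""
    pred, truth = _as_float(pred), _as_float(truth)
    if pred.shape != truth.shape:
        raise ValueError("label vectors must have equal length")
    ok = ~np.isnan(pred) & ~np.isnan(truth)
    if not ok.any():
        raise ValueError("no jointly unmasked positions")
    return float(np.mean(pred[ok] == truth[ok]))


def per_locus_accuracy(preds, truth) -> np.ndarray:
    """Per-bin fraction of cells assigning the bin to the correct compartment.

    NaN where no cell is jointly unmasked at that bin.
    """
    preds, truth = _as_float(preds), _as_float(truth)
    if preds.shape != truth.shape:
        raise ValueError("prediction and truth matrices must share shape")
    ok = ~np.isnan(preds) & ~np.isnan(truth)
    agree = (preds == truth) & ok
    counts = ok.sum(axis=0)
    with np.errstate(invalid="ignore"):
        acc = np.where(counts > 0, agree.sum(axis=0) / np.maximum(counts, 1), np.nan)
    return acc


def binary_variance(labels) -> np.ndarray:
    """Population variance p(1-p) of binary compartment labels per bin.

    p is the fraction of A among unmasked cells; values lie in [0, 0.25]
    with 0.25 attained only at a 50/50 split.  Bins with fewer than two
    unmasked cells get NaN.
    """
    labels = _as_float(labels)
    ok = ~np.isnan(labels)
    counts = ok.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(counts > 0, np.nansum(labels, axis=0) / np.maximum(counts, 1), np.nan)
    var = p * (1.0 - p)
    var[counts < 2] = np.nan
    return var


def stable_variable(variances, percentile: float = 50.0) -> np.ndarray:
    """Classify bins as 'stable' / 'variable' by variance percentile cutoffs.

    At percentile 50 the median splits the bins (ties land on the variable
    side).  At q < 50 the bottom q% are stable, the top q% variable, and
    the middle band 'NA'.  Quantiles use linear interpolation over non-NaN
    bins.
    """
    v = _as_float(variances)
    ok = ~np.isnan(v)
    if not ok.any():
        raise ValueError("all variances are NaN")
    if not (0 < percentile <= 50):
        raise ValueError("percentile must be in (0, 50]")
    out = np.full(v.shape, "NA", dtype=object)
    if percentile == 50:
        med = np.nanquantile(v, 0.5)
        out[ok & (v < med)] = "stable"
        out[ok & (v >= med)] = "variable"
    else:
        lo = np.nanquantile(v, percentile / 100.0)
        hi = np.nanquantile(v, 1.0 - percentile / 100.0)
        out[ok & (v <= lo)] = "stable"
        out[ok & (v >= hi)] = "variable"
    return out


def paired_correlation(a, b, method: str = "pearson") -> float:
    """Pearson or Spearman correlation over jointly non-NaN positions."""
    a, b = _as_float(a), _as_float(b)
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < 3:
        raise ValueError("need at least 3 jointly defined positions")
    x, y = a[ok], b[ok]
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("degenerate variance; correlation undefined", stacklevel=2)
        return float("nan")
    if method == "pearson":
        return float(pearsonr(x, y)[0])
    if method == "spearman":
        return float(spearmanr(x, y)[0])
    raise ValueError(f"unknown method {method!r}")
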
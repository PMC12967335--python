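"""Contact-matrix and genomic-track I/O, pseudo-bulk, and O/E normalization.

Single-cell Hi-C contact maps arrive in several shapes: cooler/mcool HDF5
files, dense whitespace-delimited dumps, or sparse ``bin_i bin_j count``
triplets.  Everything is held in memory as a symmetric dense
:class:`ContactMatrix` — at the 100 kb–1 Mb resolutions used for
compartment calling a chromosome is at most a few thousand bins, so dense
storage is cheap and keeps the downstream block arithmetic simple.

Distance decay is removed by observed/expected (O/E) normalization where
the expected contact frequency at each genomic separation is estimated
from a pseudo-bulk (summed) matrix rather than from the sparse single cell
itself, which would amplify noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "ContactMatrix",
    "ExpectedProfile",
    "CpGTrack",
    "read_matrix",
    "write_matrix",
    "pseudo_bulk",
    "expected_profile",
    "oe_normalize",
    "read_cpg_track",
    "mask_bins",
    "write_compartments",
]


@dataclass
class ContactMatrix:
    """A symmetric intrachromosomal contact matrix with bin metadata.

    Parameters
    ----------
    values
        ``(n, n)`` symmetric non-negative array of raw counts or O/E ratios.
    chrom
        Chromosome name.
    resolution
        Bin size in base pairs.
    bin_start
        Genomic start coordinate (bp) of bin 0.
    mask
        Boolean vector of length ``n``; ``True`` marks a usable bin.
    normalized
        ``"raw"`` for counts, ``"oe"`` after O/E normalization.
    """

    values: np.ndarray
    chrom: str = "chr"
    resolution: int = 100_000
    bin_start: int = 0
    mask: np.ndarray = None
    normalized: str = "raw"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("contact matrix must be square")
        if self.values.shape[0] < 2:
            raise ValueError("contact matrix needs n >= 2 bins")
        if np.any(self.values < 0):
            raise ValueError("contact matrix entries must be non-negative")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("contact matrix must be symmetric")
        if self.mask is None:
            self.mask = np.ones(self.values.shape[0], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (self.values.shape[0],):
                raise ValueError("mask length must match matrix dimension")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def copy(self) -> "ContactMatrix":
        return replace(self, values=self.values.copy(), mask=self.mask.copy())


@dataclass
class ExpectedProfile:
    """Mean contact count per genomic separation, from a pseudo-bulk matrix."""

    band_means: np.ndarray
    source_n_cells: int = 1

    def __post_init__(self):
        self.band_means = np.asarray(self.band_means, dtype=float)
        if np.any(self.band_means < 0):
            raise ValueError("expected band means must be non-negative")


@dataclass
class CpGTrack:
    """Per-bin CpG density for one chromosome at the matrix resolution."""

    values: np.ndarray
    chrom: str = "chr"
    resolution: int = 100_000

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("CpG track values must be finite")


# ---------------------------------------------------------------------------
# readers / writers


def _read_cooler(path: str, chrom: str, resolution: int) -> np.ndarray:
    """Read one chromosome from a cooler-schema HDF5 file.

    Accepts single-resolution ``.cool`` files (bins/pixels at the root) and
    multi-resolution ``.mcool`` files addressed either as
    ``file.mcool::resolutions/10000`` or located automatically from the
    requested resolution.
    """
    grp_path = "/"
    if "::" in path:
        path, grp_path = path.split("::", 1)
    with h5py.File(path, "r") as f:
        grp = f[grp_path]
        if "bins" not in grp and "resolutions" in grp:
            key = str(int(resolution))
            if key not in grp["resolutions"]:
                avail = ", ".join(grp["resolutions"].keys())
                raise ValueError(
                    f"resolution {resolution} not in file (available: {avail})"
                )
            grp = grp["resolutions"][key]
        binsize = int(grp.attrs.get("bin-size", resolution))
        if binsize != int(resolution):
            raise ValueError(
                f"file bin size {binsize} != requested resolution {resolution}"
            )
        chrom_names = [
            c.decode() if isinstance(c, bytes) else str(c)
            for c in grp["chroms/name"][:]
        ]
        if chrom not in chrom_names:
            raise ValueError(
                f"chromosome {chrom!r} not found; available: {', '.join(chrom_names)}"
            )
        cid = chrom_names.index(chrom)
        chrom_offset = grp["indexes/chrom_offset"][:]
        lo, hi = int(chrom_offset[cid]), int(chrom_offset[cid + 1])
        n = hi - lo
        bin1_offset = grp["indexes/bin1_offset"][:]
        plo, phi = int(bin1_offset[lo]), int(bin1_offset[hi])
        b1 = grp["pixels/bin1_id"][plo:phi]
        b2 = grp["pixels/bin2_id"][plo:phi]
        cnt = grp["pixels/count"][plo:phi].astype(float)
        # keep only intrachromosomal pixels
        keep = (b2 >= lo) & (b2 < hi)
        b1, b2, cnt = b1[keep] - lo, b2[keep] - lo, cnt[keep]
        m = np.zeros((n, n))
        np.add.at(m, (b1, b2), cnt)
        upper = np.triu(m, 1)
        return np.diag(np.diag(m)) + upper + upper.T


def _read_triplet(path: str) -> np.ndarray:
    df = pd.read_csv(
        path, sep=r"\s+", header=None, names=["i", "j", "count"], comment="#"
    )
    if (df["count"] < 0).any():
        raise ValueError("negative counts in triplet file")
    n = int(max(df["i"].max(), df["j"].max())) + 1
    n = max(n, 2)
    m = np.zeros((n, n))
    i = df["i"].to_numpy(dtype=int)
    j = df["j"].to_numpy(dtype=int)
    c = df["count"].to_numpy(dtype=float)
    # mirror-duplicates (i,j) vs (j,i) describe the same contact: sum once
    lo, hi = np.minimum(i, j), np.maximum(i, j)
    pair_ids = lo.astype(np.int64) * n + hi
    if len(np.unique(pair_ids)) < len(pair_ids):
        warnings.warn("duplicate (i,j)/(j,i) triplet entries summed", stacklevel=3)
    np.add.at(m, (lo, hi), c)
    upper = np.triu(m, 1)
    return np.diag(np.diag(m)) + upper + upper.T


def read_matrix(
    path: str,
    format_name: str,
    chrom: str = "chr",
    resolution: int = 100_000,
    bin_start: int = 0,
) -> ContactMatrix:
    """Read a contact matrix from ``cooler``, ``dense`` or ``triplet`` format.

    Triplet rows are ``bin_i bin_j count`` with 0-based indices; the result
    is always symmetrized, with (i,j)/(j,i) duplicates summed once.
    """
    if format_name == "cooler":
        values = _read_cooler(path, chrom, resolution)
    elif format_name == "dense":
        values = np.loadtxt(path, ndmin=2)
        if values.shape[0] != values.shape[1]:
            raise ValueError(
                f"dense matrix file is not square: shape {values.shape}"
            )
    elif format_name == "triplet":
        values = _read_triplet(path)
    else:
        raise ValueError(f"unknown format {format_name!r}")
    if np.any(values < 0):
        raise ValueError("negative counts in matrix file")
    return ContactMatrix(
        values=values, chrom=chrom, resolution=resolution, bin_start=bin_start
    )


def write_matrix(m: ContactMatrix, path: str, format_name: str = "dense") -> None:
    """Write a contact matrix as a dense table or upper-triangle triplets."""
    if format_name == "dense":
        np.savetxt(path, m.values, fmt="%.10g")
    elif format_name == "triplet":
        iu = np.triu_indices(m.n)
        vals = m.values[iu]
        nz = vals != 0
        df = pd.DataFrame({"i": iu[0][nz], "j": iu[1][nz], "count": vals[nz]})
        df.to_csv(path, sep="\t", header=False, index=False)
    else:
        raise ValueError(f"unknown format {format_name!r}")


# ---------------------------------------------------------------------------
# pseudo-bulk / expected / O/E


def pseudo_bulk(cells: list) -> ContactMatrix:
    """Element-wise sum of single-cell matrices; mask is the union of usable bins."""
    if not cells:
        raise ValueError("pseudo_bulk requires at least one cell")
    first = cells[0]
    total = np.zeros_like(first.values)
    mask = np.zeros(first.n, dtype=bool)
    for c in cells:
        if c.n != first.n or c.chrom != first.chrom or c.resolution != first.resolution:
            raise ValueError("all cells must share chrom, resolution and size")
        total += c.values
        mask |= c.mask
    return ContactMatrix(
        values=total,
        chrom=first.chrom,
        resolution=first.resolution,
        bin_start=first.bin_start,
        mask=mask,
    )


def expected_profile(bulk: ContactMatrix) -> ExpectedProfile:
    """Mean contact count at each genomic separation over unmasked bin pairs."""
    if bulk.normalized != "raw":
        raise ValueError("expected profile is computed from a raw-count matrix")
    n = bulk.n
    band_means = np.zeros(n)
    ok = bulk.mask
    for d in range(n):
        i = np.arange(n - d)
        valid = ok[i] & ok[i + d]
        if valid.any():
            band_means[d] = bulk.values[i[valid], i[valid] + d].mean()
    return ExpectedProfile(band_means=band_means, source_n_cells=1)


def oe_normalize(cell: ContactMatrix, expected: ExpectedProfile) -> ContactMatrix:
    """Observed/expected ratio per entry; zero-expected bands map to 0."""
    if cell.normalized != "raw":
        raise ValueError("matrix is already normalized")
    if len(expected.band_means) != cell.n:
        raise ValueError("expected profile length must equal matrix dimension")
    n = cell.n
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    exp = expected.band_means[d]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(exp > 0, cell.values / np.where(exp > 0, exp, 1.0), 0.0)
    return ContactMatrix(
        values=out,
        chrom=cell.chrom,
        resolution=cell.resolution,
        bin_start=cell.bin_start,
        mask=cell.mask.copy(),
        normalized="oe",
    )


def read_cpg_track(
    path: str, chrom: str, resolution: int, n: int, bin_start: int = 0
) -> CpGTrack:
    """Bin a bedGraph CpG-density track to per-bin coverage-weighted means.

    bedGraph intervals are 0-based half-open.  Bins with no coverage get 0.
    """
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chrom", "start", "end", "value"],
        comment="#",
    )
    df = df[df["chrom"] == chrom]
    if df.empty:
        raise ValueError(f"chromosome {chrom!r} absent from bedGraph {path}")
    weighted = np.zeros(n)
    coverage = np.zeros(n)
    for start, end, value in zip(df["start"], df["end"], df["value"]):
        s = max(int(start) - bin_start, 0)
        e = min(int(end) - bin_start, n * resolution)
        if e <= s:
            continue
        b0, b1 = s // resolution, (e - 1) // resolution
        for b in range(b0, b1 + 1):
            ov = min(e, (b + 1) * resolution) - max(s, b * resolution)
            weighted[b] += ov * value
            coverage[b] += ov
    vals = np.where(coverage > 0, weighted / np.where(coverage > 0, coverage, 1), 0.0)
    return CpGTrack(values=vals, chrom=chrom, resolution=resolution)


def mask_bins(m: ContactMatrix, min_marginal: float = 1.0) -> ContactMatrix:
    """Mask bins whose row sum falls below ``min_marginal`` raw contacts."""
    if m.normalized != "raw":
        raise ValueError("mask_bins operates on the raw matrix")
    marg = m.values.sum(axis=1)
    new_mask = m.mask & (marg >= min_marginal)
    if not new_mask.any():
        raise ValueError("all bins masked; lower min_marginal")
    out = m.copy()
    out.mask = new_mask
    return out


def write_compartments(profiles: list, path: str, format_name: str = "tsv") -> None:
    """Write per-cell compartment calls.

    ``bedgraph``: one file per cell (suffix ``_cell<i>.bedgraph``) with the
    real-valued Ncut value per bin.  ``tsv``: two cells-by-bins tables,
    ``<path>.labels.tsv`` with binary A/B labels (A=1, B=0, masked=NA) and
    ``<path>.ncut.tsv`` with the real values.  Coordinates 0-based half-open.
    """
    if not profiles:
        raise ValueError("no profiles to write")
    chrom = profiles[0].chrom
    res = profiles[0].resolution
    for p in profiles:
        if p.chrom != chrom or p.resolution != res:
            raise ValueError("profiles must share chrom and resolution")
    if format_name == "bedgraph":
        for idx, p in enumerate(profiles):
            fn = f"{path}_cell{idx}.bedgraph" if len(profiles) > 1 else f"{path}.bedgraph"
            with open(fn, "w") as fh:
                for b, v in enumerate(p.ncut_values):
                    s = p.bin_start + b * res
                    fh.write(f"{chrom}\t{s}\t{s + res}\t{v:.6g}\n")
    elif format_name == "tsv":
        labels = pd.DataFrame(
            [p.binary_labels() for p in profiles],
            columns=[f"bin{b}" for b in range(len(profiles[0].ncut_values))],
        )
        ncut = pd.DataFrame(
            [p.ncut_values for p in profiles], columns=labels.columns
        )
        labels.to_csv(f"{path}.labels.tsv", sep="\t", index=False, na_rep="NA")
        ncut.to_csv(f"{path}.ncut.tsv", sep="\t", index=False, na_rep="NA")
    else:
        raise ValueError(f"unknown format {format_name!r}")
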
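"""Binned Hi-C contact matrices: container, text readers/writers, submatrix
extraction and optional ICE balancing.

Matrices are dense, symmetric, nonnegative, per-chromosome. Bin ``i`` covers
``[start_bin + i*bin_size, start_bin + (i+1)*bin_size)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .genome_intervals import GenomicInterval

__all__ = ["BinIndex", "ContactMatrix", "read_contacts", "write_contacts",
           "extract_submatrix", "balance"]


@dataclass(frozen=True)
class BinIndex:
    chrom: str
    bin_size: int
    start_bin: int  # genomic coordinate of the first bin's left edge
    n_bins: int

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.n_bins <= 0:
            raise ValueError("n_bins must be positive")

    def bin_of(self, pos: int) -> int:
        """Index of the bin containing genomic position ``pos``."""
        i = (pos - self.start_bin) // self.bin_size
        if not 0 <= i < self.n_bins:
            raise IndexError(f"position {pos} outside bin index span {self.span()}")
        return int(i)

    def position_of(self, i: int) -> int:
        """Genomic coordinate of bin ``i``'s left edge."""
        return self.start_bin + i * self.bin_size

    def interval_of(self, i: int) -> GenomicInterval:
        p = self.position_of(i)
        return GenomicInterval(self.chrom, p, p + self.bin_size)

    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.start_bin, self.start_bin + self.n_bins * self.bin_size
        )


@dataclass
class ContactMatrix:
    """Symmetric, nonnegative binned contact counts for one chromosome."""

    bins: BinIndex
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError(f"counts must be square, got shape {c.shape}")
        if c.shape[0] != self.bins.n_bins:
            raise ValueError("counts shape does not match bin index")
        if not np.isfinite(c).all():
            raise ValueError("counts must be finite")
        if (c < 0).any():
            raise ValueError("counts must be nonnegative")
        if not np.allclose(c, c.T):
            raise ValueError("counts must be symmetric")
        self.counts = c

    @property
    def n_bins(self) -> int:
        return self.bins.n_bins


def _symmetrize_max(m: np.ndarray) -> np.ndarray:
    return np.maximum(m, m.T)


def read_contacts(
    path,
    format: str = "coo",
    bin_size: Optional[int] = None,
    region: Optional[GenomicInterval] = None,
    chrom: str = "",
) -> ContactMatrix:
    """Read a contact matrix from text.

    ``coo``: three whitespace-separated columns (bin_i_start, bin_j_start,
    count) — either triangle may be listed; the matrix is symmetrized by
    max-fill, and conflicting duplicates resolve to the larger value with a
    warning. ``dense``: a square whitespace-separated matrix (requires
    ``bin_size``; first bin starts at ``region.start`` or 0).
    """
    if format == "dense":
        m = np.loadtxt(path, ndmin=2)
        if m.shape[0] != m.shape[1]:
            raise ValueError(f"{path}: dense matrix is not square: {m.shape}")
        if (m < 0).any():
            raise ValueError(f"{path}: negative counts")
        if bin_size is None:
            raise ValueError("dense format requires bin_size")
        start = region.start if region is not None else 0
        bins = BinIndex(chrom or (region.chrom if region else ""), bin_size,
                        start, m.shape[0])
        return ContactMatrix(bins, _symmetrize_max(m))

    if format != "coo":
        raise ValueError(f"unknown format {format!r} (expected 'coo' or 'dense')")
    if bin_size is None:
        raise ValueError("coo format requires bin_size")

    data = np.loadtxt(path, ndmin=2)
    if data.size == 0:
        raise ValueError(f"{path}: empty COO file")
    if data.shape[1] != 3:
        raise ValueError(f"{path}: COO input must have 3 columns, got {data.shape[1]}")
    si, sj, v = data[:, 0], data[:, 1], data[:, 2]
    if (v < 0).any():
        raise ValueError(f"{path}: negative counts")
    if ((si % bin_size) != 0).any() or ((sj % bin_size) != 0).any():
        raise ValueError(f"{path}: bin starts are not multiples of bin_size={bin_size}")

    if region is not None:
        start, end = region.start, region.end
        chrom = chrom or region.chrom
    else:
        start = int(min(si.min(), sj.min()))
        end = int(max(si.max(), sj.max())) + bin_size
    start = (start // bin_size) * bin_size
    n = int(np.ceil((end - start) / bin_size))
    bins = BinIndex(chrom, bin_size, start, n)

    m = np.zeros((n, n))
    ii = ((si - start) // bin_size).astype(int)
    jj = ((sj - start) // bin_size).astype(int)
    inside = (ii >= 0) & (ii < n) & (jj >= 0) & (jj < n)
    conflict = False
    for i, j, c in zip(ii[inside], jj[inside], v[inside]):
        if m[i, j] != 0 and m[i, j] != c:
            conflict = True
        m[i, j] = max(m[i, j], c)
    if conflict:
        warnings.warn("conflicting duplicate COO entries resolved by max")
    return ContactMatrix(bins, _symmetrize_max(m))


def write_contacts(cm: ContactMatrix, path) -> None:
    """Write the upper triangle (incl. diagonal) as COO triplet text."""
    b = cm.bins
    with open(path, "w") as fh:
        iu, ju = np.triu_indices(cm.n_bins)
        for i, j in zip(iu, ju):
            c = cm.counts[i, j]
            if c != 0:
                fh.write(f"{b.position_of(i)}\t{b.position_of(j)}\t{c:g}\n")


def extract_submatrix(cm: ContactMatrix, region: GenomicInterval) -> ContactMatrix:
    """Submatrix over ``region``, boundaries snapped outward to bin edges."""
    b = cm.bins
    span = b.span()
    if region.chrom and span.chrom and region.chrom != span.chrom:
        raise ValueError(f"region chromosome {region.chrom!r} != matrix {span.chrom!r}")
    if region.start < span.start or region.end > span.end:
        raise ValueError(f"region {region.start}-{region.end} outside matrix span "
                         f"{span.start}-{span.end}")
    i0 = int((region.start - b.start_bin) // b.bin_size)
    i1 = int(np.ceil((region.end - b.start_bin) / b.bin_size))
    sub_bins = BinIndex(b.chrom, b.bin_size, b.position_of(int(i0)), int(i1 - i0))
    return ContactMatrix(sub_bins, cm.counts[i0:i1, i0:i1].copy())


def balance(
    cm: ContactMatrix,
    method: str = "none",
    max_iter: int = 200,
    tol: float = 1e-5,
) -> ContactMatrix:
    """Matrix balancing. ``ice`` iteratively corrects so that retained bins
    (those with positive marginal) have near-equal row sums; ``none`` is the
    identity.
    """
    if method == "none":
        return cm
    if method != "ice":
        raise ValueError(f"unknown balancing method {method!r}")
    c = cm.counts.copy()
    rowsum = c.sum(axis=1)
    retained = rowsum > 0
    if not retained.any():
        raise ValueError("cannot balance an all-zero matrix")
    bias = np.ones(cm.n_bins)
    for _ in range(max_iter):
        w = c * np.outer(bias, bias)
        s = w.sum(axis=1)
        mean_s = s[retained].mean()
        cv = s[retained].std() / mean_s
        if cv < tol:
            break
        adj = np.ones_like(s)
        adj[retained] = s[retained] / mean_s
        bias /= np.sqrt(adj)
    return ContactMatrix(cm.bins, c * np.outer(bias, bias))
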
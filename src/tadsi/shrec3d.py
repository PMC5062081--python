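"""ShRec3D-style 3D reconstruction of a chromatin region from its Hi-C
submatrix.

Contact frequencies are converted to dissimilarities (d = 1/c^alpha), the
incomplete dissimilarity matrix is completed to a metric by all-pairs
shortest paths, and classical (Torgerson) multidimensional scaling embeds
the bins in 3D. Per-bin annotations (e.g. a ChIP-seq signal) can be
overlaid on the coordinates for rendering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import orthogonal_procrustes
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .boundaries import BoundaryCall
from .genome_intervals import CREvent, GenomicInterval
from .hic_matrix import BinIndex, ContactMatrix, extract_submatrix

__all__ = [
    "DistanceMatrix",
    "Coords3D",
    "contacts_to_distances",
    "shortest_path_completion",
    "classical_mds",
    "procrustes_rmsd",
    "model_region",
    "annotate_coords",
    "write_xyz",
    "write_pdb",
]


@dataclass
class DistanceMatrix:
    bins: BinIndex
    d: np.ndarray
    complete: bool = False

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        self.d = d


@dataclass
class Coords3D:
    bins: BinIndex
    xyz: np.ndarray                      # n x 3, centered
    eigenvalues: np.ndarray = field(default_factory=lambda: np.zeros(0))
    strain: float = 0.0                  # sum|negative eigenvalues| / sum|all|
    annotation: Optional[np.ndarray] = None
    cr_mask: Optional[np.ndarray] = None  # bins overlapping the modeled CR


def contacts_to_distances(cm: ContactMatrix, alpha: float = 1.0) -> DistanceMatrix:
    """d[i,j] = 1 / c[i,j]^alpha for positive contacts; bins with zero
    contact are unreachable (inf) until shortest-path completion; d[i,i] = 0.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    c = cm.counts
    d = np.full(c.shape, np.inf)
    pos = c > 0
    d[pos] = 1.0 / np.power(c[pos], alpha)
    np.fill_diagonal(d, 0.0)
    complete = bool(np.isfinite(d).all())
    return DistanceMatrix(cm.bins, d, complete=complete)


def shortest_path_completion(dm: DistanceMatrix) -> DistanceMatrix:
    """Complete the dissimilarity matrix to a metric by all-pairs shortest
    paths over the graph of finite entries."""
    d = dm.d
    n = d.shape[0]
    finite = np.isfinite(d) & ~np.eye(n, dtype=bool)
    graph = csr_matrix(np.where(finite, d, 0.0))
    n_comp, labels = connected_components(graph, directed=False)
    if n_comp > 1 and n > 1:
        groups = [list(np.flatnonzero(labels == k)) for k in range(n_comp)]
        raise ValueError(
            f"contact graph is disconnected ({n_comp} components): {groups}"
        )
    sp = shortest_path(graph, method="auto", directed=False)
    np.fill_diagonal(sp, 0.0)
    return DistanceMatrix(dm.bins, sp, complete=True)


def classical_mds(dm: DistanceMatrix, dim: int = 3) -> Coords3D:
    """Torgerson classical MDS: double-center B = -1/2 J D^2 J, take the
    top ``dim`` eigenpairs, scale eigenvectors by sqrt(eigenvalue).

    Negative eigenvalues among the retained spectrum (non-Euclidean input)
    are clipped to zero with a warning; the reported strain is
    sum|negative eigenvalues| / sum|all eigenvalues| over the full spectrum.
    Rank-deficient inputs (e.g. 2 points, collinear points) embed with the
    surplus coordinates identically zero.
    """
    if not dm.complete:
        raise ValueError("distance matrix must be complete; run shortest_path_completion")
    d = dm.d
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points to embed")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    top = evals[:dim]
    if (top < -1e-9 * max(1.0, abs(evals[0]))).any():
        warnings.warn(
            "negative eigenvalues among the top spectrum: distances are not "
            "Euclidean-embeddable in the requested dimension"
        )
    lam = np.clip(top, 0.0, None)
    xyz = evecs[:, :dim] * np.sqrt(lam)
    xyz = xyz - xyz.mean(axis=0)
    total = np.abs(evals).sum()
    strain = float(np.abs(evals[evals < 0]).sum() / total) if total > 0 else 0.0
    return Coords3D(dm.bins, xyz, eigenvalues=evals[:dim], strain=strain)


def procrustes_rmsd(X: np.ndarray, Y: np.ndarray) -> float:
    """RMSD between two point sets after optimal translation and
    rotation/reflection (no scaling)."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {Y.shape}")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    r, _ = orthogonal_procrustes(Yc, Xc)
    diff = Xc - Yc @ r
    return float(np.sqrt((diff ** 2).sum() / X.shape[0]))


def _model_span(
    cm: ContactMatrix,
    cr: CREvent,
    flank: Optional[int],
    boundaries: Optional[Sequence[BoundaryCall]],
) -> GenomicInterval:
    span = cm.bins.span()
    if boundaries:
        lefts = [b.position for b in boundaries
                 if b.chrom == cr.interval.chrom and b.position <= cr.interval.start]
        rights = [b.position for b in boundaries
                  if b.chrom == cr.interval.chrom and b.position >= cr.interval.end]
        start = max(lefts) if lefts else span.start
        end = min(rights) + cm.bins.bin_size if rights else span.end
    else:
        f = 1_000_000 if flank is None else flank
        start = cr.interval.start - f
        end = cr.interval.end + f
    start = max(span.start, start)
    end = min(span.end, end)
    return GenomicInterval(span.chrom, start, end)


def model_region(
    cm: ContactMatrix,
    cr: CREvent,
    flank: Optional[int] = None,
    boundaries: Optional[Sequence[BoundaryCall]] = None,
    alpha: float = 1.0,
) -> Coords3D:
    """3D model of the TADs surrounding a CR.

    The modeled span snaps outward to the TAD boundaries flanking the CR
    when boundary calls are given, else extends by ``flank`` bp (default
    1 Mb), clipped to the matrix span. Bins overlapping the CR are flagged
    in ``cr_mask`` so renderers can highlight the rearranged segment.
    The pipeline is deterministic: no randomness in any stage.
    """
    region = _model_span(cm, cr, flank, boundaries)
    sub = extract_submatrix(cm, region)
    coords = classical_mds(shortest_path_completion(contacts_to_distances(sub, alpha)))
    mask = np.zeros(sub.n_bins, dtype=bool)
    for i in range(sub.n_bins):
        mask[i] = sub.bins.interval_of(i).overlaps(cr.interval)
    coords.cr_mask = mask
    return coords


def annotate_coords(coords: Coords3D, track: Sequence[float]) -> Coords3D:
    """Attach per-bin scalar annotation values (no smoothing)."""
    values = np.asarray(track, dtype=float)
    if values.shape != (coords.bins.n_bins,):
        raise ValueError(
            f"annotation length {values.shape} does not match {coords.bins.n_bins} bins"
        )
    coords.annotation = values
    return coords


def write_xyz(coords: Coords3D, path, header: str = "") -> None:
    """TSV: chrom, start, end, x, y, z[, annotation][, in_cr]."""
    b = coords.bins
    with open(path, "w") as fh:
        if header:
            for line in header.rstrip().split("\n"):
                fh.write(f"# {line}\n")
        cols = ["chrom", "start", "end", "x", "y", "z"]
        if coords.annotation is not None:
            cols.append("annotation")
        if coords.cr_mask is not None:
            cols.append("in_cr")
        fh.write("\t".join(cols) + "\n")
        for i in range(b.n_bins):
            iv = b.interval_of(i)
            row = [iv.chrom, str(iv.start), str(iv.end)]
            row += [f"{v:.6f}" for v in coords.xyz[i]]
            if coords.annotation is not None:
                row.append(f"{coords.annotation[i]:.6g}")
            if coords.cr_mask is not None:
                row.append("1" if coords.cr_mask[i] else "0")
            fh.write("\t".join(row) + "\n")


def write_pdb(coords: Coords3D, path) -> None:
    """Minimal PDB-like file: one pseudo-atom per bin, CONECT along the
    chain, chain B for bins inside the CR."""
    xyz = coords.xyz
    scale = 10.0 / max(np.abs(xyz).max(), 1e-12)
    with open(path, "w") as fh:
        for i in range(xyz.shape[0]):
            chain = "B" if (coords.cr_mask is not None and coords.cr_mask[i]) else "A"
            x, y, z = xyz[i] * scale
            fh.write(
                f"ATOM  {i + 1:5d}  CA  BIN {chain}{(i + 1) % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
        for i in range(1, xyz.shape[0]):
            fh.write(f"CONECT{i:5d}{i + 1:5d}\n")
        fh.write("END\n")
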
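"""Synthetic TAD-structured Hi-C data, enhancer tracks and labelled CR
events for testing every pipeline stage without external downloads.

The contact model is a power-law distance decay with a block enrichment for
bin pairs inside the same TAD:

    lambda(i, j) = A * (|i - j| + 1)^(-gamma) * (f if same TAD else 1)

with optional Poisson noise. TAD membership is defined by a list of planted
boundary *elements* (bin indices): boundary ``t`` separates bins ``t-1``
and ``t``.

Two rearrangement routes exist. :func:`apply_rearrangement` remaps the
wild-type matrix by bin index (c'(i,j) = c(m(i), m(j))) — the contact
pattern travels with the sequence, so cross-junction depletion is
preserved. :func:`simulate_rearranged` instead rebuilds the expected
contact model of the rearranged genome from its surviving boundary
elements, with distance decay in the *new* coordinates: deleting a
boundary element there merges the flanking TADs, the classic
enhancer-hijacking scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome_intervals import CREvent, EnhancerTrack, GenomicInterval, overlap_bp, window_around
from .hic_matrix import BinIndex, ContactMatrix

__all__ = [
    "SyntheticConfig",
    "simulate_contact_matrix",
    "simulate_enhancers",
    "simulate_crs",
    "apply_rearrangement",
    "rearranged_truth",
    "simulate_rearranged",
    "truth_positions",
]


@dataclass(frozen=True)
class SyntheticConfig:
    n_bins: int = 500
    bin_size: int = 10_000
    boundary_positions: tuple = (100, 200, 300, 400)  # bin indices
    decay_exponent: float = 1.0       # gamma
    within_tad_enrichment: float = 3.0  # f
    base_intensity: float = 100.0     # A
    noise: str = "poisson"            # {"none", "poisson"}
    seed: int = 0
    chrom: str = "chrS"
    start_bin: int = 0

    def __post_init__(self) -> None:
        bp = tuple(self.boundary_positions)
        if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
            raise ValueError("boundary positions must be strictly increasing")
        if bp and not (0 < bp[0] and bp[-1] < self.n_bins):
            raise ValueError("boundary positions must lie inside (0, n_bins)")
        if self.within_tad_enrichment < 1:
            raise ValueError("within_tad_enrichment must be >= 1")
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be positive")
        if self.base_intensity <= 0:
            raise ValueError("base_intensity must be positive")
        if self.noise not in ("none", "poisson"):
            raise ValueError(f"unknown noise model {self.noise!r}")

    def bin_index(self) -> BinIndex:
        return BinIndex(self.chrom, self.bin_size, self.start_bin, self.n_bins)


def truth_positions(cfg: SyntheticConfig) -> list[int]:
    """Genomic coordinates (bin left edges) of the planted boundaries."""
    return [cfg.start_bin + t * cfg.bin_size for t in cfg.boundary_positions]


def _expected_matrix(cfg: SyntheticConfig) -> np.ndarray:
    idx = np.arange(cfg.n_bins)
    dist = np.abs(idx[:, None] - idx[None, :])
    lam = cfg.base_intensity * np.power(dist + 1.0, -cfg.decay_exponent)
    tad = np.searchsorted(np.asarray(cfg.boundary_positions), idx, side="right")
    same = tad[:, None] == tad[None, :]
    lam = np.where(same, lam * cfg.within_tad_enrichment, lam)
    return lam


def simulate_contact_matrix(cfg: SyntheticConfig) -> tuple[ContactMatrix, np.ndarray]:
    """Simulate a TAD-block contact matrix; returns the matrix and the
    planted boundary bin indices (the ground truth)."""
    lam = _expected_matrix(cfg)
    if cfg.noise == "none":
        counts = lam
    else:
        rng = np.random.default_rng(cfg.seed)
        iu = np.triu_indices(cfg.n_bins)
        sampled = rng.poisson(lam[iu]).astype(float)
        counts = np.zeros_like(lam)
        counts[iu] = sampled
        counts = counts + np.triu(counts, 1).T
    return (
        ContactMatrix(cfg.bin_index(), counts),
        np.asarray(cfg.boundary_positions, dtype=int),
    )


def simulate_enhancers(
    bins: BinIndex,
    density: float = 0.05,
    mean_length: int = 2_000,
    hotspot_positions: Optional[Sequence[int]] = None,
    hotspot_width: int = 400_000,
    hotspot_fraction: float = 0.7,
    seed: int = 0,
    max_tries: int = 200_000,
) -> EnhancerTrack:
    """Random non-overlapping enhancer intervals covering ~``density`` of
    the span; ``hotspot_positions`` (genomic coords) concentrate a fraction
    of the placements near those loci."""
    if not 0 <= density < 1:
        raise ValueError("density must be in [0, 1)")
    span = bins.span()
    span_len = len(span)
    target = int(density * span_len)
    if target == 0:
        return EnhancerTrack([])
    rng = np.random.default_rng(seed)
    occupied = np.zeros(span_len, dtype=bool)
    intervals: list[GenomicInterval] = []
    covered = 0
    tries = 0
    hotspots = list(hotspot_positions) if hotspot_positions else []
    while covered < target:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place enhancers to density {density} after {max_tries} tries"
            )
        length = max(200, int(rng.exponential(mean_length)))
        if hotspots and rng.random() < hotspot_fraction:
            center = hotspots[rng.integers(len(hotspots))]
            pos = int(center + rng.integers(-hotspot_width // 2, hotspot_width // 2))
        else:
            pos = int(span.start + rng.integers(span_len))
        start = max(span.start, pos)
        end = min(span.end, start + length)
        if end <= start:
            continue
        s, e = start - span.start, end - span.start
        if occupied[s:e].any():
            continue
        occupied[s:e] = True
        covered += e - s
        intervals.append(GenomicInterval(span.chrom, start, end))
    return EnhancerTrack(intervals, frozenset({"synthetic_strong_enhancer"}))


def _window_coverage(
    cr: CREvent,
    enhancers: EnhancerTrack,
    anchors: Sequence[int],
    window_bp: int = 400_000,
) -> float:
    """Mean enhancer coverage fraction over the windows the scorer will
    inspect: the two breakpoints plus any extra anchors (the spanned
    boundary for boundary-spanning CRs)."""
    chrom = cr.interval.chrom
    fracs = []
    for pos in [cr.interval.start, cr.interval.end, *anchors]:
        w = window_around(pos, window_bp, chrom)
        fracs.append(overlap_bp(w, enhancers) / len(w))
    return float(np.mean(fracs))


def simulate_crs(
    truth_boundaries: Sequence[int],
    enhancers: EnhancerTrack,
    bins: BinIndex,
    n_pos: int = 20,
    n_neg: int = 20,
    seed: int = 0,
    background_density: float = 0.05,
    max_tries: int = 10_000,
) -> tuple[list[CREvent], pd.DataFrame]:
    """Place labelled CR events: positives span >= 1 planted boundary,
    negatives lie strictly inside one TAD. Types are drawn from
    {deletion, duplication, inversion}.

    Returns the events plus a truth table (cr_id, spans_boundary,
    enhancer_rich, expected_high_si); enhancer_rich is the measured
    breakpoint-window coverage relative to the background density.
    """
    rng = np.random.default_rng(seed)
    tb = sorted(int(t) for t in truth_boundaries)
    if not tb:
        raise ValueError("need at least one truth boundary to place positives")
    types = ("deletion", "duplication", "inversion")
    bs = bins.bin_size
    events: list[CREvent] = []
    rows: list[dict] = []

    def genomic(b: int) -> int:
        return bins.start_bin + b * bs

    for k in range(n_pos):
        placed = None
        for _ in range(max_tries):
            t = tb[rng.integers(len(tb))]
            left = int(rng.integers(15, 60))
            right = int(rng.integers(15, 60))
            b0, b1 = t - left, t + right
            if b0 <= 1 or b1 >= bins.n_bins - 1:
                continue
            iv = GenomicInterval(bins.chrom, genomic(b0), genomic(b1))
            cr = CREvent(f"pos_{k}", iv, types[rng.integers(3)])
            # require enhancer-rich scoring windows for positives
            if _window_coverage(cr, enhancers, [genomic(t)]) >= background_density:
                placed = cr
                break
            if placed is None:
                placed = cr  # best-effort fallback, richness re-measured below
        if placed is None:
            raise RuntimeError("could not place a boundary-spanning CR")
        events.append(placed)
        rows.append({"cr_id": placed.cr_id, "spans_boundary": True})

    # TADs as (start_bin, end_bin) segments between boundaries
    edges = [0] + tb + [bins.n_bins]
    tads = [(a, b) for a, b in zip(edges, edges[1:]) if b - a >= 20]
    if not tads:
        raise ValueError("no TAD wide enough to place intra-TAD negatives")
    for k in range(n_neg):
        for _ in range(max_tries):
            a, b = tads[rng.integers(len(tads))]
            length = int(rng.integers(10, max(11, (b - a) // 2)))
            b0 = int(rng.integers(a + 3, b - 3 - length)) if b - 6 - length > a + 3 else a + 3
            b1 = b0 + length
            if b1 >= b - 3:
                continue
            iv = GenomicInterval(bins.chrom, genomic(b0), genomic(b1))
            cr = CREvent(f"neg_{k}", iv, types[rng.integers(3)])
            events.append(cr)
            rows.append({"cr_id": cr.cr_id, "spans_boundary": False})
            break
        else:
            raise RuntimeError("could not place an intra-TAD CR")

    truth = pd.DataFrame(rows)
    tb_pos = [genomic(t) for t in tb]
    cov = []
    for cr in events:
        spanned = [p for p in tb_pos if cr.interval.start <= p < cr.interval.end]
        cov.append(_window_coverage(cr, enhancers, spanned[:1]))
    truth["enhancer_rich"] = [c >= background_density for c in cov]
    truth["expected_high_si"] = truth["spans_boundary"] & truth["enhancer_rich"]
    return events, truth


def _cr_bins(cm: ContactMatrix, cr: CREvent) -> tuple[int, int]:
    b = cm.bins
    span = b.span()
    iv = cr.interval
    if iv.start < span.start or iv.end > span.end:
        raise ValueError(f"CR {iv.start}-{iv.end} outside matrix span")
    b0 = (iv.start - b.start_bin) // b.bin_size
    b1 = int(np.ceil((iv.end - b.start_bin) / b.bin_size))
    return int(b0), int(b1)


def apply_rearrangement(cm: ContactMatrix, cr: CREvent) -> ContactMatrix:
    """Rearranged matrix by bin-index remapping: c'(i,j) = c(m(i), m(j)).

    deletion drops the CR bins; duplication inserts a second copy right
    after the original; inversion reverses the CR bin order.
    """
    b0, b1 = _cr_bins(cm, cr)
    n = cm.n_bins
    before = np.arange(0, b0)
    inside = np.arange(b0, b1)
    after = np.arange(b1, n)
    if cr.cr_type == "deletion":
        m = np.concatenate([before, after])
    elif cr.cr_type == "duplication":
        m = np.concatenate([before, inside, inside, after])
    elif cr.cr_type == "inversion":
        m = np.concatenate([before, inside[::-1], after])
    else:
        raise ValueError(f"cannot rearrange CR of type {cr.cr_type!r}")
    counts = cm.counts[np.ix_(m, m)]
    counts = np.maximum(counts, counts.T)  # exact symmetry despite remap
    bins = BinIndex(cm.bins.chrom, cm.bins.bin_size, cm.bins.start_bin, m.size)
    return ContactMatrix(bins, counts)


def rearranged_truth(cfg: SyntheticConfig, cr: CREvent) -> tuple[int, tuple]:
    """(new n_bins, new boundary-element positions) after applying ``cr``
    to the wild-type genome. Boundary elements inside a deletion are lost;
    a duplication copies them; an inversion reflects them within the CR."""
    bins = cfg.bin_index()
    b0 = (cr.interval.start - cfg.start_bin) // cfg.bin_size
    b1 = int(np.ceil((cr.interval.end - cfg.start_bin) / cfg.bin_size))
    tb = list(cfg.boundary_positions)
    k = b1 - b0
    if cr.cr_type == "deletion":
        new = [t for t in tb if t <= b0] + [t - k for t in tb if t >= b1]
        n = cfg.n_bins - k
    elif cr.cr_type == "duplication":
        new = (
            [t for t in tb if t <= b1]
            + [t + k for t in tb if b0 < t < b1]
            + [t + k for t in tb if t >= b1]
        )
        n = cfg.n_bins + k
    elif cr.cr_type == "inversion":
        new = [t for t in tb if t <= b0 or t >= b1] + [
            b0 + b1 - t for t in tb if b0 < t < b1
        ]
        n = cfg.n_bins
    else:
        raise ValueError(f"cannot rearrange CR of type {cr.cr_type!r}")
    new = sorted({t for t in new if 0 < t < n})
    return n, tuple(new)


def simulate_rearranged(cfg: SyntheticConfig, cr: CREvent) -> tuple[ContactMatrix, np.ndarray]:
    """Expected-contact model of the rearranged genome: surviving boundary
    elements, distance decay in post-rearrangement coordinates."""
    n, new_tb = rearranged_truth(cfg, cr)
    new_cfg = replace(cfg, n_bins=n, boundary_positions=new_tb)
    return simulate_contact_matrix(new_cfg)
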
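"""TAD boundary detection: per-bin insulation score, Dixon-style
directionality index (DI) with a 3-state Gaussian HMM, and boundary calls
with insulation-valley strengths.

The insulation score of bin *i* is the mean contact count in the square
window of bins upstream-vs-downstream of *i*; local minima of its log2
normalization mark insulating loci. The DI is a chi-square-like statistic of
upstream/downstream contact bias; an HMM segments it into upstream-biased,
downstream-biased and unbiased states, and a boundary is placed where an
upstream-biased run (domain end) hands over to a downstream-biased run
(domain start).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .hic_matrix import BinIndex, ContactMatrix

__all__ = [
    "InsulationTrack",
    "DITrack",
    "BoundaryCall",
    "insulation_track",
    "directionality_index",
    "fit_hmm_states",
    "call_boundaries",
    "boundary_strength",
    "write_bedgraph",
    "write_boundary_bed",
]

STATE_UPSTREAM = "upstream"
STATE_DOWNSTREAM = "downstream"
STATE_NONE = "none"


@dataclass
class InsulationTrack:
    bins: BinIndex
    raw: np.ndarray          # mean contact in the sliding square window
    normalized: np.ndarray   # log2(raw / mean raw over valid bins); NaN if invalid
    valid_mask: np.ndarray
    window_bins: int


@dataclass
class DITrack:
    bins: BinIndex
    di: np.ndarray
    A: np.ndarray  # upstream contact sum within window
    B: np.ndarray  # downstream contact sum within window


@dataclass(frozen=True)
class BoundaryCall:
    chrom: str
    position: int        # genomic coordinate (bin left edge)
    strength: float      # insulation valley depth, >= 0
    bin: int
    hmm_transition: bool = True


def insulation_track(
    cm: ContactMatrix,
    window_bins: int = 50,
    min_coverage_frac: float = 0.1,
) -> InsulationTrack:
    """Sliding-square insulation: raw(i) = mean of counts[i-w..i-1, i+1..i+w].

    Bins within ``window_bins`` of the matrix edge are invalid, as are
    low-coverage bins (row sum below ``min_coverage_frac`` of the median
    row sum) and bins with raw = 0.
    """
    w = int(window_bins)
    if w < 1:
        raise ValueError("window_bins must be >= 1")
    n = cm.n_bins
    if n < 2 * w + 1:
        raise ValueError(f"matrix too small ({n} bins) for window of {w} bins")
    c = cm.counts
    rowsum = c.sum(axis=1)
    covered = rowsum >= min_coverage_frac * np.median(rowsum)
    raw = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for i in range(w, n - w):
        raw[i] = c[i - w:i, i + 1:i + w + 1].mean()
        valid[i] = covered[i]
    mean_raw = np.nanmean(raw[valid])
    if not mean_raw > 0:
        raise ValueError("chromosome mean insulation is zero; matrix is empty "
                         "in all windows")
    normalized = np.full(n, np.nan)
    ok = valid & (raw > 0)
    normalized[ok] = np.log2(raw[ok] / mean_raw)
    valid = ok
    return InsulationTrack(cm.bins, raw, normalized, valid, w)


def directionality_index(cm: ContactMatrix, window_bp: int = 2_000_000) -> DITrack:
    """Dixon directionality index.

    For bin *i* with upstream sum A and downstream sum B within the window
    and E = (A+B)/2:  di = sign(B-A) * ((A-E)^2/E + (B-E)^2/E); di = 0 when
    A = B or A + B = 0. Windows truncate at chromosome ends.
    """
    bs = cm.bins.bin_size
    if window_bp % bs != 0:
        raise ValueError(f"window_bp={window_bp} is not a multiple of bin_size={bs}")
    w = window_bp // bs
    n = cm.n_bins
    if w >= n:
        raise ValueError(f"DI window of {w} bins exceeds chromosome ({n} bins)")
    c = cm.counts
    A = np.empty(n)
    B = np.empty(n)
    for i in range(n):
        A[i] = c[i, max(0, i - w):i].sum()
        B[i] = c[i, i + 1:i + 1 + w].sum()
    E = (A + B) / 2.0
    di = np.zeros(n)
    nz = E > 0
    dev = np.zeros(n)
    dev[nz] = (A[nz] - E[nz]) ** 2 / E[nz] + (B[nz] - E[nz]) ** 2 / E[nz]
    di[nz] = np.sign(B[nz] - A[nz]) * dev[nz]
    return DITrack(cm.bins, di, A, B)


def fit_hmm_states(
    di: DITrack,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-4,
    emissions: str = "gaussian",
) -> np.ndarray:
    """Segment the DI track with a 3-state HMM fit by EM.

    Initialization is deterministic (emission means at the 10/50/90 %
    quantiles of DI, shared variance, sticky transitions); decoding is
    Viterbi. States are labelled by fitted emission-mean sign: most negative
    mean -> "upstream", most positive -> "downstream", middle -> "none".
    ``emissions="mixture"`` uses a 3-component Gaussian mixture per state
    (the Dixon-style emission model) instead of a single Gaussian.
    """
    x = np.asarray(di.di, dtype=float)
    n = x.size
    if n < 50:
        raise ValueError(f"need >= 50 bins to fit the HMM, got {n}")
    if np.allclose(x, x[0]):
        # degenerate constant track: no directional signal anywhere
        return np.array([STATE_NONE] * n)

    from hmmlearn.hmm import GMMHMM, GaussianHMM

    q10, q50, q90 = np.quantile(x, [0.10, 0.50, 0.90])
    startprob = np.full(3, 1 / 3)
    transmat = np.array(
        [[0.90, 0.05, 0.05], [0.05, 0.90, 0.05], [0.05, 0.05, 0.90]]
    )
    var = max(x.var() / 4.0, 1e-6)
    if emissions == "gaussian":
        model = GaussianHMM(
            n_components=3, covariance_type="diag", init_params="",
            params="stmc", n_iter=max_iter, tol=tol, random_state=int(seed),
        )
        model.means_ = np.array([[q10], [q50], [q90]])
        model.covars_ = np.full((3, 1), var)
    elif emissions == "mixture":
        # convergence threshold kept loose: on a single long sequence the
        # mixture EM degenerates (point-mass components) if driven far past
        # convergence
        model = GMMHMM(
            n_components=3, n_mix=3, covariance_type="diag", init_params="",
            params="stmcw", n_iter=min(max_iter, 100), tol=max(tol, 1e-2),
            random_state=int(seed),
        )
        # per-state mixture components straddle the state's quantile mean
        offsets = np.array([-1.0, 0.0, 1.0]) * np.sqrt(var)
        model.means_ = np.array([[[q + o] for o in offsets] for q in (q10, q50, q90)])
        model.covars_ = np.full((3, 3, 1), var)
        model.weights_ = np.full((3, 3), 1 / 3)
    else:
        raise ValueError(f"unknown emission model {emissions!r}")
    model.startprob_ = startprob
    model.transmat_ = transmat

    X = x.reshape(-1, 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X)
    if not model.monitor_.converged or not np.isfinite(model.transmat_).all():
        raise RuntimeError(
            "HMM EM did not converge after "
            f"{max_iter} iterations (last log-likelihood "
            f"{model.monitor_.history[-1] if model.monitor_.history else float('nan')})"
        )
    decoded = model.predict(X)
    if emissions == "mixture":
        state_means = (model.means_[:, :, 0] * model.weights_).sum(axis=1)
    else:
        state_means = model.means_.ravel()
    order = np.argsort(state_means)
    label_of = {order[0]: STATE_UPSTREAM, order[1]: STATE_NONE, order[2]: STATE_DOWNSTREAM}
    # guard: if a fitted mean is essentially zero, treat it as "none"
    for k in (order[0], order[2]):
        if abs(state_means[k]) < 1e-9:
            label_of[k] = STATE_NONE
    return np.array([label_of[s] for s in decoded])


def boundary_strength(ins: InsulationTrack, bin: int, flank_bins: int) -> float:
    """Insulation valley depth at ``bin``:
    min(max normalized over left flank, max over right flank) - normalized(bin),
    clamped at 0. Flanks are restricted to valid bins.
    """
    if not (0 <= bin < ins.bins.n_bins) or not ins.valid_mask[bin]:
        raise ValueError(f"bin {bin} is not a valid insulation bin")
    z = ins.normalized
    left = z[max(0, bin - flank_bins):bin]
    right = z[bin + 1:bin + 1 + flank_bins]
    left = left[~np.isnan(left)]
    right = right[~np.isnan(right)]
    if left.size == 0 or right.size == 0:
        return 0.0
    depth = min(left.max(), right.max()) - z[bin]
    return float(max(0.0, depth))


def _local_minima(z: np.ndarray, valid: np.ndarray) -> np.ndarray:
    n = z.size
    mins = []
    for i in range(1, n - 1):
        if not (valid[i] and valid[i - 1] and valid[i + 1]):
            continue
        if z[i] <= z[i - 1] and z[i] <= z[i + 1]:
            mins.append(i)
    return np.asarray(mins, dtype=int)


def call_boundaries(
    states: np.ndarray,
    ins: InsulationTrack,
    search_bins: int = 5,
    flank_bins: int | None = None,
) -> list[BoundaryCall]:
    """Place a boundary between each upstream-biased run and the next
    downstream-biased run (domain end -> domain start, the Dixon
    convention), refined to the nearest local minimum of normalized
    insulation within ±``search_bins`` bins; strength is the insulation
    valley depth there.
    """
    states = np.asarray(states)
    if states.size != ins.bins.n_bins:
        raise ValueError("states and insulation track have different lengths")
    flank = ins.window_bins if flank_bins is None else flank_bins

    calls: list[BoundaryCall] = []
    minima = _local_minima(ins.normalized, ins.valid_mask)
    last_up: int | None = None
    used_bins: set[int] = set()
    i = 0
    n = states.size
    while i < n:
        if states[i] == STATE_UPSTREAM:
            last_up = i
        elif states[i] == STATE_DOWNSTREAM:
            if last_up is not None:
                center = (last_up + i) // 2
                b = _refine_to_minimum(center, minima, ins, search_bins)
                if b is not None and b not in used_bins:
                    strength = boundary_strength(ins, b, flank)
                    calls.append(
                        BoundaryCall(
                            chrom=ins.bins.chrom,
                            position=ins.bins.position_of(b),
                            strength=strength,
                            bin=b,
                        )
                    )
                    used_bins.add(b)
            last_up = None
            # skip to the end of this downstream run
            while i + 1 < n and states[i + 1] == STATE_DOWNSTREAM:
                i += 1
        i += 1
    calls.sort(key=lambda c: c.position)
    return calls


def _refine_to_minimum(center, minima, ins, search_bins):
    if minima.size:
        near = minima[np.abs(minima - center) <= search_bins]
        if near.size:
            return int(near[np.argmin(np.abs(near - center))])
    # no local minimum nearby: fall back to the transition midpoint if valid
    if 0 <= center < ins.bins.n_bins and ins.valid_mask[center]:
        return int(center)
    return None


def write_bedgraph(bins: BinIndex, values: np.ndarray, path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.rstrip().split("\n"):
                fh.write(f"# {line}\n")
        for i, v in enumerate(values):
            if np.isnan(v):
                continue
            iv = bins.interval_of(i)
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{v:.6g}\n")


def write_boundary_bed(calls: list[BoundaryCall], bin_size: int, path,
                       header: str = "") -> None:
    """BED6; score = strength * 1000, capped at 1000."""
    with open(path, "w") as fh:
        if header:
            for line in header.rstrip().split("\n"):
                fh.write(f"# {line}\n")
        for k, c in enumerate(calls):
            score = min(1000, int(round(c.strength * 1000)))
            fh.write(f"{c.chrom}\t{c.position}\t{c.position + bin_size}\t"
                     f"boundary_{k}\t{score}\t.\n")
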
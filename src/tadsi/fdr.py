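"""Permutation null for the SI score and FDR estimation.

The null shuffles the pairing between the insulation and enhancer
percentiles across CRs and recomputes the product score. The FDR of the
top set is the mean number of null scores exceeding the top-set threshold,
divided by the observed top-set size; the FDR of the mean SI across cell
lines is the minimum per-cell-line FDR.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Dict, Sequence

import numpy as np

__all__ = [
    "FDRReport",
    "top_threshold",
    "permutation_fdr",
    "mean_si_fdr",
    "per_cr_tail_fdr",
]


@dataclass
class FDRReport:
    threshold_c: float
    top_fraction: float
    n_top: int               # observed SI strictly above threshold_c (>= 1)
    n_top_strict: int        # the raw strict count, before the k fallback
    k: int                   # round(top_fraction * N)
    n_perms: int
    mean_null_exceed: float
    fdr: float
    seed: int

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s


def top_threshold(si: Sequence[float], top_fraction: float = 0.05) -> float:
    """The smallest score of the top ``top_fraction`` of SI values, i.e.
    the k-th largest with k = round(top_fraction * N)."""
    v = np.sort(np.asarray(si, dtype=float))[::-1]
    if v.size == 0:
        raise ValueError("empty SI list")
    k = int(round(top_fraction * v.size))
    if k < 1:
        raise ValueError(
            f"top set is empty: N={v.size} with top_fraction={top_fraction}"
        )
    return float(v[k - 1])


def permutation_fdr(
    pct_ins: Sequence[float],
    pct_enh: Sequence[float],
    threshold_c: float,
    n_perms: int = 1000,
    seed: int = 0,
    top_fraction: float = 0.05,
) -> FDRReport:
    """Estimate the FDR of the SI top set by pairing permutation.

    Each permutation shuffles the enhancer percentiles against the
    insulation percentiles (uniform random permutation), recomputes the
    products, and counts entries strictly above ``threshold_c``; the FDR is
    min(1, mean count / n_top). n_top counts observed products strictly
    above the threshold; if ties leave that count at zero it falls back to
    k = round(top_fraction * N).
    """
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    a = np.asarray(pct_ins, dtype=float)
    b = np.asarray(pct_enh, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("pct_ins and pct_enh must be aligned 1-D vectors")
    n = a.size
    si_obs = a * b
    n_strict = int((si_obs > threshold_c).sum())
    k = max(1, int(round(top_fraction * n)))
    n_top = n_strict if n_strict >= 1 else k

    rng = np.random.default_rng(seed)
    exceed = np.empty(n_perms)
    for p in range(n_perms):
        perm = rng.permutation(n)
        exceed[p] = (a * b[perm] > threshold_c).sum()
    mean_exceed = float(exceed.mean())
    return FDRReport(
        threshold_c=float(threshold_c),
        top_fraction=float(top_fraction),
        n_top=n_top,
        n_top_strict=n_strict,
        k=k,
        n_perms=int(n_perms),
        mean_null_exceed=mean_exceed,
        fdr=float(min(1.0, mean_exceed / n_top)),
        seed=int(seed),
    )


def mean_si_fdr(reports: Dict[str, FDRReport]) -> float:
    """FDR of the mean SI score: the minimum FDR over cell lines."""
    if not reports:
        raise ValueError("empty report map")
    return min(r.fdr for r in reports.values())


def per_cr_tail_fdr(
    pct_ins: Sequence[float],
    pct_enh: Sequence[float],
    n_perms: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Per-CR tail FDR: the permutation tail ratio evaluated at each CR's
    own SI value.

    For CR *i*: (mean number of null products strictly above SI_i) divided
    by the number of observed products >= SI_i, capped at 1.
    """
    a = np.asarray(pct_ins, dtype=float)
    b = np.asarray(pct_enh, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("pct_ins and pct_enh must be aligned 1-D vectors")
    n = a.size
    si_obs = a * b
    rng = np.random.default_rng(seed)
    null = np.concatenate([a * b[rng.permutation(n)] for _ in range(n_perms)])
    null.sort()
    # mean count of null values strictly above each observed SI
    n_null_above = null.size - np.searchsorted(null, si_obs, side="right")
    mean_null = n_null_above / n_perms
    obs_sorted = np.sort(si_obs)
    n_obs_ge = si_obs.size - np.searchsorted(obs_sorted, si_obs, side="left")
    return np.minimum(1.0, mean_null / n_obs_ge)
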
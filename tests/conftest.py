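import numpy as np
import pytest

from tadsi.boundaries import (
    call_boundaries,
    directionality_index,
    fit_hmm_states,
    insulation_track,
)
from tadsi.synthetic import SyntheticConfig, simulate_contact_matrix

# Analysis windows matched to the generator's 100-bin (1 Mb) TADs.
INS_WINDOW = 10
DI_WINDOW_BP = 400_000


def run_boundary_pipeline(cm, seed=0, ins_window=INS_WINDOW, di_window_bp=DI_WINDOW_BP):
    ins = insulation_track(cm, window_bins=ins_window)
    di = directionality_index(cm, window_bp=di_window_bp)
    states = fit_hmm_states(di, seed=seed)
    return ins, di, states, call_boundaries(states, ins)


def coverage_oracle(iv, intervals):
    """Per-base boolean-array oracle for overlap counting."""
    mask = np.zeros(iv.end - iv.start, dtype=bool)
    for m in intervals:
        if m.chrom != iv.chrom:
            continue
        lo, hi = max(iv.start, m.start), min(iv.end, m.end)
        if hi > lo:
            mask[lo - iv.start:hi - iv.start] = True
    return int(mask.sum())


@pytest.fixture(scope="session")
def default_cfg():
    return SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def sim(default_cfg):
    return simulate_contact_matrix(default_cfg)


@pytest.fixture(scope="session")
def pipeline(sim):
    cm, truth = sim
    return run_boundary_pipeline(cm, seed=7)
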
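# tadsi

Structure-Influence (SI) scoring of disease-associated chromosomal
rearrangements from Hi-C data.

Structural variants — deletions, duplications, inversions — can cause
disease without touching a coding sequence: when a rearrangement removes or
displaces a TAD boundary, enhancers can be brought into contact with genes
they normally never see ("enhancer hijacking"), as in the limb-malformation
rearrangements at the *EPHA4*/*IHH* locus. `tadsi` prioritizes
rearrangements by how likely they are to act through this mechanism,
scoring each event against a cell line's Hi-C-derived TAD boundaries and
its ChromHMM strong-enhancer annotation. It is intended for groups curating
structural-variant call sets (ClinVar-like tables) who want a ranked,
FDR-annotated shortlist of candidate 3D-genome-disrupting events.

## The score

For each rearrangement (CR) that passes filtering (deletion / duplication /
inversion; length bounds; contains ≥ 1 TAD boundary):

* **Insulation Score** `I` — the strength (insulation-valley depth, in
  log2 units) of the strongest TAD boundary inside the CR. Boundaries are
  called per cell line from the binned contact matrix by a Dixon-style
  directionality index segmented with a 3-state HMM, and positioned/scored
  on the sliding-square insulation profile.
* **Enhancer Score** `E` — the total strong-enhancer base pairs in the
  three 400 kb windows centred on the two CR breakpoints and the strongest
  contained boundary (alternatively: enhancer bp over the whole CR divided
  by CR length).
* **SI score** — with `pct(·)` the percentile of a value within the CR
  cohort of that cell line,

  `SI = pct(I) × pct(E)  ∈ (0, 1]`.

Significance of the top SI set is estimated by a pairing-permutation test:
shuffle `pct(E)` against `pct(I)` (1000 permutations), count null products
exceeding the top-5 % threshold `c`, and report
`FDR = mean null exceedances / |{SI > c}|`. Across cell lines, the mean SI
is the arithmetic mean of per-cell-line SI values and its FDR is the
minimum per-cell-line FDR.

The package also includes a ShRec3D-style reconstruction for visualizing
the affected locus: contacts → dissimilarities (`d = 1/c^α`) → metric
completion by all-pairs shortest paths → classical MDS into 3D, with
per-bin annotation overlay (e.g. H3K4me1) and CR-bin highlighting.

## Worked example

Everything below runs on synthetic data generated by the package itself
(TAD-block contact matrices with power-law distance decay and Poisson
noise, enhancer hotspots at the planted boundaries, and labelled CRs that
do / do not span a boundary):

```python
import numpy as np
from scipy.stats import mannwhitneyu
from tadsi import (SyntheticConfig, simulate_contact_matrix, simulate_enhancers,
                   simulate_crs, insulation_track, directionality_index,
                   fit_hmm_states, call_boundaries, score_crs)
from tadsi.synthetic import truth_positions

cfg = SyntheticConfig(seed=11)            # 500 bins x 10 kb, 4 planted TAD boundaries
cm, truth = simulate_contact_matrix(cfg)
enh = simulate_enhancers(cfg.bin_index(), density=0.05,
                         hotspot_positions=truth_positions(cfg), seed=11)
crs, labels = simulate_crs(truth, enh, cfg.bin_index(), n_pos=20, n_neg=20, seed=11)

ins = insulation_track(cm, window_bins=10)
di = directionality_index(cm, window_bp=400_000)
calls = call_boundaries(fit_hmm_states(di, seed=11), ins)
print(f"boundaries called at bins {[c.bin for c in calls]} (truth: {list(truth)})")

scores = score_crs(crs, calls, enh, missing_boundary="zero")
print(scores.nlargest(3, "si")[["cr_id", "pct_ins", "pct_enh", "si"]].to_string(index=False))

y = labels.set_index("cr_id").loc[scores["cr_id"], "expected_high_si"].values
pos, neg = scores["si"][y], scores["si"][~y]
auc = mannwhitneyu(pos, neg, alternative="greater").statistic / (len(pos) * len(neg))
print(f"SI separates boundary-disrupting from intra-TAD CRs: AUC = {auc:.3f}")
```

Output:

```
boundaries called at bins [99, 199, 300, 399] (truth: [100, 200, 300, 400])
 cr_id  pct_ins  pct_enh    si
 pos_2     1.00    0.825 0.825
pos_16     1.00    0.800 0.800
pos_19     0.85    0.900 0.765
SI separates boundary-disrupting from intra-TAD CRs: AUC = 1.000
```

All four planted boundaries are recovered within one bin; the top-SI CRs
are boundary-spanning events with enhancer-rich windows, and SI cleanly
separates the engineered structure-disrupting CRs (`pos_*`, SI near 1)
from intra-TAD controls.

The same pipeline is scriptable from the shell:

```sh
tadsi simulate --seed 11 --out sim/
tadsi boundaries sim/matrix.coo.txt --chrom chrS \
      --insulation-window 10 --di-window 400000 --out tracks/
tadsi score sim/matrix.coo.txt sim/enhancers.bed sim/crs.tsv --chrom chrS \
      --insulation-window 10 --di-window 400000 \
      --enhancer-states synthetic_strong_enhancer --out scored/
tadsi fdr scored/scores.tsv --out fdr.json
tadsi model3d sim/matrix.coo.txt --chrom chrS \
      --cr 1700000-2300000:duplication --out model/
```

With real data, `tadsi score` takes a COO/dense contact-matrix text file,
a ChromHMM segmentation BED (the strong-enhancer states
`4_Strong_Enhancer,5_Strong_Enhancer` are the default filter) and a TSV of
rearrangements (`chrom  start  end  type` plus optional
`cr_id disease gene pubmed`; half-open 0-based coordinates).

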
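# tpac

Tissue-adjusted single-sample gene set scoring for tumor expression data.

Each tumor expression profile is scored against each gene set by a squared
Mahalanobis-style distance between the tumor and a matched normal-tissue
reference, using a diagonal covariance whose per-gene variances are inflated
or deflated by the tissue-specificity fold-change `t* = t / t_bar` (matched
tissue mean over cross-tissue average mean). Deviations are split into
up-regulated and down-regulated parts and scored separately (`S+`, `S-`) and
jointly (`S`). Distances are calibrated against a column-permutation null
with per-set maximum-likelihood gamma fits, so scores are gamma CDF values
in `[0, 1]` and `1 - S` is a valid p-value supporting single-sample
inference with BH FDR control.

Inputs must be **linear-scale** normalized expression (TPM-like); `t*` is a
linear fold-change, and log-scale input silently changes its meaning.

## CLI

```bash
# generate a small self-consistent toy dataset
tpac fixtures --out demo --seed 1

# score it: writes scores_{total,plus,minus}.tsv, pvalues_*.tsv, fdr_*.tsv
# and provenance.json
tpac score --expression demo/expression.tsv \
           --ref-tissue demo/tissue_mean.tsv \
           --ref-average demo/tissue_average.tsv \
           --gmt demo/sets.gmt --out demo/scores --seed 1

# Poisson calibration studies (prints the empirical type I error / power)
tpac simulate null --out demo/sim --seed 1
tpac simulate power --out demo/sim --seed 1 --delta-grid 0.5,1.0,2.0
```

File conventions: expression is a TSV with rows = samples and columns =
genes (first column sample id); reference profiles are two-column
`gene<TAB>value` TSVs; gene sets are GMT. Failed gamma fits yield empty
fields in the output matrices, never fabricated scores.

## Python API

```python
from tpac import tpac, TpacConfig, read_gmt

result = tpac(values, sample_ids, gene_ids, t, t_bar,
              read_gmt("hallmark.gmt"), TpacConfig(seed=1))
result.S          # n x m total-dysregulation scores in [0, 1]
result.P          # 1 - S, valid p-values under the permutation null
```

`tpac.calls` adds FDR-based significance calls (`call_significant`),
display thresholding and a tidy long-format export; `tpac.simulation`
exposes the Poisson null/power study (`estimate_type1_error`,
`estimate_power`).

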
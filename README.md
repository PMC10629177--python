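# sclstm

Single-cell type detection from scRNA-seq expression matrices. The pipeline
maps a cells × genes expression matrix through a sigmoid-kernel similarity
embedding (log-transform → row inner products → global min-max → tanh),
learns a cell-pair similarity function with a weight-sharing twin-LSTM
network trained on same/different pairs, and assigns cell types by
agglomerative hierarchical clustering of the learned similarity matrix.
External validation metrics (ARI, NMI, Hungarian-mapped ACC, balanced
accuracy) and a synthetic scRNA-seq generator are included, so everything is
testable without downloading data.

The twin-LSTM (forward pass, backpropagation through time, Adam) is
implemented in pure NumPy — no deep-learning framework required.

## Library quick start

```python
import numpy as np
from sclstm import (SyntheticSpec, simulate_counts, run_pipeline, RunConfig,
                    SiameseConfig)

X, truth = simulate_counts(SyntheticSpec(n_cells=200, n_genes=2000, k=4, seed=0))
cfg = RunConfig(variant="sclstm", k=4, siamese=SiameseConfig(seed=0))
res = run_pipeline(X, cfg, true_labels=truth)
print(res.metrics)           # {'ari': ..., 'nmi': ..., 'acc': ..., 'bas': ...}
print(res.clustering.labels) # per-cell assignments
```

Variants: `sclstm` (full pipeline), `siglstm` (single-branch ablation:
cluster the per-cell LSTM embeddings), `raw_kernel` (cluster the kernel
similarity directly). Clustering methods: `AG` (agglomerative, default),
`KM` (k-means), `SC` (spectral). When `k` is not given, the number of
clusters is estimated by a silhouette sweep.

## CLI

Every stage is independently scriptable:

```bash
sclstm simulate --spec spec.yaml --out expr.csv --labels-out truth.tsv
sclstm kernel   --input expr.csv --output S.csv
sclstm train    --input expr.csv --k 4 --config cfg.yaml --out model/
sclstm score    --model model/ --out M.csv
sclstm cluster  --similarity M.csv --k 4 --method AG --out pred.tsv
sclstm evaluate --true truth.tsv --pred pred.tsv
```

or end to end:

```bash
sclstm run --input expr.csv --labels truth.tsv --k 4 \
    --variant sclstm --method AG --seed 0 --out run1/
```

`run` writes `labels.tsv`, `M.csv`, `metrics.json` (when truth is given),
`run.log` (seed, config hash, per-epoch losses, stage timings) and
`config.echo.yaml`; it refuses to overwrite without `--force`.

Input formats: delimited text (CSV/TSV, cells × genes with id column and
header; `--orientation genes_by_cells` for transposed files) or Matrix
Market `.mtx` with companion `genes.tsv`/`barcodes.tsv` (10x convention,
genes × cells on disk). `--filter-genes 3` drops genes expressed in fewer
than 3 cells (droplet-data preprocessing; off by default).

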
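# lazytox

Local lazy learning models for rat acute oral toxicity (LD50) prediction.

Instead of one global QSAR model, every query compound gets its own local
models, fitted at prediction time on its nearest reference compounds under
four molecular similarity metrics (ECFP4, FCFP4, MACCS fingerprints with
Tanimoto distance; a normalized 2D descriptor panel, "DES", with a
dimension-normalized Euclidean distance):

- **LLR** — local lazy regression: a univariate least-squares line with
  automatic selection of the most predictive descriptor and of the neighbor
  count k (5–20), gated by leave-one-out Q².
- **SA** — arithmetic mean of the n nearest neighbor activities.
- **SR** — similarity-weighted mean of the n nearest neighbor activities.
- **GP** — geometric projection: the query is projected onto the line through
  each pair of neighbors in distance space and the projections are averaged
  with similarity-product weights; k is chosen per query starting at 3.

The 16 individual (model × metric) predictions are combined into per-kind
consensus models and a final consensus (arithmetic means). A distance-based
applicability domain (AD) per metric — threshold `D_T = d̄ + Z·σ` over
nearest-neighbor distances in the reference set — flags unreliable
predictions, and the *consensus prediction fraction* (share of the four
metric units covering a query) gates the reliability of the final consensus.

Activities are modeled as −log10(mol/kg); `convert_ld50` converts LD50 doses
in mg/kg (with molecular weight) onto that scale.

## CLI

```sh
# write a small toy SMILES world (reference.csv / query.csv)
lazytox simulate --out toy --seed 1

# per-metric feature files
lazytox featurize --reference toy/reference.csv --out toy/features

# fit applicability-domain thresholds
lazytox ad-fit --reference toy/reference.csv --out toy/ad.json

# pick the SA/SR neighbor count by 10-fold CV
lazytox select-n --reference toy/reference.csv --model sa --folds 4

# predict: 16 individual + 5 consensus rows per query, with AD columns
lazytox predict --reference toy/reference.csv --query toy/query.csv \
    --out toy/predictions.csv --seed 1

# score against observed activities (R², MAE, within/outside-AD MAE)
lazytox evaluate --predictions toy/predictions.csv --observed toy/query.csv \
    --out toy/report
```

Inputs are SMILES (`.smi`), SDF, or CSV/TSV with `id,smiles[,activity]` or
`id,smiles,ld50_mg_per_kg,mw` columns. Exit codes: 0 success, 1 usage error,
2 data error. All stochastic steps honor `--seed`.

## Library

```python
from lazytox import (
    read_compound_set, compute_fingerprints, find_neighbors,
    predict_sa, predict_sr, predict_gp, fit_predict_llr,
    fit_ad, check_ad, consensus, consensus_fraction, score,
)
```

`lazytox.workflow.predict_all` orchestrates the full 16-model + consensus
run over per-metric feature matrices (real molecules or synthetic worlds).

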
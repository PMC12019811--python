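# ntsvae

Joint imputation of missing **node features** and missing **weighted edges**
in *networked time series* (NTS) — multivariate time series whose entities
are nodes of a time-varying weighted graph, as found in epidemiological
surveillance (case counts linked by mobility), air-quality monitoring and
traffic-sensor networks. When a sensor or reporting unit fails, both its
measurements and its observed connections disappear, so feature imputation
and link prediction have to be solved together.

## The model

The data are a feature tensor `X̃ ∈ R^{T×N×D}` with binary observation mask
`Mˣ` and a sequence of weighted adjacency matrices `Ã_t ∈ R^{N×N}` with edge
mask `Mᴬ` (1 = observed, 0 = missing). `ntsvae` fits a bidirectional
variational autoencoder:

* **Position embeddings.** Each node's structural coordinates are its
  random-walk-with-restart (RWR) scores `r = (1−c) W r + c e_a` against a
  small anchor set, recomputed for every observed graph in the sequence.
  Unlike message-passing aggregation (bounded by 1-WL colour refinement),
  these scores separate nodes by their distance to the anchors even on
  vertex-transitive graphs.
* **Encoder.** A 2-layer GRU over `[features ‖ mask ‖ positions]` per node,
  mapping to a diagonal-Gaussian posterior over a per-node latent `z`.
* **Three-stage decoder**, per time step: (1) a linear predictor fills
  missing features from the recurrent state; (2) node link-embeddings plus a
  unit-norm Bochner time encoding predict the full weighted adjacency, and
  one round of degree-normalised message passing on that *predicted* graph
  produces structural embeddings; (3) self-attention across nodes refines
  the feature imputation. A GRU memory cell closes the recurrence. The
  whole decoder is replicated on the time-reversed sequence and an MLP
  merges both directions.
* **Loss.** Masked MAE on the merged output and on the raw stage-1/stage-3
  predictions, a per-entry-normalised Frobenius error on predicted vs
  observed adjacencies (weight `γ`), and `β`-weighted KL terms — a
  multi-task evidence lower bound. Observed entries are *never* overwritten:
  the filler operator `M ⊙ X̃ + (1−M) ⊙ Ŷ` guarantees exact conservation.

Everything runs on a small reverse-mode autodiff engine over numpy float64
(`ntsvae.autodiff`), so results are bit-reproducible from a single seed on
any CPU.

## Worked example

```python
import numpy as np
from ntsvae import (GeneratorConfig, ModelConfig, TrainConfig, generate_nts,
                    train, impute, evaluate, mean_baseline)

truth = generate_nts(GeneratorConfig(seed=0))       # N=12, T=200, 25% missing
mcfg = ModelConfig(hidden_dim=32, latent_dim=16, time_enc_pairs=4,
                   mlp_hidden=32, seed=0, time_scale=200)
tcfg = TrainConfig(epochs=300, window=24, stride=24, seed=0)
model, scaler, log = train(truth.bundle, mcfg, tcfg)
fx, fa = impute(truth.bundle, model, scaler, 24, 24)
m = evaluate(fx, fa, truth.features, truth.adjacency,
             truth.eval_feature_mask, truth.eval_edge_mask)
mb = evaluate(mean_baseline(truth.bundle), np.zeros_like(fa), truth.features,
              truth.adjacency, truth.eval_feature_mask, truth.eval_edge_mask)
print(f"trained MAE {m.mae:.3f} vs mean baseline {mb.mae:.3f}")
print(f"link Frobenius {m.link_frobenius:.1f} vs zero predictor {mb.link_frobenius:.1f}")
```

prints (about 90 s on one CPU core):

```
trained MAE 0.152 vs mean baseline 0.818
link Frobenius 14.7 vs zero predictor 44.2
```

i.e. on entries deliberately hidden from the model, the trained network
reconstructs features ~5× more accurately than per-node mean imputation and
the hidden edge weights ~3× more accurately than predicting no edges.

The same workflow is available from the shell:

```bash
ntsvae --seed 0 simulate --out data/
ntsvae --seed 0 train --bundle data/ --out model.npz --log losses.csv
ntsvae --seed 0 impute --bundle data/ --ckpt model.npz --out filled/
ntsvae --seed 0 evaluate --filled filled/ --truth data/ --out metrics.json
```

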
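# trfpid

Encoding-model comparison machinery for continuous neural responses to
speech: feature extraction, per-subspace ridge temporal response functions
(TRFs) under nested cross-validation with black-box hyperparameter
optimization, Gaussian-copula mutual information and pointwise partial
information decomposition (PID) of model predictions, iterative redundancy
mapping over leakage-correlated channel grids, phoneme-locked decoding
analyses, and hierarchical Bayesian performance comparison.  Every stage is
exercisable end to end on synthetic data with known ground truth — no
recordings are required.

## Modules

| module               | what it does |
|----------------------|--------------|
| `synthetic_data`     | smoothed-noise feature series, renewal-process event tables, gamma-kernel TRFs, shared-signal repeats, leakage grids, designed PID triplets |
| `features`           | log-mel spectrogram (31 bands), envelope, half-wave rectified derivatives, 455-filter 2-D Gabor modulation bank, 16-band Hilbert spectrogram, phoneme-onset / articulatory impulse spaces, resample + z-score, subspace concatenation |
| `encoding`           | lagged design matrices, closed-form ridge with block-diagonal per-subspace penalties, Pearson scoring, 6x5 nested CV with hyperparameter/weight averaging, block-rotation grid search |
| `hyperopt`           | bounded derivative-free maximizer (RBF-surrogate + poll steps), autocorrelation time, ACT-proportional lag-window allocation for modulation groups |
| `infotheory`         | copula normalization, bias-corrected Gaussian-copula MI (continuous + discrete targets), equipopulated-bin MI, pointwise common-surprisal PID, co-information, circular-shift permutation thresholds |
| `redundancy_mapping` | repeat-reliability maps, greedy iterative unique-information source search |
| `phoneme_analysis`   | event-locked epoching, per-class averages, MI and PID time courses over manner-of-articulation classes |
| `stats`              | hierarchical Bayesian comparison (Gibbs, half-t scale priors), directed-hypothesis fractions, silhouette index |

## CLI

```bash
trfpid simulate --config cfg.yaml --out sim/ --seed 1
trfpid features --audio x.wav --events x.tsv --spaces Sg,Deriv,Art --rate 40 --out x.h5
trfpid fit --features x.h5 --response y.h5 --mode nested --out fit.h5
trfpid pid --x predA.h5 --y predB.h5 --t observed.h5 --out pid.json
trfpid redmap --grid grid.h5 --out redmap.h5
trfpid prf --response y.h5 --events x.tsv --out prf.h5
trfpid compare --table perf.csv --family gaussian --out stats/
```

## Notes

- All information quantities are in bits.
- Event tables ship with a default ARPAbet phoneme-to-articulatory-feature
  and manner-class mapping (`src/trfpid/data/articulatory_features.tsv`),
  overridable by a user TSV of the same layout.
- The black-box optimizer is a contract plus a reference implementation
  (surrogate-assisted direct search); any maximizer that stays in bounds,
  is seed-deterministic and returns its evaluation trace can be plugged into
  `encoding.nested_cv`.
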
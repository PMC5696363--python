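# ssbl — structured sparse Bayesian learning for EEG source imaging

Two empirical-Bayes solvers for the spatio-temporal EEG inverse problem
`V = K J + ε`:

* **ENET-SSBL** — a hierarchical Bayesian Elastic Net. Each source amplitude
  carries a Gaussian prior whose variance is a truncated-Gamma scale mixture;
  marginally this is the Normal × Laplace (elastic-net) density. The variance
  scale `α1` and the truncation limit `k` are learned per time point.
* **ELASSO-SSBL** — a hierarchical Bayesian Elitist Lasso. The mixed-norm
  prior `exp(−α Σ_t ‖J_t‖₁²)` is decomposed as a pairwise Markov random
  field; conditioning on the cross-component couplings `δ` yields the same
  truncated-Gamma machinery with limits `α δ²`. One global `α` couples every
  time point.

Both are fitted by coordinate-descent minimization of the type-II objective
(negative log posterior of the hyperparameters) with the Gaussian posterior
moments held fixed between sweeps; the objective is non-increasing across
iterations by construction.

Also included:

* **LORETA** baseline (Laplacian-penalized ridge) with per-time GCV selection
  over a 100-point grid,
* a **simulator** for desk-scale benchmark studies — patch sources (30/20/10
  mm geodesic radii, slow cosines and a thresholded Gaussian-pulse train),
  alpha-band AR(2) source noise plus white sensor noise at an exact target
  SNR, and a jittered second lead field so inversion never uses the exact
  forward operator ("inverse crime" avoidance),
* the **quality-measure battery**: Earth Mover's Distance (exact transport
  LP), dipole localization error, ROC-AUC and F1 at the ROC-optimal operating
  point (reported as percentages), sparsity/activation curves, typical-trial
  ranking and pairwise Wilcoxon win-count tables.

## Command line

```bash
# generate a trial archive (4 hemispheric patch configurations)
ssbl simulate --out study/ --seed 1 --trials 20

# fit one method from TSV matrices
ssbl fit --method enet-ssbl  --leadfield K.tsv --eeg V.tsv --out J.tsv
ssbl fit --method loreta     --leadfield K.tsv --eeg V.tsv --laplacian L.tsv --out J.tsv

# score externally produced estimates against an archive
ssbl evaluate --archive study/ --estimates est/ --out metrics.csv

# end-to-end benchmark: simulate -> fit -> evaluate -> reports
ssbl benchmark --out run/ --seed 1 --methods enet-ssbl,elasso-ssbl,loreta
```

Matrices are plain TSV (comment lines start with `#`); trial archives are
NumPy `.npz` containers plus a JSON manifest. Every benchmark output records
the master seed and a config hash; equal seeds give identical outputs.

## Package layout

| module | contents |
|---|---|
| `ssbl.core` | shared types, Gaussian posterior (N×N route), type-II objective, graph Laplacian |
| `ssbl.enet` | hierarchical Elastic Net solver and its coordinate updates |
| `ssbl.elasso` | hierarchical Elitist Lasso solver (`update_delta`, `winv_apply`, global α) |
| `ssbl.loreta` | Laplacian ridge + GCV baseline |
| `ssbl.simulate` | source spaces, spherical/smoothed-random lead fields, patch sources, noise, trial archives |
| `ssbl.metrics` | EMD, DLE, AUC, F1, sparsity level, rank summaries |
| `ssbl.benchmark` | end-to-end pipeline and report writing |
| `ssbl.cli` | `ssbl` command-line entry point |
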
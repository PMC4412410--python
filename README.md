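# motorpls

Two-sided dimensionality reduction for motor encoding: extract the features
of a high-dimensional rhythmic motor output (within-wingstroke yaw torque)
that covary with a small set of neuromuscular spike-timing signals, then
test whether those signals act as a **muscle synergy** (a single linear
combination) or encode the movement **independently**.

The package targets the kind of experiment where a tethered insect flies in
front of a visual stimulus while a torquemeter records yaw torque and EMG
electrodes record one spike per wingstroke from each of the paired
downstroke muscles (left/right DLM of a hawkmoth). It is equally usable on
synthetic data from its own generator, which reproduces the statistical
structure of that experiment with known ground truth.

## The method

Per wingstroke the data are a timing vector and a torque waveform, stacked
into a standardised N x 2 signal matrix **U** = (t_L, t_R) and a
centred/scaled N x 500 waveform matrix **M**. The core decomposition is
SIMPLS partial least squares run from movement to motor signals: with
S0 = MᵀU, each step takes the leading singular pair (r, c) of the deflated
cross-covariance and forms

    k = M r / ||M r||      (score: how much of the feature each wingstroke has)
    p = Mᵀ k               (loading: the motor feature, a torque waveform shape)
    q = Uᵀ k,  d = U q     (signal-side loadings and scores)

deflating S by the orthonormalised feature direction (modified
Gram–Schmidt) and orthogonalising d against previous scores, so each
feature beyond the first explains only independent signal variation.
Feature significance is judged against a permutation null (shuffle M's rows
against U, re-fit; threshold at the 99.5% quantile of per-column maxima
over 1000 resamples). Encoding models — independence (t_L, t_R),
differential synergy (Δt = t_L − t_R), empirical synergy (first PC of the
timings), redundancy (one muscle) — are compared by leave-one-out PRESS on
mean torque and on the feature scores, and by reconstructing torque as

    M′ = STA + s·k₁p₁ᵀ + s·k₂p₂ᵀ

with scores either measured or predicted from each model. A torquemeter
module calibrates and inverts the instrument's second-order rotational
dynamics (I·φ̈ + C·φ̇ + κ·φ = τ) so the analysis runs on applied torque, not
raw angle.

## Worked example

```python
import numpy as np
from motorpls import (GeneratorConfig, generate_ensemble, simpls,
                      significance_by_resampling, variance_explained,
                      encoding_model, press_loo, reconstruct, error_metrics)

# a default synthetic experiment: 500 wingstrokes, independent encoding
ens, signals, truth = generate_ensemble(GeneratorConfig(), seed=1)

pls = simpls(ens.M, signals.U, n_components=10)
ve = variance_explained(pls, signals.U)
sig = significance_by_resampling(ens.M, signals.U, n_features=10,
                                 n_resamples=1000, seed=1)
print("significant features per muscle:", list(sig.n_significant))
print("variance explained by features 1+2:", np.round(ve.cumulative[1], 3))

for name in ("independence", "synergy_dt", "synergy_pca"):
    X = encoding_model(name).design_matrix(signals)
    press, _ = press_loo(X, pls.K[:, 0])
    print(f"PRESS k1 {name}: {press:.4f}")

rec = reconstruct(ens, pls, n_features=2)
m = error_metrics(ens.raw_rows(), rec.rows)
print(f"2-feature reconstruction: nRMSE {m.nrmse:.3f}, "
      f"residual variance {m.residual_variance:.3f}")
```

Output:

```
significant features per muscle: [2, 2]
variance explained by features 1+2: [0.959 0.953]
PRESS k1 independence: 0.0395
PRESS k1 synergy_dt: 1.0037
PRESS k1 synergy_pca: 0.0514
2-feature reconstruction: nRMSE 0.055, residual variance 0.003
```

Reading it: the permutation test finds exactly the two generative torque
features, which together explain ~95% of the variance in each muscle's
spike timing. Predicting the first feature's score, the two-variable
independence model (PRESS 0.04 on a unit-variance response) clearly beats
the differential synergy (PRESS ≈ 1: Δt carries almost none of this
feature) and modestly but consistently beats the empirical PCA synergy —
the signature of independent encoding. The two-feature reconstruction
recovers the torque waveforms to 5.5% RMS error.

## Command line

The same pipeline is scriptable from the shell; each stage reads/writes a
shared HDF5 container so stages can be rerun independently:

```
motorpls simulate --seed 1 --out data/           # synthetic dataset + truth
motorpls run --simulate-seed 1 --seed 1 --out results/
motorpls align --torque data/torque.csv --spikes data/spikes.csv \
         --mode phase --container results.h5
motorpls decompose --container results.h5 --n-resamples 1000
motorpls test-models --container results.h5
motorpls reconstruct --container results.h5 --cv-reps 200
```

`motorpls run` writes `report.json`, per-stage CSV tables and a JSON-lines
run log with seeds, config hash and dropped-cycle counts; reruns with the
same seed are byte-identical.

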
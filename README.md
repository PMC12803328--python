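# lairelease

Time-independent, explainable prediction of drug release from the material
characteristics of polymer-based long-acting injectables (LAIs).

Long-acting injectables — typically drug-loaded PLGA microparticles — release
their payload over days to months. Characterizing an in-vitro release profile
is the slowest step of formulation development, and profiles from different
studies are measured at irregular times over wildly different durations, which
makes it hard to learn how material characteristics (polymer molecular weight,
encapsulation efficiency, particle size, drug lipophilicity, ...) shape the
release curve. `lairelease` is a toolkit for formulation scientists and
ML practitioners that makes such heterogeneous data comparable and models it
three ways:

1. **Early release** — interpolate the fractional release at 24, 48 and 72 h
   and regress it on the 11 material descriptors (linear, random-forest and
   gradient-boosted models, the latter reported as "XGB").
2. **Release-type classification** — min-max normalize each profile's time
   axis to [0, 1], normalize its magnitude, resample it onto a fixed uniform
   grid, and summarize its shape by the area under the curve:

   AUC = ∫₀¹ R(t̃) dt̃,  with t̃ = (t − t_min)/(t_max − t_min).

   AUC = 0.5 is a perfectly linear (monophasic) release; burst-biphasic
   curves are front-loaded (AUC > 0.5) while delayed-biphasic and triphasic
   curves stay below (AUC ≤ 0.5). Profiles are classified into these two
   release types from the material descriptors alone.
3. **Complete profiles** — a custom static-to-sequence recurrent network maps
   the descriptor vector X ∈ ℝ^(N×d) through a fully connected embedding to
   Z ∈ ℝ^(N×f), repeats Z along a new time axis to ℝ^(N×T×f), runs an LSTM or
   GRU stack, and projects each hidden state to one release value, producing
   the full curve R̂ ∈ ℝ^(N×T) **without ever taking time as an input**.
   Training minimizes MSE = (1/N)(1/T) Σᵢ Σₜ (R_{i,t} − R̂_{i,t})²; the
   time-as-input gradient-boosted baseline ("XGB-Time") and its no-time
   ablation (which can only produce flat curves) are included for comparison.

Every model is evaluated with 10×2 nested cross-validation (50-trial seeded
random hyperparameter search per outer fold, standardization fit on training
folds only) reporting RMSE and Pearson correlation, or accuracy / AUROC /
precision / recall / F1, plus per-AUC-group profile errors. Exact Shapley
attributions (closed-form for linear models, tree-path TreeSHAP for forests
and boosted trees) rank the material characteristics and report their
direction of effect.

A fully seeded synthetic study generator (`lairelease.synthetic`) emulates
the structure of published PLGA release compilations — 11-descriptor feature
tables, irregular sampling, 3–120 day durations, a 0.26/0.74 delayed/burst
class mixture, and known feature→kinetics drivers — so the entire pipeline is
testable without external data.

## Worked example

```python
import numpy as np
import lairelease as lr

ds = lr.generate_dataset(150, seed=42)
normalized = [lr.resample_profile(p, T=101, magnitude_mode="max") for p in ds.profiles]
labels = np.array([lr.assign_profile_type(lr.compute_auc(p)).release_type
                   for p in normalized])
print(f"release types  0 (delayed, AUC<=0.5): {(labels == 0).sum()}"
      f"   1 (burst, AUC>0.5): {(labels == 1).sum()}")

y24 = np.array([lr.early_release_targets(p).frac_24h for p in ds.profiles])
reports = lr.run_nested_cv(ds.feature_frame(), y24, "regression", ["gbdt"],
                           trials=10, seed=42)
rep = reports["gbdt"]
from lairelease.evaluation import pooled_pearson
print(f"24 h release, XGB nested CV: RMSE {rep.metric_mean('rmse'):.3f}, "
      f"pooled Pearson r {pooled_pearson(rep):.2f}")

fm, _ = lr.encode_and_standardize(ds.feature_frame())
from lairelease.tabular import ModelSpec, make_model
model = make_model(ModelSpec("gbdt", "regression",
                             {"max_depth": 6, "n_estimators": 200})).fit(fm.X, y24)
att = lr.compute_attributions(model, fm)
print(lr.rank_features(att).head(3)[["feature", "mean_abs", "share"]].to_string(index=False))
```

prints

```
release types  0 (delayed, AUC<=0.5): 40   1 (burst, AUC>0.5): 110
24 h release, XGB nested CV: RMSE 0.240, pooled Pearson r 0.17
                 feature  mean_abs    share
              polymer_mw  0.082589 0.246051
encapsulation_efficiency  0.057037 0.169927
                 drug_mw  0.039503 0.117689
```

The class split mirrors the configured 0.26/0.74 mixture; the Shapley
ranking recovers the generator's configured early-release drivers (polymer
MW and encapsulation efficiency lead; both lower early release as they
increase). The held-out correlation is modest by construction: synthetic
study durations are drawn independently of the descriptors, which caps how
much of the 24 h release the features can explain (see `docs/methods.md`).

The same stages run from the shell:

```bash
lairelease simulate --seed 42 --out runs/demo
lairelease run-all  --seed 42 --out runs/demo
```

writing metric tables, predictions, attribution rankings and a
reproducibility manifest under `runs/demo/`.

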
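# riemecg

Riemannian covariance features from 12-lead ECGs, fused with clinical-history
text, for predicting cardiopulmonary exercise testing (CPET) outcomes in
congenital heart disease (CHD) cohorts.

## The problem

CPET variables — VE/VCO₂ (ventilatory efficiency), VO₂ %pred (percent of
predicted oxygen uptake) and VO₂ peak (L/min) — are robust surrogate markers
of mortality risk in CHD. Predicting them directly from routinely collected
12-lead ECGs and clinical letters would let clinicians track functional
capacity between exercise tests. CHD cohorts are small, heterogeneous and
imbalanced across lesion classes (tetralogy of Fallot, ASD, pulmonary
atresia, Fontan, Mustard), which defeats large deep-learning models; this
package implements a geometric alternative:

1. **Covariance features.** Each recording is summarised by its 12×12
   inter-lead covariance **C**, estimated from R-peak-aligned ~1 s beats.
   **C** is symmetric positive-definite (SPD), a point on a curved manifold.
2. **Tangent-space mapping.** Under the affine-invariant Riemannian metric
   (AIRM), d(A,B) = ‖logm(A^{-1/2} B A^{-1/2})‖_F, covariances are projected
   at the cohort Fréchet mean **C̄**:

       V_i = upper( C̄^{-1/2} Log_C̄(C_i) C̄^{-1/2} )

   giving n(n+1)/2 = 78 Euclidean features per ECG whose norms equal
   Riemannian distances (off-diagonals scaled by √2).
3. **Covariance mixup.** Training pairs are interpolated along manifold
   geodesics: C_aug = argmin_C Σᵢ wᵢ d(C, Cᵢ)², with weights (1−α, α) and
   α ~ Beta(0.4, 0.4). The matched clinical-letter term-frequency vectors are
   mixed linearly with the *same* α, keeping augmented samples coherent
   across modalities. Minority outcome groups are balanced this way.
4. **Fusion and evaluation.** Tangent features are concatenated with
   bag-of-words counts from the letter nearest in date to the ECG, and
   SVM models are scored under a stratified patient leave-out protocol:
   100 random splits, each holding out one patient per lesion class, with
   every fold-dependent fit (Fréchet reference, vocabulary, scaler,
   augmentation) computed from training patients only.

Because the motivating clinical dataset is private, the package ships a
synthetic multimodal cohort generator (`riemecg.cohort`) with ground truth:
class-structured SPD prototypes, ECG waveforms realising them with
detectable R peaks, class/severity-conditioned letters, and CPET outcomes
that are noisy linear functions of the true tangent coordinates.

## Worked example

```python
import numpy as np
from riemecg import cohort, evaluate, geometry

cfg = cohort.CohortConfig(seed=1)                   # 5 classes, 40 patients
dataset = cohort.to_dataset(cohort.simulate_cohort(cfg))
plan = evaluate.make_split_plan(dataset.class_by_patient, n_repeats=100, seed=2)

acc = evaluate.lesion_recovery_accuracy(dataset, plan)
print(f"lesion-class accuracy: {acc.mean:.3f} +/- {acc.std:.3f}")

reg = evaluate.pooled_regression_metrics(
    dataset, plan, "tangent_ecg", "vo2_peak", seed=3)
print(f"VO2 peak pooled pearson r: {reg['pearson_r']:.3f}  RMSE: {reg['rmse']:.3f} L/min")
```

prints

```
lesion-class accuracy: 1.000 +/- 0.000
VO2 peak pooled pearson r: 0.614  RMSE: 0.352 L/min
```

Covariance estimation, tangent projection and an SVM recover the five
simulated lesion classes perfectly at the default class separation, and the
held-out correlation for VO₂ peak approaches the ceiling set by the
generator's signal-to-noise ratio (true R² = 0.6 ⇒ r ≤ 0.77).

The ablation harness mirrors the clinical study design:

```python
rep = evaluate.run_ablation(
    dataset, plan, "classification", labels=["ve_vco2"],
    arms=("tangent_ecg", "tangent_ecg+text", "tangent_ecg+text+cov_aug"),
    seed=3)
print(rep[rep.metric == "f1_macro"])
```

From a shell, the same pipeline is available as
`riemecg simulate --out dir/` and
`riemecg train-eval --data dir/ --task classification --out report.csv`.

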
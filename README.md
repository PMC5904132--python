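# rhen — single-trial error/correct EEG classification via cortical rhythm entropy

`rhen` is a tested, reusable implementation of a single-trial EEG analysis used to
detect erroneous responses during auditory attention tasks: scalp epochs are mapped
to cortical dipoles by weighted-minimum-norm estimation (WMNE), each dipole's
spectral composition is summarized by **rhythm entropy** — the Shannon entropy of
its theta/alpha/beta band-power proportions — discriminative dipoles are selected by
an R² criterion, and error vs. correct trials are classified by a class-balanced
RBF-SVM with leave-one-out cross-validation.  A time-varying directed-network stage
(Kalman-tracked MVAAR + adaptive directed transfer function with phase-randomized
surrogate testing) quantifies information flow between the discriminative regions.

Because no public recording of this kind is deposited, the package ships a
first-class synthetic-EEG generator with known ground truth (active dipoles,
per-class band-power proportions, directed couplings) so that every stage can be
validated end to end.

## The model in brief

- **Inverse**: S(t) = W x(t) with W = R Aᵀ (A R Aᵀ + λ²C)⁻¹ and
  λ² = trace(A R Aᵀ)/(trace(C)·SNR²), SNR = 5 by default.
- **Feature**: per trial and dipole, Power_b = Σ_t S_b(t)² for b ∈ {θ, α, β};
  P_b = Power_b / Σ Power_b; iEn = −Σ_b P_b log₂ P_b ∈ [0, log₂ 3].
- **Selection**: R² = (E X₊ − E X₋)² / (4σ²); keep dipoles with R² ≥ 0.6·max R²
  (the fraction can also be chosen by a 0.1…1.0 sweep on LOOCV accuracy).
- **Classifier**: RBF-SVM, C ∈ {10⁻⁸, 10⁻⁷·², …, 10⁸} by nested grid search,
  leave-one-out evaluation with fold re-balancing; CA/SE/SP and rank-based AUC.
- **Connectivity**: X(t) = Σ_k w_k(t) X(t−k) + ε(t) tracked by a Kalman/RLS
  recursion; H(f,t) = (I − Σ_k w_k(t) e^{−j2πfkΔt})⁻¹;
  ADTF ι²_ij = |H_ij|²/Σ_k |H_ik|², integrated over 4–30 Hz; significance from 200
  phase-randomized surrogates.

## Worked example

```python
from rhen.pipeline import RunConfig, run_pipeline

manifest = run_pipeline(RunConfig(), "runs/demo")
print(manifest["results"]["metrics"])
```

which prints (seed 0, the default configuration):

```
{'ca': 1.0, 'se': 1.0, 'sp': 1.0, 'auc': 1.0, 'confusion': {'TP': 20, 'TN': 20,
 'FP': 0, 'FN': 0}, 'best_C': 0.9999999999999959}
```

Here the generator's default condition (theta-dominant error trials, 0.8/0.1/0.1,
vs. a uniform rhythm split in correct trials, sensor SNR 10) is strongly separable,
so all 40 trials classify correctly; `runs/demo/` also contains the per-dipole R²
map, the per-fold predictions, the directed-network edge list with surrogate
significance, and a manifest with per-stage timing and the full parameter echo.
The same pipeline is available from the shell:

```bash
rhen run --out runs/demo
rhen simulate --seed 3 --out data/sim3
rhen network --series nodes.csv --sfreq 250 --surrogates 200 --out edges.csv
```

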
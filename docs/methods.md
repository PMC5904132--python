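# Methods

This note documents the models, parameter choices, numerical decisions and known
limitations of the `rhen` pipeline, in the order the stages run.

## Synthetic data generator (`rhen.synth`)

The generator emulates the statistical structure the analysis targets, not EEG
morphology.  Each active cortical dipole emits a sum of three band-limited noise
components (theta 4–8, alpha 8–13, beta 13–30 Hz), produced by zero-phase
band-pass filtering of white noise with a one-second guard band against filter
transients and rescaled so each component's mean-square power matches its
configured proportion exactly.  The two trial classes differ only in those
proportions; the defaults are the study condition used throughout the tests —
error trials theta-dominant at (0.8, 0.1, 0.1) (error-related activity is
theta-heavy in frontal cortex), correct trials uniform (1/3, 1/3, 1/3), giving
analytic rhythm entropies of 0.922 vs. 1.585 bits.

Defaults: 32 channels, 200 dipoles, 250 Hz, 700 ms epochs, 20 trials per class,
sensor SNR 10 (signal power / white-sensor-noise power, enforced per trial), and
three small active clusters (dipoles 20–22, 90–91, 150–152) mirroring the
medial-frontal / bilateral-SMA geometry of interest.  Inactive dipoles carry
broadband 4–30 Hz background at 10 % of the active amplitude, keeping selection
non-trivial.  Reaction times are truncated normal (floor 100 ms) with error trials
slower (800 ± 120 ms) than correct ones (650 ± 100 ms); only the direction of that
difference is meaningful.

The leadfield stand-in is a random mixing matrix with spatially correlated rows
(Gaussian smoothing across the channel axis, σ = 0.8 channels) and unit-norm
columns.  The smoothing is deliberately mild: a real electrode montage is
correlated but not rank-deficient, and stronger smoothing collapses the effective
rank of the forward model (σ = 1.5 already drops it from ~30 to ~13 of 32), which
no longer resembles any usable recording geometry.  Full row rank is verified at
construction.

What the generator does **not** emulate: ERP waveform shape (N1/P3), realistic
head geometry or depth-dependent gain, correlated (non-white) sensor noise,
inter-subject variability.  Passing tests therefore demonstrate correctness of the
algorithms under the stated statistical structure, not performance on real EEG.

## Preprocessing (`rhen.preproc`)

Artifact rejection removes whole trials whose amplitude exceeds ±75 µV on any
channel.  Rejection runs after filtering in the bundled pipeline; the order is a
configuration choice.

The 0.1–30 Hz band-pass is applied in the frequency domain: the squared Butterworth
magnitude (order 4 low-pass, order 2 high-pass) multiplies the epoch's spectrum.
A time-domain recursive filter cannot realize a 0.1 Hz edge on sub-second epochs —
its startup transient is longer than the data — whereas the spectral filter is
exactly zero-phase, rejects DC exactly, and has no transient.  The trade-off is the
implicit periodicity assumption of the DFT, acceptable for short, detrended
epochs.  Band decomposition into theta/alpha/beta uses zero-phase Butterworth
band-passes (the band edges are moderate, so forward–backward SOS filtering is
stable there); a Morlet-kernel backend is available as the field's alternative
convention.  The entropy feature depends only on band powers, so the two backends
agree to within their roll-off differences.

Re-referencing: common average by default; REST (reference electrode
standardization) when a leadfield is available, implemented as
V_∞ ≈ G · pinv(G_avg) · V_avg.

## Inverse (`rhen.inverse`)

W = R Aᵀ (A R Aᵀ + λ²C)⁻¹ with λ² = trace(A R Aᵀ)/(trace(C)·SNR²) and SNR = 5, the
conventional evoked-response value.  R and C default to identities; depth
weighting (R = diag‖a_j‖⁻²) is a switch and is moot for unit-norm synthetic
leadfields.  The operator is built with a symmetric solve rather than an explicit
matrix inverse and refuses systems with condition number above 10¹², reporting the
condition number.  The operator is computed once per dataset and reused across
trials and bands (it does not depend on the data under identity covariances).

## Rhythm entropy (`rhen.entropy`)

Power is the sum of squared amplitudes over the whole 700 ms window (no
sub-windowing).  0·log₂0 := 0 by the usual continuity convention.  Trials in which
some dipole has zero total band power admit no proportion vector; they are dropped
and logged rather than imputed (this occurs only for degenerate constructed
inputs).  Entropy is invariant to amplitude scaling and to permutation of the
bands, and non-decreasing along mixtures toward the uniform split — all property-
tested.

## Selection (`rhen.select`)

R² = (mean(X₊) − mean(X₋))²/(4σ²) with σ the **population SD of the pooled
feature values**; with the factor 4 and equal class sizes this equals the squared
point-biserial correlation between feature and class tag, matching the
"correlation between features and class tags" reading.  Error trials are the
positive class (R² is sign-free).  Dipoles at or above 0.6 of the maximum R² are
kept; the threshold sweep evaluates fractions 0.1…1.0 by LOOCV accuracy and breaks
ties toward the smallest fraction.  Back-projection places selected-space values
at their dipole indices (identity mapping), zero elsewhere.  Thresholding is
per-dataset (per-subject).

## Classification (`rhen.classify`)

RBF-SVM with γ = 1/(n_features·var(X)) (scale-aware default), features
standardized with training-fold statistics, C chosen from
10⁻⁸ … 10⁸ in steps of 10^0.8 (21 values) by stratified 5-fold grid search run
inside each LOOCV training fold (nested; a non-nested "one grid search on all
data" mode exists for comparison).  Grid-search ties go to the C nearest 1 on the
log scale: at chance level all C score alike, and extreme C values degenerate the
classifier, so the neutral centre is the only defensible tie-break.

Two protocol details matter for honest evaluation and are worth spelling out:

1. **Fold re-balancing.** With the dataset forced to exact class balance, removing
   the held-out trial leaves its class one short in every training fold — the
   fold's composition alone then reveals the held-out label.  Degenerate
   classifiers exploit this (measured chance-level accuracy reaches 1.0 or 0.0
   depending on class weighting), and an accuracy-driven grid search selects for
   it.  Each training fold therefore drops one random trial of the opposite
   class, making every fold exactly balanced and the composition uninformative.
   With this fix the measured chance-level accuracy is ~0.51.
2. **Selection inside the fold.** By default the R² dipole selection is recomputed
   on each training fold (no selection leakage); a global-selection mode mirrors
   the simpler protocol.

CA/SE/SP come from pooled confusion counts; AUC is the tie-corrected Mann–Whitney
statistic of the pooled decision scores (sklearn's implementation is used only as
an independent cross-check in the tests).  libsvm gets a generous iteration cap
(5·10⁴) as a guard against rare solver stalls at extreme C; problems of this size
normally converge orders of magnitude sooner.

## Time-varying network (`rhen.network`)

Node series are region means of dipole waveforms from the trial-averaged ERP.
Coefficients of the time-varying VAR are tracked by a Kalman/RLS recursion with
forgetting factor 1 − uc, uc = 10⁻³ (effective memory ≈ 1000 samples; results are
stable over uc ∈ 10⁻⁴…10⁻²), initial state 0 and initial covariance 100·I; the
first max(50, 5p) samples are excluded as burn-in.  Model order comes from the
Schwarz Bayesian criterion over stationary fits (statsmodels), clamped to ≥ 1.

The coefficient spectrum uses A(f,t) = I − Σ_{k=1..p} w_k(t) e^{−j2πfkΔt} — the
identity lag-0 term — so that the uncoupled case yields H = I.  The frequency grid
is 1 Hz over 1…Nyquist; the integrated ADTF is the **mean** of ι² over bins within
[4, 30] Hz inclusive (a sum divided by f2 − f1 would exceed 1 by one bin's worth on
an inclusive grid).  ADTF row sums (per receiver, per frequency, per time) equal 1
to 1e-10 by construction and are asserted in tests.

Surrogates randomize Fourier phases independently per node with Hermitian
symmetry — amplitude spectra are preserved to machine precision, cross-node phase
relations destroyed — and the full fit → H → ι² → ϑ² pipeline runs per surrogate
(batched; the Kalman recursion is vectorized across surrogates).  The per-edge
null pools surrogate values across retained time points by default (a per-time
mode exists); the 95th percentile is the significance threshold.  Measured
false-positive rate under a no-coupling null is ~4–5 % of edge-time points.
ADTF evaluation uses every 5th post-burn-in sample, which is dense relative to the
uc = 10⁻³ coefficient dynamics.

## Association statistics (`rhen.stats`)

Pearson correlations (two-sided) between reaction time and entropy or
degree-adjusted edge values; paired t-tests with Cohen's d = mean(diff)/sd(diff)
for entropy contrasts.  "Weighted degree" is the node's total incident strength
(in + out, diagonal excluded); in-only and out-only variants are options.  Edge
adjustment divides by that degree, making the value invariant to global network
scaling.  No multiple-testing correction is applied; reports carry the number of
tests performed.  Both tests are verified against textbook formulas to 1e-12 and
calibrated to 5 % type-I error under simulation.

## Problem sizes in the bundled studies

Replicate studies in the test suite and acceptance script use the generator's
default condition: 20 (tests) or 12 (script) replicate datasets per condition for
the classification studies, 50/30 seeds for chain-edge recovery, 20/8 null
datasets × 200 surrogates for the false-positive calibration, and 2000/1000
replicates for the type-I-error checks.  These sizes give standard errors well
inside the asserted tolerances.

## Known limitations

- The three-band mixture is a stand-in for unspecified source spectra; entropy
  recovery tolerances (±0.1–0.15 bits) reflect band-filter leakage at 700 ms.
- The REST implementation uses the synthetic leadfield and claims only
  "closer to the infinite reference than the raw recording", verified in
  simulation.
- DTF-family measures show indirect (cascade) influences; the chain benchmark
  asserts ranking of direct edges above indirect ones, which holds for these
  coefficient magnitudes but is not a general guarantee.
- Single-trial inverse + entropy is amplitude-invariant per dipole, so crosstalk
  between dipoles — not amplitude error — is the limiting factor for selection
  recovery (mean Jaccard ≈ 0.5 at the default geometry).
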
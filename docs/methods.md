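# Methods

This note documents the models, conventions and design choices behind
`s21density`: what is computed, why the defaults are what they are, and what
the synthetic phantoms do and do not establish about clinical data.

## Problem and data model

A multistatic microwave breast scan records the complex forward-transmission
scattering parameter S21 between a transmitting and a receiving antenna that
rotate around the breast: 10 transmitter angles
{0°, 9°, 72°, 81°, 144°, 153°, 216°, 225°, 288°, 297°} (five pairs 72° apart,
the members of each pair 9° apart), 80 receiver positions every 4.5°, and
1601 frequency points from 1 GHz to 9 GHz in 5 MHz steps. One scan is an
800 × 1601 complex matrix, transmitter-major: rows `t*80 .. t*80+79` belong to
transmitter `t`. All indices are 0-based internally; frequency column `i`
holds `f = 1 GHz + i · 5 MHz`.

The scientific task is two-fold: classify breast density (low density LD =
BI-RADS A/B vs high density HD = C/D) directly from the calibrated
S-parameters, without image reconstruction; and quantify whether knowing the
density stratum improves healthy/non-healthy detection.

## Dual-domain FFT features

Per transmitter block `M_t` (80 × F):

1. **DC removal** — subtract each receiver row's mean across frequency.
   Removes receiver-wise background/system bias. Requires ≥ 2 columns;
   idempotent.
2. **Two DFTs** — unnormalised forward transforms with kernel
   `exp(-j·2πkn/N)`: along frequency per row (*RF-spectral* domain, N = F)
   and along receiver angle per column (*spatial* domain, N = 80).
3. **Truncation and polar split** — keep coefficients `k = 0..K-1`
   (default K = 40, where classification accuracy stabilises: low-order
   coefficients carry the dominant scattering structure, higher orders mostly
   noise), take magnitude and phase. Phase is `atan2` in (−π, π]; the phase
   of an exactly-zero coefficient is 0. `k = 0` is retained in both domains
   (it is ≈ 0 in the spectral domain after DC removal; in the spatial domain
   it carries the informative angular mean).
4. **Pooling** — mean and *population* standard deviation over all retained
   entries (rows × K), separately for magnitude and phase in each domain:
   8 statistics per block, concatenated over the 10 transmitters
   → 80 features whole-band.

In **per-band mode** the 1–9 GHz grid is first cut into eight 1 GHz sub-bands
SB1..SB8 (half-open [b, b+1) GHz; the 9 GHz endpoint belongs to SB8, so SB8
has 201 columns and the others 200). Each selected band is processed
independently — DC removal recomputed inside the band, then steps 2–4 —
and the per-band statistics are concatenated in (transmitter, band) order:
`8 · 10 · n_bands` features. Per-band recomputation of the DC term keeps each
band's features self-contained; the alternative (one DC pass, or a single
DFT of the concatenated selected columns) would couple a band's features to
the mask it was selected with.

Pooling choices that the feature definition leaves open, fixed here once:
statistics pool globally over rows × components (not per-row-then-averaged);
phase statistics use ordinary linear moments of the principal-value phase,
not circular moments.

**Standardization** is per-feature z-scoring with mean/std learned on
training samples only (applied inside every training split of the evaluation
harness, never on pooled data — no test leakage). Features constant on the
training set are flagged and mapped to exactly 0.

Baseline families, computed per block and concatenated the same way:
**SF** — mean, population std, min, max, median, range and Shannon index
`H = −Σ p_i ln p_i`, `p_i = |x_i| / Σ|x_j|`, of the flattened |S21| (an
all-zero block has H = 0); **block-PCA** — top 10 or 40 principal-component
scores of the flattened |S21| per transmitter, loadings fitted on training
scans only (PCA needs real inputs, hence the magnitude representation;
requesting more components than the centred training rank is an error).

## Evaluation protocol and the balance rate

Per Monte-Carlo run (default 5): a stratified 20% test split is held out;
4-fold cross-validation inside the remaining 80% gives validation metrics;
the model is refitted on the full 80% and scored on the held-out 20%.
Aggregates are means ± sample stds (ddof = 1) across runs. Splits are
stratified by class to preserve the near-balanced LD/HD ratio, and depend
only on (seed, labels), so sub-band masks evaluated under one plan share
identical partitions and are directly comparable.

The **balance rate**

    BR = (2 − (sensitivity + specificity)) + |sensitivity − specificity|

lies in [0, 2]: 0 only for a perfect balanced classifier, 2 at the
degenerate corners (always-one-class predictors). The absolute difference
penalises class imbalance that total accuracy hides. For density
classification, LD accuracy occupies the sensitivity slot and HD accuracy
the specificity slot; BR is symmetric, so the assignment is cosmetic. BR is
computed per run and then averaged — which is why recomputing BR from
*aggregated* class accuracies can differ from the averaged BR by up to a few
hundredths when the two class accuracies are nearly equal.

The classifier registry covers 5-NN (k = 5: small k is noise-sensitive,
large k oversmooths), Gaussian naive Bayes, SVM-RBF (C = 1,
`gamma = 1/(n_features · mean feature variance)`), linear SVM, decision
tree, random forest, AdaBoost, XGBoost (optional import) and a
majority-class dummy baseline. Hyperparameters beyond these are library
defaults, recorded in the report for audit.

**Sub-band search** ranks masks by mean test BR (ties: higher test
accuracy). The default candidate list is the 19 studied combinations (8
singles + 11 unions); all 255 non-empty masks are available. Ranks are raw
means ± stds; no multiple-testing correction is applied.

**Density-stratified detection**: with the density prior, one
healthy/non-healthy detector is trained per stratum and test samples are
routed by their density label; without it, a single pooled detector is
trained, metrics still reported per stratum (sensitivity = non-healthy
recall, specificity = healthy recall). A stratum with fewer than two
training samples of either health class is skipped with a warning.

## Synthetic phantom generator

Clinical scans are available only on request, so the package ships a
generator whose defaults reproduce the published across-receiver magnitude
statistics of healthy breasts: at 4 GHz, spatial std 5.73·10⁻⁵ (HD) vs
4.66·10⁻⁵ (LD) — a ≈ 23% HD excess — with CVs 0.46 (HD) / 0.53 (LD); at
6 GHz, CVs 0.62 (HD) / 0.68 (LD) and an HD std excess of ≈ 14%.

Magnitude is a lognormal angular field
`m(θ, f) = μ_c(f) · exp(s_c(f)·u(θ) − s_c(f)²/2)` with
`u(θ) = Σ_m √w_m (α_m cos mθ + β_m sin mθ)`, `α, β ~ N(0,1)` drawn per scan
and transmitter block. LD uses M = 4 harmonics, HD M = 12 with equal power
per order ("flat" profile) — HD therefore carries strictly more spatial-DFT
energy above harmonic 4, encoding the denser tissue's richer angular
scattering. Phase is a propagation delay `ψ = −2πf·τ(θ)` with
`τ(θ) = τ0 (1 + d cos(θ − θ_tx))` (τ0 = 1.5 ns, d = 0.1; the 1.5 ns delay
puts ~0.67 GHz oscillations into every sub-band), plus a class-scaled random
angular ripple (0.1 rad LD, 0.3 rad HD). Complex Gaussian noise with std
2% of μ_c(f) is added per sample.

Calibration targets the statistics that were actually measured — the
*across-receiver* std and CV — not the per-point ensemble moments. The
closed-form lognormal scale `s² = ln(1 + cv²)` is only the initial guess:
with finitely many harmonics the angular field is correlated across the 80
receivers, which biases the spatial std/CV low by ~1.5–4% (more for LD's 4
harmonics than HD's 12), enough to distort the inter-class excess ratios.
`calibrate` therefore root-finds `s_c` (and then scales `μ_c`) at 4 and
6 GHz so that the *expected* spatial CV and std match the anchors, using a
fixed-seed Monte-Carlo of the angular field (4000 draws; deterministic and
independent of user seeds), and interpolates the correction factors linearly
in f between the anchors (clamped outside). Consequence: the per-point
ensemble CV slightly exceeds the nominal cv (by a few percent) while the
measured spatial statistics land on the anchors. Between the anchors, CV is
linear in f and μ log-linear; μ_LD(6 GHz)/μ_LD(4 GHz) = 0.5 by the default
attenuation convention (the absolute 6 GHz level is otherwise
under-determined by the published CVs and ratio).

Tumours multiply the magnitude by `1 + κ_c · G(θ; θ₀, 25°)` (Gaussian
angular bump at a random angle) and add a delay bump of 0.02 ns with the
sign of κ_c. Defaults κ_LD = +0.15, κ_HD = −0.40: the contrast inverts
between fatty and dense backgrounds (tumour/background dielectric contrast
is large against fat and can invert against fibroglandular tissue), and HD
needs the larger |κ| because its richer angular field masks localized
perturbations. The delay bump is kept small because it is a sign-independent
signature that even a pooled detector can learn. These values were fixed at
design time so that the within-stratum tumour signal is learnable while the
pooled signal largely cancels — the construction that makes the
stratified-vs-pooled comparison meaningful.

`estimate_spatial_moments` computes population std across the 80 receivers
per transmitter block, then averages the 10 block values (the published
anchors do not state whether std was population or sample, per-block or
pooled; this choice is fixed once and its alternatives differ by less than
the 5% verification tolerance).

### What the phantoms do and do not show

They reproduce the published second-order spatial statistics, the
class-richness ordering, a plausible delay structure, and a density ×
tumour interaction — enough to exercise every pipeline stage end-to-end and
to verify calibration and protocol correctness. They are not
electromagnetic simulations: no anatomy, no frequency-dependent tissue
dispersion beyond the smooth μ/CV curves, no coupling between frequency and
angular structure, and the tumour model is a single smooth bump. Passing
the end-to-end tests therefore validates the *software* and the *protocol*,
not clinical performance; the published clinical accuracies (e.g. 73.66%
test accuracy for the five-band mask) depend on the unavailable cohort and
are deliberately out of scope.

## Problem sizes and numerical conventions

Ensemble verification uses 200 scans per class (sampling error of the mean
spatial std ≈ 0.8%, comfortably inside the 5% tolerance); the end-to-end
separability experiment uses 100 scans per class (SVM-RBF test accuracy
≥ 0.90 required, ≤ 0.55 for the identical-class null control); the
stratified-vs-pooled detection experiment uses 30 scans per density × health
cell with the naive-Bayes detector. Per-scan seeds derive from a master
seed via `numpy.random.SeedSequence`; identical (seed, config) pairs give
bit-identical scans and identical evaluation reports for deterministic
classifiers.

Text scan containers round-trip at full float64 precision (`%.17g`); the
binary container is a NumPy `.npz` with a JSON metadata block. Ties and
degenerate inputs: single-column DC removal is an error (it would zero the
row); an all-zero block has zero statistics and zero Shannon index; phase
−π is mapped to +π; a CV with zero mean and zero std is 0.

## Known limitations

* The phase model is separable in θ and f; real dispersion couples them.
* Phase-feature statistics use linear (not circular) moments; features
  whose phases straddle ±π inherit wrap noise.
* The spatial-moment calibration fixes first and second across-receiver
  moments only; higher moments follow from the lognormal assumption.
* Sub-band search reports raw means; with 255 masks, selection noise is
  not corrected for.
* The detection experiment demonstrates a qualitative ordering
  (stratified > pooled) under a constructed interaction; the magnitude of
  the improvement is a property of the phantom design, not a clinical
  estimate.
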